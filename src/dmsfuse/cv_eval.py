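"""Leave-one-protein-out evaluation of the AS-augmented predictor.

Each fold withholds every dataset of one protein; the substitution matrix
and the AS imputation mean are rebuilt from the remaining training data
only.  Two models are fitted per fold — with and without the AS feature —
and, for every (DMS, AS) pair of the held-out protein, prediction quality
is scored by Spearman correlation against the observed DMS scores over the
variant set V (missense variants at AS-covered residues).  The gain
attributable to AS data is delta_rho = rho_with - rho_without per pair.

The statistical layer provides Welch's unequal-variance t-test, the paired
t-test, step-down Holm-Sidak multiple-testing correction, and the
Gaussian asymptotic (order-statistic) confidence interval for medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import matching, model as model_mod
from .features import (
    assemble_features,
    build_substitution_matrix,
    impute_as_scores,
)
from .io_formats import AA_ORDER, ASDataset, MSAProfile, ScoreSet, VariantKey
from .model import LinearModel


class EvaluationError(ValueError):
    pass


@dataclass
class Corpus:
    """All normalized datasets and profiles for one run."""

    scoresets: list[ScoreSet]
    as_datasets: list[ASDataset]
    profiles: dict[str, MSAProfile]


@dataclass
class CVConfig:
    match_mode: str = "all"  # all | compat_high | compat_high_medium | correlation | none
    train_subset: str = "all_variants"  # all_variants | as_covered_only
    as_feature_source: str = "as_data"  # as_data | dms_alanine
    merge_replicates: bool = False
    as_combine: str = "per_source"  # per_source | mean
    alanine_only_eval: bool = False
    imputation_scope: str = "training"  # training | all_studies
    min_overlap: int = 3
    compat_rules: dict | None = None
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        allowed = ("all", "compat_high", "compat_high_medium", "correlation", "none")
        if self.match_mode not in allowed:
            raise EvaluationError(
                f"unknown match_mode {self.match_mode!r}; expected one of {allowed}"
            )


@dataclass
class PairEvaluation:
    dms_id: str
    as_id: str
    protein_id: str
    n_variants: int
    n_residues: int
    rho_with_as: float
    rho_without_as: float
    delta_rho: float
    all_variant_dms_as_corr: float


# --- splitting and matching -------------------------------------------------

def lopo_splits(
    scoresets: list[ScoreSet],
) -> list[tuple[list[ScoreSet], str]]:
    """One (training score sets, held-out protein) split per protein."""
    proteins = sorted({s.protein_id for s in scoresets})
    if len(proteins) < 2:
        raise EvaluationError(
            f"leave-one-protein-out needs >= 2 proteins, got {len(proteins)}"
        )
    return [
        ([s for s in scoresets if s.protein_id != p], p)
        for p in proteins
    ]


def dms_alanine_as(dms: ScoreSet) -> ASDataset:
    """The DMS dataset's own alanine column repackaged as an AS dataset.

    Used for the ablation that feeds complete X->A substitution information
    from DMS into the AS feature slot.
    """
    residues = {
        (k.position, k.wt_aa): s
        for k, s in dms.missense().items()
        if k.var_aa == "A"
    }
    return ASDataset(
        dataset_id=f"{dms.dataset_id}:alanine_column",
        protein_id=dms.protein_id,
        assay_category=dms.assay_category,
        residues=residues,
        wt_score=1.0,
        nonsense_score=0.0,
        normalized=dms.normalized,
        study_id=dms.study_id,
    )


def matched_as_for(
    dms: ScoreSet,
    candidates: list[ASDataset],
    config: CVConfig,
) -> list[ASDataset]:
    """AS datasets paired with one DMS dataset under the configured strategy."""
    if config.match_mode == "none":
        return []
    if config.as_feature_source == "dms_alanine":
        return [dms_alanine_as(dms)]
    same_protein = [a for a in candidates if a.protein_id == dms.protein_id]
    if config.match_mode == "all":
        return same_protein
    if config.match_mode == "compat_high":
        return matching.filter_by_compatibility(
            dms, same_protein, "high_only", config.compat_rules
        )
    if config.match_mode == "compat_high_medium":
        return matching.filter_by_compatibility(
            dms, same_protein, "high_and_medium", config.compat_rules
        )
    best = matching.match_by_correlation(dms, same_protein, config.min_overlap)
    return [best] if best is not None else []


def define_evaluation_variants(
    dms: ScoreSet,
    as_data: ASDataset,
    alanine_only: bool = False,
) -> list[VariantKey]:
    """Variant set V: missense DMS variants at residues the AS study covers.

    With ``alanine_only`` only the X->A substitutions themselves are kept
    (the literal shared-variant reading).
    """
    covered = set(as_data.residues)
    keys = [
        k for k in dms.missense()
        if (k.position, k.wt_aa) in covered
        and (not alanine_only or k.var_aa == "A")
    ]
    return sorted(keys)


# --- replicate merging ------------------------------------------------------

def merge_replicates(datasets: list):
    """Average datasets from the same study and assay category.

    Score sets are merged per variant, AS datasets per residue, by
    arithmetic mean of (normalized) scores; singleton groups pass through
    unchanged.
    """
    groups: dict = {}
    for ds in datasets:
        key = (ds.protein_id, ds.study_id, ds.assay_category)
        groups.setdefault(key, []).append(ds)
    merged = []
    for (protein, study, category), members in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))
    ):
        if len(members) == 1:
            merged.append(members[0])
            continue
        first = members[0]
        merged_id = f"{study}:merged:{len(members)}"
        if isinstance(first, ScoreSet):
            pooled: dict = {}
            for ds in members:
                for k, s in ds.scores.items():
                    pooled.setdefault(k, []).append(s)
            merged.append(replace(
                first, dataset_id=merged_id,
                scores={k: float(np.mean(v)) for k, v in pooled.items()},
            ))
        else:
            pooled = {}
            for ds in members:
                for k, s in ds.residues.items():
                    pooled.setdefault(k, []).append(s)
            merged.append(replace(
                first, dataset_id=merged_id,
                residues={k: float(np.mean(v)) for k, v in pooled.items()},
            ))
    return merged


# --- statistics -------------------------------------------------------------

def welch_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch unequal-variance t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EvaluationError("Welch's test needs n >= 2 in each group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise EvaluationError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(differences) -> tuple[float, float]:
    """Two-sided one-sample t-test on paired differences."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise EvaluationError("paired t-test needs n >= 2")
    if d.var(ddof=1) == 0:
        raise EvaluationError("zero variance of differences; test degenerate")
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue)


def holm_sidak(p_values) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise EvaluationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def median_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Gaussian asymptotic CI for the median via order-statistic ranks.

    Ranks n/2 +- z*sqrt(n)/2 (rounded half away from zero, clipped to
    [1, n]) on the sorted sample.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        raise EvaluationError("median CI needs n >= 2")
    z = stats.norm.ppf(0.5 + level / 2)

    def _round_half_away(x: float) -> int:
        return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))

    lo = min(max(_round_half_away(n / 2 - z * math.sqrt(n) / 2), 1), n)
    hi = min(max(_round_half_away(n / 2 + z * math.sqrt(n) / 2), 1), n)
    return float(v[lo - 1]), float(v[hi - 1])


# --- evaluation -------------------------------------------------------------

def evaluate_pair(
    model_with: LinearModel,
    model_without: LinearModel,
    dms: ScoreSet,
    as_data: ASDataset,
    V: list[VariantKey],
    *,
    profile: MSAProfile,
    matrix,
    imputed_mean: float,
    feature_source: ASDataset | None = None,
    pseudocount: float = 0.5,
    control: bool = False,
) -> PairEvaluation | None:
    """Score one (DMS, AS) pair on the variant set V.

    Returns None when the pair is excluded (fewer than 2 distinct residues,
    fewer than 2 variants, or a constant vector making the correlation
    undefined).  ``feature_source`` overrides the AS dataset used to build
    the prediction feature (for the DMS-alanine ablation); V and the
    score-correlation axis always come from ``as_data``.
    """
    n_residues = len({k.position for k in V})
    if len(V) < 2 or n_residues <= 1:
        return None
    sub = replace(dms, scores={k: dms.scores[k] for k in V})
    source = feature_source if feature_source is not None else as_data
    rows_without = assemble_features(
        sub, [], profile, matrix, as_enabled=False, pseudocount=pseudocount,
    )
    pred_without = model_mod.predict(model_without, rows_without)
    if control:
        rows_with, pred_with = rows_without, pred_without
    else:
        rows_with = assemble_features(
            sub, [source], profile, matrix, as_enabled=True,
            imputed_mean=imputed_mean, pseudocount=pseudocount,
        )
        pred_with = model_mod.predict(model_with, rows_with)
    observed = np.array([r.target for r in rows_with])
    as_at_residue = np.array(
        [as_data.residues[(r.key.position, r.key.wt_aa)] for r in rows_with]
    )
    try:
        rho_with = matching.spearman(pred_with, observed)
        rho_without = matching.spearman(pred_without, observed)
    except matching.MatchingError:
        return None
    try:
        pair_corr = matching.spearman(observed, as_at_residue)
    except matching.MatchingError:
        pair_corr = float("nan")
    return PairEvaluation(
        dms_id=dms.dataset_id,
        as_id=as_data.dataset_id,
        protein_id=dms.protein_id,
        n_variants=len(V),
        n_residues=n_residues,
        rho_with_as=rho_with,
        rho_without_as=rho_without,
        delta_rho=rho_with - rho_without,
        all_variant_dms_as_corr=pair_corr,
    )


def aggregate_by_amino_acid(pooled: pd.DataFrame) -> pd.DataFrame:
    """Prediction correlation per wild-type and per variant amino acid.

    ``pooled`` needs columns wt_aa, var_aa, observed, pred_with, pred_without.
    The wild-type alanine group is marked not applicable (AS data cannot
    exist there); groups with fewer than 2 variants are dropped.
    """
    records = []
    for kind, column in (("wt", "wt_aa"), ("var", "var_aa")):
        for aa in AA_ORDER:
            group = pooled[pooled[column] == aa]
            applicable = not (kind == "wt" and aa == "A")
            if len(group) < 2:
                continue
            if applicable:
                try:
                    rho_with = matching.spearman(group["pred_with"], group["observed"])
                    rho_without = matching.spearman(
                        group["pred_without"], group["observed"]
                    )
                except matching.MatchingError:
                    continue
            else:
                rho_with = rho_without = float("nan")
            records.append(dict(
                kind=kind, aa=aa, n=len(group), applicable=applicable,
                rho_with_as=rho_with, rho_without_as=rho_without,
            ))
    return pd.DataFrame(records)


# --- the full cross-validation loop ----------------------------------------

def _training_artifacts(train_sets, train_as, corpus, config):
    """Substitution matrix, matched sources and imputation mean for a fold."""
    matrix = build_substitution_matrix(
        [(k, s) for ds in train_sets for k, s in ds.missense().items()]
    )
    matched: dict[str, list[ASDataset]] = {
        ds.dataset_id: matched_as_for(ds, train_as, config) for ds in train_sets
    }
    if config.imputation_scope == "all_studies":
        pool_sets = corpus.scoresets
        pool_as = corpus.as_datasets
    else:
        pool_sets, pool_as = train_sets, train_as
    seen: dict[str, ASDataset] = {}
    for ds in pool_sets:
        for src in matched_as_for(ds, pool_as, config):
            seen[src.dataset_id] = src
    scores = [s for src in seen.values() for s in src.residues.values()]
    imputed_mean = impute_as_scores(scores) if scores else None
    return matrix, matched, imputed_mean


def run_cv(config: CVConfig, corpus: Corpus):
    """Full leave-one-protein-out run; returns (evaluations, summary).

    Per fold: match AS data per strategy, rebuild the substitution matrix
    and imputation mean from training data, fit the with-AS and without-AS
    models, and evaluate every (DMS, AS) pair of the held-out protein.
    Pairs with <= 1 distinct residue or undefined correlations are counted
    and excluded.  The summary carries per-strategy medians with CIs, a
    paired t-test of delta_rho against zero, the delta-vs-correlation table
    and the per-amino-acid table.
    """
    scoresets = corpus.scoresets
    as_datasets = corpus.as_datasets
    if config.merge_replicates:
        scoresets = merge_replicates(scoresets)
        as_datasets = merge_replicates(as_datasets)
    evaluations: list[PairEvaluation] = []
    pooled_records = []
    n_excluded = 0
    skipped_folds = []
    for train_sets, protein in lopo_splits(scoresets):
        train_as = [a for a in as_datasets if a.protein_id != protein]
        matrix, matched, imputed_mean = _training_artifacts(
            train_sets, train_as, corpus, config
        )
        as_possible = config.match_mode != "none" and imputed_mean is not None
        rows_with, rows_without = [], []
        for ds in train_sets:
            profile = corpus.profiles[ds.protein_id]
            rows_without.extend(assemble_features(
                ds, [], profile, matrix, as_enabled=False,
                pseudocount=config.pseudocount,
            ))
            if not as_possible:
                continue
            sources = matched[ds.dataset_id]
            rows = assemble_features(
                ds, sources, profile, matrix, as_enabled=True,
                imputed_mean=imputed_mean, as_combine=config.as_combine,
                pseudocount=config.pseudocount,
            )
            if config.train_subset == "as_covered_only":
                by_id = {s.dataset_id: s for s in sources}
                rows = [
                    r for r in rows
                    if r.as_source_id is not None
                    and (r.key.position, r.key.wt_aa)
                    in by_id[r.as_source_id].residues
                ]
            rows_with.extend(rows)
        model_mod.compute_row_weights(rows_without)
        model_without = model_mod.fit(
            rows_without, as_enabled=False, training_meta={"fold": protein}
        )
        control = config.match_mode == "none"
        fold_usable = True
        if control or not (as_possible and rows_with):
            model_with = model_without
            if not control:
                # with-AS arm cannot be trained in this fold; log and skip it
                skipped_folds.append(protein)
                fold_usable = False
        else:
            model_mod.compute_row_weights(rows_with)
            model_with = model_mod.fit(
                rows_with, as_enabled=True, training_meta={"fold": protein}
            )
        if not fold_usable:
            continue
        # evaluate every (DMS, AS) pair of the held-out protein
        test_sets = [s for s in scoresets if s.protein_id == protein]
        test_as = [a for a in as_datasets if a.protein_id == protein]
        for dms in test_sets:
            profile = corpus.profiles[dms.protein_id]
            if control:
                pairs = [(a, a) for a in test_as]
            elif config.as_feature_source == "dms_alanine":
                # feature comes from the DMS alanine column; pairs stay real
                pairs = [(a, dms_alanine_as(dms)) for a in test_as]
            else:
                pairs = [(a, a) for a in matched_as_for(dms, test_as, config)]
            for as_data, feature_source in pairs:
                V = define_evaluation_variants(
                    dms, as_data, config.alanine_only_eval
                )
                result = evaluate_pair(
                    model_with, model_without, dms, as_data, V,
                    profile=profile, matrix=matrix,
                    imputed_mean=imputed_mean if imputed_mean is not None else 0.0,
                    feature_source=feature_source,
                    pseudocount=config.pseudocount,
                    control=control,
                )
                if result is None:
                    n_excluded += 1
                    continue
                evaluations.append(result)
                sub = replace(dms, scores={k: dms.scores[k] for k in V})
                rows_wo = assemble_features(
                    sub, [], profile, matrix, as_enabled=False,
                    pseudocount=config.pseudocount,
                )
                pwo = model_mod.predict(model_without, rows_wo)
                if control:
                    rows_w, pw = rows_wo, pwo
                else:
                    rows_w = assemble_features(
                        sub, [feature_source], profile, matrix, as_enabled=True,
                        imputed_mean=imputed_mean if imputed_mean is not None else 0.0,
                        pseudocount=config.pseudocount,
                    )
                    pw = model_mod.predict(model_with, rows_w)
                for r, a, b in zip(rows_w, pw, pwo):
                    pooled_records.append(dict(
                        wt_aa=r.key.wt_aa, var_aa=r.key.var_aa,
                        observed=r.target, pred_with=a, pred_without=b,
                    ))
    summary = summarize(evaluations, n_excluded, skipped_folds)
    pooled = pd.DataFrame(pooled_records)
    summary["per_amino_acid"] = (
        aggregate_by_amino_acid(pooled) if len(pooled) else pd.DataFrame()
    )
    return evaluations, summary


def summarize(evaluations, n_excluded=0, skipped_folds=()) -> dict:
    deltas = np.array([e.delta_rho for e in evaluations])
    summary = {
        "n_pairs": len(evaluations),
        "n_excluded": n_excluded,
        "skipped_folds": list(skipped_folds),
        "median_delta_rho": float(np.median(deltas)) if deltas.size else float("nan"),
        "median_rho_with_as": float(np.median([e.rho_with_as for e in evaluations]))
        if evaluations else float("nan"),
        "median_rho_without_as": float(
            np.median([e.rho_without_as for e in evaluations])
        ) if evaluations else float("nan"),
    }
    if deltas.size >= 2:
        summary["median_delta_rho_ci"] = median_ci(deltas)
        try:
            t, p = paired_t_test(deltas)
            summary["paired_t_vs_zero"] = {"t": t, "p": p}
        except EvaluationError:
            summary["paired_t_vs_zero"] = None
    summary["pair_table"] = evaluations_frame(evaluations)
    return summary


def evaluations_frame(evaluations: list[PairEvaluation]) -> pd.DataFrame:
    """Tabular form of the pair evaluations (delta-vs-correlation table)."""
    return pd.DataFrame([vars(e) for e in evaluations])


def compare_strategies(results: dict[str, list[PairEvaluation]]) -> pd.DataFrame:
    """Pairwise Welch tests on delta_rho between strategies, Holm-Sidak adjusted."""
    names = sorted(results)
    rows, raw_p = [], []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            da = [e.delta_rho for e in results[a]]
            db = [e.delta_rho for e in results[b]]
            try:
                t, p = welch_test(da, db)
            except EvaluationError:
                t, p = float("nan"), float("nan")
            rows.append(dict(strategy_a=a, strategy_b=b, t=t, p_raw=p))
            raw_p.append(p)
    df = pd.DataFrame(rows)
    if len(df):
        finite = np.isfinite(raw_p)
        adjusted = np.full(len(raw_p), np.nan)
        if finite.any():
            adjusted[finite] = holm_sidak(np.asarray(raw_p)[finite])
        df["p_adjusted"] = adjusted
    return df
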