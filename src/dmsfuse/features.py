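"""Predictor variables for the variant-effect model.

Three scalar features per variant — positional Shannon entropy of the MSA
column, log frequency of the variant amino acid among homologs, and the
mean training score for the wild-type->variant substitution pair — plus,
when alanine-scanning data are enabled, a 40-dimensional score-injection
encoding: two 20-blocks (wild-type and variant amino acid, alphabetical
order) each carrying the residue's AS score in one slot and zeros elsewhere.
Variants at residues without AS coverage receive the global mean of all
available AS scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import AA_INDEX, AA_ORDER, ASDataset, MSAProfile, ScoreSet, VariantKey

SCALAR_COLUMNS = ("entropy", "log_var_freq", "subst_score")
AS_COLUMNS = tuple(f"as_wt_{aa}" for aa in AA_ORDER) + tuple(
    f"as_var_{aa}" for aa in AA_ORDER
)


class FeatureError(ValueError):
    pass


@dataclass
class SubstitutionMatrix:
    """Mean normalized training score per ordered (wt, var) amino-acid pair.

    Up to 380 entries (20 x 19 ordered pairs of distinct amino acids); pairs
    unobserved in training fall back to the global training mean.
    """

    entries: dict[tuple[str, str], float]
    fallback: float
    n_observed: int

    def lookup(self, wt_aa: str, var_aa: str) -> float:
        return self.entries.get((wt_aa, var_aa), self.fallback)


@dataclass
class FeatureRow:
    key: VariantKey
    entropy: float
    log_var_freq: float
    subst_score: float
    as_value: float | None = None  # measured or imputed; None when AS disabled
    weight: float = 1.0
    target: float | None = None
    dms_id: str | None = None
    as_source_id: str | None = None

    @property
    def as_encoding(self) -> np.ndarray | None:
        if self.as_value is None:
            return None
        return encode_as_feature(self.key, self.as_value)


def positional_entropy(profile: MSAProfile, position: int) -> float:
    """Shannon entropy (nats) of the amino-acid frequencies at a position."""
    if position not in profile.frequencies:
        raise FeatureError(f"position {position} absent from profile")
    p = profile.frequencies[position]
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def log_variant_frequency(
    profile: MSAProfile,
    position: int,
    var_aa: str,
    pseudocount: float = 0.5,
) -> float:
    """Log homolog frequency of the variant amino acid at a position.

    Counts are recovered as frequency x alignment depth and smoothed:
    ln((count + c) / (depth + 20c)) with pseudocount c.
    """
    if position not in profile.frequencies:
        raise FeatureError(f"position {position} absent from profile")
    if var_aa not in AA_INDEX:
        raise FeatureError(f"non-canonical amino acid {var_aa!r}")
    freq = profile.frequencies[position][AA_INDEX[var_aa]]
    count = freq * profile.depth
    if count == 0 and pseudocount <= 0:
        raise FeatureError(
            "variant frequency is 0; a positive pseudocount is required"
        )
    return math.log((count + pseudocount) / (profile.depth + 20 * pseudocount))


def build_substitution_matrix(
    training_rows: list[tuple[VariantKey, float]]
) -> SubstitutionMatrix:
    """Per-pair arithmetic means of training scores.

    Must be rebuilt from training data only inside every cross-validation
    fold; the fallback for unobserved pairs is the global training mean.
    """
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    total, n = 0.0, 0
    for key, score in training_rows:
        if not key.is_missense:
            continue
        pair = (key.wt_aa, key.var_aa)
        sums[pair] = sums.get(pair, 0.0) + score
        counts[pair] = counts.get(pair, 0) + 1
        total += score
        n += 1
    if n == 0:
        raise FeatureError("no missense training observations")
    entries = {pair: sums[pair] / counts[pair] for pair in sums}
    return SubstitutionMatrix(entries=entries, fallback=total / n,
                              n_observed=len(entries))


def impute_as_scores(available) -> float:
    """Global mean of all available AS scores, used for uncovered residues."""
    values = list(available.values()) if isinstance(available, dict) else list(available)
    if not values:
        raise FeatureError("no AS scores available anywhere; cannot impute")
    return float(np.mean(values))


def encode_as_feature(key: VariantKey, as_value: float) -> np.ndarray:
    """40-vector with the AS score in the wild-type and variant slots.

    Block 1 (indices 0-19) is hot at the wild-type amino acid, block 2
    (20-39) at the variant amino acid; the other 38 entries are exactly 0.
    """
    if not key.is_missense:
        raise FeatureError(f"cannot encode non-missense variant {key}")
    if not np.isfinite(as_value):
        raise FeatureError(f"non-finite AS value {as_value!r}")
    vec = np.zeros(40)
    vec[AA_INDEX[key.wt_aa]] = as_value
    vec[20 + AA_INDEX[key.var_aa]] = as_value
    return vec


def assemble_features(
    dms: ScoreSet,
    as_sources: list[ASDataset],
    profile: MSAProfile,
    matrix: SubstitutionMatrix,
    as_enabled: bool,
    imputed_mean: float | None = None,
    as_combine: str = "per_source",
    pseudocount: float = 0.5,
    with_targets: bool = True,
) -> list[FeatureRow]:
    """One feature row per missense DMS variant (x matched AS source).

    With ``as_combine="per_source"`` each matched AS dataset contributes its
    own row per variant, carrying that source's score at the variant's
    residue or the global imputed mean; ``"mean"`` collapses the sources
    into a single row per variant.  When ``as_enabled`` is false the AS
    columns are omitted entirely (the control model) and one row per
    variant is emitted.
    """
    if as_enabled and imputed_mean is None:
        raise FeatureError("imputed_mean is required when AS features are enabled")
    if as_combine not in ("per_source", "mean"):
        raise FeatureError(f"unknown as_combine mode {as_combine!r}")
    missense = dms.missense()
    missing = sorted(
        {k.position for k in missense} - set(profile.frequencies)
    )
    if missing:
        raise FeatureError(
            f"profile for {dms.protein_id} lacks positions {missing}"
        )
    rows: list[FeatureRow] = []
    for key in sorted(missense):
        scalars = dict(
            entropy=positional_entropy(profile, key.position),
            log_var_freq=log_variant_frequency(
                profile, key.position, key.var_aa, pseudocount
            ),
            subst_score=matrix.lookup(key.wt_aa, key.var_aa),
            target=missense[key] if with_targets else None,
            dms_id=dms.dataset_id,
        )
        if not as_enabled:
            rows.append(FeatureRow(key=key, **scalars))
            continue
        residue = (key.position, key.wt_aa)
        if as_combine == "per_source" and as_sources:
            for src in as_sources:
                rows.append(FeatureRow(
                    key=key,
                    as_value=src.residues.get(residue, imputed_mean),
                    as_source_id=src.dataset_id,
                    **scalars,
                ))
        else:
            measured = [s.residues[residue] for s in as_sources
                        if residue in s.residues]
            value = float(np.mean(measured)) if measured else imputed_mean
            rows.append(FeatureRow(key=key, as_value=value, **scalars))
    return rows


def design_matrix(rows: list[FeatureRow], as_enabled: bool):
    """Stack feature rows into (X, column names, y, w) numpy arrays."""
    columns = SCALAR_COLUMNS + (AS_COLUMNS if as_enabled else ())
    X = np.empty((len(rows), len(columns)))
    y = np.empty(len(rows))
    w = np.empty(len(rows))
    for i, row in enumerate(rows):
        X[i, 0] = row.entropy
        X[i, 1] = row.log_var_freq
        X[i, 2] = row.subst_score
        if as_enabled:
            if row.as_value is None:
                raise FeatureError(f"row {row.key} lacks an AS value")
            X[i, 3:] = row.as_encoding
        y[i] = np.nan if row.target is None else row.target
        w[i] = row.weight
    return X, list(columns), y, w
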