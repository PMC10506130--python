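"""Pairing DMS datasets with alanine-scanning datasets.

Two strategies are supported.  Compatibility filtering classifies each
DMS/AS assay pair as high / medium / low compatibility from their assay
categories (by default: same category and qualifier -> high; same category,
different qualifier -> medium; different categories -> low; a user rule
table can override any pair).  Correlation matching computes, for every
candidate AS dataset, the Spearman correlation between AS scores and the
DMS scores of the corresponding alanine substitutions, shrinks it by the
small-sample factor (n-1)/(n+1) (the empirical-copula estimator), and keeps
the single best-correlated AS dataset per DMS dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ASDataset, AssayCategory, ScoreSet, VariantKey

LEVELS = ("high", "medium", "low")
_LEVEL_RANK = {"high": 0, "medium": 1, "low": 2}


class MatchingError(ValueError):
    pass


@dataclass(frozen=True)
class MatchedPair:
    dms_id: str
    as_id: str
    compatibility: str
    n_alanine_overlap: int
    rho: float  # Spearman on shared alanine substitutions (nan if n < 2)
    rho_r: float  # regularized: rho * (n-1)/(n+1)


def classify_compatibility(
    dms_category: AssayCategory,
    as_category: AssayCategory,
    rules: dict | None = None,
) -> str:
    """Compatibility level of an assay pair.

    ``rules`` maps ``(dms_value, as_value)`` or, with qualifiers,
    ``((dms_value, dms_qualifier), (as_value, as_qualifier))`` to a level and
    overrides the defaults pairwise.
    """
    if rules:
        qual_key = (
            (dms_category.value, dms_category.qualifier),
            (as_category.value, as_category.qualifier),
        )
        plain_key = (dms_category.value, as_category.value)
        for key in (qual_key, plain_key):
            if key in rules:
                level = rules[key]
                if level not in LEVELS:
                    raise MatchingError(f"unknown compatibility level {level!r}")
                return level
    if dms_category.value != as_category.value:
        return "low"
    if dms_category.qualifier == as_category.qualifier:
        return "high"
    return "medium"


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MatchingError("vectors have different lengths")
    if x.size < 2:
        raise MatchingError(f"need at least 2 observations, got {x.size}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise MatchingError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def regularized_spearman(x, y) -> float:
    """Spearman correlation shrunk by (n-1)/(n+1) to temper small samples."""
    n = len(x)
    return spearman(x, y) * (n - 1) / (n + 1)


def overlap_alanine_scores(
    dms: ScoreSet, as_data: ASDataset
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair AS residue scores with the DMS scores of X->A substitutions.

    Returns (dms_vector, as_vector, n) over the residues present in both;
    empty overlap gives n = 0.
    """
    if dms.protein_id != as_data.protein_id:
        raise MatchingError(
            f"{dms.dataset_id} and {as_data.dataset_id} target different proteins"
        )
    d, a = [], []
    for (pos, wt), as_score in sorted(as_data.residues.items()):
        key = VariantKey(dms.protein_id, pos, wt, "A")
        if key in dms.scores:
            d.append(dms.scores[key])
            a.append(as_score)
    return np.array(d), np.array(a), len(d)


def make_pair(dms: ScoreSet, as_data: ASDataset,
              rules: dict | None = None) -> MatchedPair:
    """Describe one DMS/AS pair: compatibility, overlap, rho, rho_r."""
    d, a, n = overlap_alanine_scores(dms, as_data)
    try:
        rho = spearman(d, a) if n >= 2 else float("nan")
    except MatchingError:
        rho = float("nan")
    rho_r = rho * (n - 1) / (n + 1) if np.isfinite(rho) else float("nan")
    return MatchedPair(
        dms_id=dms.dataset_id,
        as_id=as_data.dataset_id,
        compatibility=classify_compatibility(
            dms.assay_category, as_data.assay_category, rules
        ),
        n_alanine_overlap=n,
        rho=rho,
        rho_r=rho_r,
    )


def filter_by_compatibility(
    dms: ScoreSet,
    candidates: list[ASDataset],
    level: str = "high_only",
    rules: dict | None = None,
) -> list[ASDataset]:
    """Keep AS candidates whose compatibility meets the threshold.

    ``level`` is ``"high_only"`` or ``"high_and_medium"``.
    """
    if level not in ("high_only", "high_and_medium"):
        raise MatchingError(f"unknown threshold {level!r}")
    max_rank = 0 if level == "high_only" else 1
    kept = []
    for cand in candidates:
        compat = classify_compatibility(dms.assay_category, cand.assay_category, rules)
        if _LEVEL_RANK[compat] <= max_rank:
            kept.append(cand)
    return kept


def match_by_correlation(
    dms: ScoreSet,
    candidates: list[ASDataset],
    min_overlap: int = 3,
) -> ASDataset | None:
    """Pick the AS candidate with the highest regularized correlation.

    Candidates with fewer than ``min_overlap`` shared alanine substitutions
    (or undefined correlation) are ineligible.  Ties are broken by larger
    overlap, then lexicographic dataset id.  Returns None when nothing is
    eligible.
    """
    best = None
    best_key = None
    for cand in candidates:
        pair = make_pair(dms, cand)
        if pair.n_alanine_overlap < min_overlap or not np.isfinite(pair.rho_r):
            continue
        key = (-pair.rho_r, -pair.n_alanine_overlap, cand.dataset_id)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best
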