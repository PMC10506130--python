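"""Rescaling DMS and AS scores to a common scale.

Every dataset is mapped affinely so that the wild-type anchor lands at 1 and
the nonsense-like (complete loss of function) anchor at 0:

    s' = (s - s_wt) / (s_wt - s_non) + 1

Anchors are taken from dataset metadata when declared; otherwise the
wild-type score is the median of synonymous variants, and the nonsense-like
score is the median of the worst 1% of missense variants (DMS) or the most
extreme observed score (AS, when the extreme-value rule is enabled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .io_formats import ASDataset, ScoreSet


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationAnchors:
    wt_score: float
    nonsense_like_score: float
    source_wt: str = "declared"  # declared | synonymous_median
    source_non: str = "declared"  # declared | worst_1pct_missense | extreme_value

    def __post_init__(self) -> None:
        if self.wt_score == self.nonsense_like_score:
            raise NormalizationError(
                "wild-type and nonsense-like anchors coincide "
                f"({self.wt_score}); normalization undefined"
            )


def infer_wildtype_score(scoreset: ScoreSet) -> float:
    """Declared wild-type score, else median score of synonymous variants."""
    if scoreset.wt_score is not None:
        return float(scoreset.wt_score)
    syn = sorted(scoreset.synonymous_scores())
    if not syn:
        raise NormalizationError(
            f"{scoreset.dataset_id}: no declared wild-type score and "
            "no synonymous variants"
        )
    n = len(syn)
    mid = n // 2
    return syn[mid] if n % 2 else 0.5 * (syn[mid - 1] + syn[mid])


def infer_nonsense_like_score(scoreset: ScoreSet) -> float:
    """Declared nonsense score, else median of the worst 1% of missense scores.

    With m missense variants, k = ceil(0.01*m) (at least 1) scores farthest
    in the loss-of-function direction are taken; exactly k values are used,
    ties broken by variant key for determinism.
    """
    if scoreset.nonsense_score is not None:
        return float(scoreset.nonsense_score)
    missense = scoreset.missense()
    if not missense:
        raise NormalizationError(
            f"{scoreset.dataset_id}: no missense variants to infer "
            "a nonsense-like anchor from"
        )
    m = len(missense)
    k = max(1, math.ceil(0.01 * m))
    lof_first = scoreset.orientation == "higher_is_functional"
    ranked = sorted(missense.items(), key=lambda kv: (kv[1], kv[0]),
                    reverse=not lof_first)
    worst = sorted(s for _, s in ranked[:k])
    mid = k // 2
    return worst[mid] if k % 2 else 0.5 * (worst[mid - 1] + worst[mid])


def resolve_dms_anchors(scoreset: ScoreSet) -> NormalizationAnchors:
    wt = infer_wildtype_score(scoreset)
    non = infer_nonsense_like_score(scoreset)
    return NormalizationAnchors(
        wt_score=wt,
        nonsense_like_score=non,
        source_wt="declared" if scoreset.wt_score is not None else "synonymous_median",
        source_non="declared" if scoreset.nonsense_score is not None
        else "worst_1pct_missense",
    )


def resolve_as_anchors(asdataset: ASDataset) -> NormalizationAnchors:
    """AS anchors: declared wild type; declared nonsense or extreme value.

    The extreme-value rule returns the dataset score farthest in the
    loss-of-function direction (minimum when higher means more functional).
    """
    if asdataset.wt_score is None:
        raise NormalizationError(f"{asdataset.dataset_id}: no wild-type anchor")
    if asdataset.nonsense_score is not None:
        return NormalizationAnchors(float(asdataset.wt_score),
                                    float(asdataset.nonsense_score))
    if not asdataset.extreme_value_rule:
        raise NormalizationError(
            f"{asdataset.dataset_id}: no nonsense-like anchor and the "
            "extreme-value rule is disabled"
        )
    if not asdataset.residues:
        raise NormalizationError(f"{asdataset.dataset_id}: no scores")
    values = asdataset.residues.values()
    non = min(values) if asdataset.orientation == "higher_is_functional" else max(values)
    return NormalizationAnchors(float(asdataset.wt_score), float(non),
                                source_non="extreme_value")


def _rescale(s: float, anchors: NormalizationAnchors) -> float:
    return (s - anchors.wt_score) / (anchors.wt_score - anchors.nonsense_like_score) + 1.0


def normalize_scores(dataset, anchors: NormalizationAnchors):
    """Return a normalized copy of a :class:`ScoreSet` or :class:`ASDataset`.

    Wild type maps to 1 and the nonsense-like anchor to 0 by construction.
    """
    # after rescaling the functional direction is always upward (wt=1 > non=0)
    if isinstance(dataset, ScoreSet):
        return replace(
            dataset,
            scores={k: _rescale(s, anchors) for k, s in dataset.scores.items()},
            wt_score=1.0, nonsense_score=0.0, normalized=True,
            orientation="higher_is_functional",
        )
    if isinstance(dataset, ASDataset):
        return replace(
            dataset,
            residues={k: _rescale(s, anchors) for k, s in dataset.residues.items()},
            wt_score=1.0, nonsense_score=0.0, normalized=True,
            orientation="higher_is_functional",
        )
    raise TypeError(f"cannot normalize {type(dataset).__name__}")


def normalize_scoreset(scoreset: ScoreSet) -> ScoreSet:
    """Infer DMS anchors and normalize in one step."""
    return normalize_scores(scoreset, resolve_dms_anchors(scoreset))


def normalize_asdataset(asdataset: ASDataset) -> ASDataset:
    """Resolve AS anchors and normalize in one step."""
    return normalize_scores(asdataset, resolve_as_anchors(asdataset))
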