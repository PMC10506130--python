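import numpy as np
import pytest

from dmsfuse.cv_eval import Corpus
from dmsfuse.io_formats import (
    AA_ORDER,
    ASDataset,
    AssayCategory,
    MSAProfile,
    ScoreSet,
    VariantKey,
)


@pytest.fixture
def category():
    return AssayCategory("binding_affinity")


def make_scoreset(
    protein_id="P1",
    dataset_id="d1",
    scores=None,
    category="binding_affinity",
    qualifier=None,
    orientation="higher_is_functional",
    normalized=True,
    **kwargs,
):
    """Score set from {(pos, wt, var): score} shorthand."""
    scores = scores or {}
    keyed = {
        VariantKey(protein_id, pos, wt, var): s
        for (pos, wt, var), s in scores.items()
    }
    return ScoreSet(
        dataset_id=dataset_id,
        protein_id=protein_id,
        assay_category=AssayCategory(category, qualifier),
        orientation=orientation,
        scores=keyed,
        normalized=normalized,
        **kwargs,
    )


def make_as(
    protein_id="P1",
    dataset_id="a1",
    residues=None,
    category="binding_affinity",
    qualifier=None,
    normalized=True,
    **kwargs,
):
    return ASDataset(
        dataset_id=dataset_id,
        protein_id=protein_id,
        assay_category=AssayCategory(category, qualifier),
        residues=dict(residues or {}),
        normalized=normalized,
        **kwargs,
    )


def uniform_profile(protein_id, positions):
    freqs = {pos: np.full(20, 0.05) for pos in positions}
    return MSAProfile(protein_id, freqs, depth=20)


@pytest.fixture
def small_corpus():
    """Two proteins, fully covered positions, deterministic scores."""
    rng = np.random.default_rng(7)
    scoresets, as_sets, profiles = [], [], {}
    for pid, length in (("P1", 8), ("P2", 9)):
        seq = "".join(rng.choice(list(AA_ORDER.replace("A", "")), size=length))
        scores = {}
        for pos in range(1, length + 1):
            for var in AA_ORDER:
                if var == seq[pos - 1]:
                    continue
                scores[(pos, seq[pos - 1], var)] = float(rng.uniform(0, 1))
        scoresets.append(make_scoreset(pid, f"{pid}-dms", scores))
        residues = {
            (pos, seq[pos - 1]): float(rng.uniform(0, 1))
            for pos in range(1, length + 1, 2)
        }
        as_sets.append(make_as(pid, f"{pid}-as", residues))
        profiles[pid] = uniform_profile(pid, range(1, length + 1))
    return Corpus(scoresets, as_sets, profiles)
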