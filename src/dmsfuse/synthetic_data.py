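"""Synthetic corpora with controlled ground truth.

A synthetic protein has a per-position sensitivity in [0, 1] and a
per-substitution exchangeability effect in [0, 1]; the ground-truth
normalized score of variant (pos, wt -> var) is

    1 - sensitivity[pos] * effect[(wt, var)]

so wild-type-like behaviour scores 1 and complete loss of function 0.
DMS datasets observe this truth through a random affine map plus Gaussian
noise (exercising normalization genuinely); alanine-scanning datasets cover
a random residue subset, either derived from the same truth (with
configurable noise, controlling the AS-DMS correlation) or as pure noise.
MSA profiles are built so conserved (low-entropy) columns coincide with
sensitive positions, giving the evolutionary features real signal.

Exchangeability is drawn once per corpus and shared across proteins, so
substitution preferences transfer across leave-one-protein-out folds, as
they do for real proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cv_eval import Corpus
from .io_formats import (
    AA_ORDER,
    ASDataset,
    AssayCategory,
    MSAProfile,
    ScoreSet,
    VariantKey,
)
from .normalization import normalize_asdataset, normalize_scoreset


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n_proteins: int = 6
    length_range: tuple[int, int] = (50, 80)
    dms_per_protein: int = 1
    as_per_protein: int = 1
    as_residue_fraction: float = 0.5
    dms_noise_sd: float = 0.1
    as_noise_sd: float = 0.1
    as_mode: str = "from_truth"  # from_truth | pure_noise
    dms_coverage: float = 1.0
    n_synonymous: int = 10
    msa_depth: int = 100
    # Conservation tracks functional sensitivity only imperfectly in real
    # alignments (assay-specific effects, alignment noise); this jitter on
    # the sensitivity seen by the profile generator models that slack.
    conservation_noise_sd: float = 0.3
    dms_category: str = "binding_affinity"
    as_categories: tuple[str, ...] | None = None  # cycled over AS datasets
    orientation: str = "higher_is_functional"
    declare_anchors: bool = False
    uniform_exchangeability: bool = False  # effect == 1 for every substitution
    exclude_alanine_wt: bool = False  # sequences without alanine residues
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.as_residue_fraction <= 1 and 0 < self.dms_coverage <= 1):
            raise GeneratorError("fractions must lie in [0, 1]")
        if self.dms_noise_sd < 0 or self.as_noise_sd < 0:
            raise GeneratorError("noise standard deviations must be >= 0")
        if self.length_range[0] < 2 or self.length_range[0] > self.length_range[1]:
            raise GeneratorError(f"invalid length range {self.length_range}")
        if self.as_mode not in ("from_truth", "pure_noise"):
            raise GeneratorError(f"unknown as_mode {self.as_mode!r}")


@dataclass
class SyntheticProtein:
    protein_id: str
    length: int
    sequence: str
    position_sensitivity: np.ndarray  # length floats in [0, 1]
    exchangeability: dict[tuple[str, str], float]

    def truth(self, position: int, var_aa: str) -> float:
        """Ground-truth normalized score of (position, wt -> var)."""
        wt = self.sequence[position - 1]
        if var_aa == wt:
            return 1.0
        return 1.0 - self.position_sensitivity[position - 1] * \
            self.exchangeability[(wt, var_aa)]


def draw_exchangeability(rng: np.random.Generator,
                         uniform: bool = False) -> dict[tuple[str, str], float]:
    """Effect scale per ordered amino-acid pair; symmetric-free, in [0.2, 1]."""
    pairs = [(w, v) for w in AA_ORDER for v in AA_ORDER if w != v]
    if uniform:
        return {p: 1.0 for p in pairs}
    values = rng.uniform(0.2, 1.0, size=len(pairs))
    return dict(zip(pairs, values))


def simulate_protein(
    config: GeneratorConfig,
    rng: np.random.Generator,
    protein_id: str = "SYNP1",
    exchangeability: dict | None = None,
) -> SyntheticProtein:
    length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
    alphabet = AA_ORDER.replace("A", "") if config.exclude_alanine_wt else AA_ORDER
    sequence = "".join(rng.choice(list(alphabet), size=length))
    sensitivity = rng.uniform(0.0, 1.0, size=length)
    if exchangeability is None:
        exchangeability = draw_exchangeability(rng, config.uniform_exchangeability)
    return SyntheticProtein(
        protein_id=protein_id,
        length=length,
        sequence=sequence,
        position_sensitivity=sensitivity,
        exchangeability=exchangeability,
    )


def _affine(rng: np.random.Generator, orientation: str) -> tuple[float, float]:
    a = rng.uniform(1.0, 3.0)
    b = rng.uniform(-1.0, 1.0)
    if orientation == "inverted":
        a = -a
    return a, b


def simulate_dms(
    protein: SyntheticProtein,
    config: GeneratorConfig,
    rng: np.random.Generator,
    dataset_id: str = "dms1",
    category: AssayCategory | None = None,
) -> ScoreSet:
    """Raw DMS score set: affine(truth + noise) with synonymous variants.

    Synonymous variants sit near the wild-type anchor; the worst observed
    missense scores form the low tail that exercises the worst-1% nonsense
    anchor inference when anchors are not declared.
    """
    category = category or AssayCategory(config.dms_category)
    a, b = _affine(rng, config.orientation)
    scores: dict[VariantKey, float] = {}
    n_cov = max(2, round(config.dms_coverage * protein.length))
    positions = np.sort(rng.choice(protein.length, size=n_cov, replace=False)) + 1
    for pos in positions:
        wt = protein.sequence[pos - 1]
        for var in AA_ORDER:
            if var == wt:
                continue
            truth = protein.truth(int(pos), var)
            noisy = truth + rng.normal(0.0, config.dms_noise_sd)
            scores[VariantKey(protein.protein_id, int(pos), wt, var)] = a * noisy + b
    syn_positions = rng.choice(positions, size=min(config.n_synonymous, len(positions)),
                               replace=False)
    for pos in syn_positions:
        wt = protein.sequence[pos - 1]
        noisy = 1.0 + rng.normal(0.0, config.dms_noise_sd)
        scores[VariantKey(protein.protein_id, int(pos), wt, "SYNONYMOUS")] = a * noisy + b
    return ScoreSet(
        dataset_id=dataset_id,
        protein_id=protein.protein_id,
        assay_category=category,
        orientation=config.orientation,
        scores=scores,
        wt_score=a * 1.0 + b if config.declare_anchors else None,
        nonsense_score=a * 0.0 + b if config.declare_anchors else None,
    )


def simulate_as(
    protein: SyntheticProtein,
    config: GeneratorConfig,
    rng: np.random.Generator,
    mode: str | None = None,
    dataset_id: str = "as1",
    category: AssayCategory | None = None,
    sensitivity_override: np.ndarray | None = None,
) -> ASDataset:
    """Raw AS dataset on a random residue subset (non-alanine wild types).

    ``from_truth`` draws scores from the ground-truth alanine column plus
    noise; ``pure_noise`` draws independent uniform scores.  A sensitivity
    override emulates a low-compatibility assay measuring a different
    property of the same protein.
    """
    mode = mode or config.as_mode
    category = category or AssayCategory(config.dms_category)
    eligible = [p for p in range(1, protein.length + 1)
                if protein.sequence[p - 1] != "A"]
    if not eligible:
        raise GeneratorError(f"{protein.protein_id}: no non-alanine residues")
    n_sel = round(config.as_residue_fraction * len(eligible))
    n_sel = max(2, min(n_sel, len(eligible)))
    chosen = np.sort(rng.choice(eligible, size=n_sel, replace=False))
    a, b = _affine(rng, config.orientation)
    sens = (sensitivity_override if sensitivity_override is not None
            else protein.position_sensitivity)
    residues: dict[tuple[int, str], float] = {}
    for pos in chosen:
        wt = protein.sequence[pos - 1]
        if mode == "pure_noise":
            residues[(int(pos), wt)] = rng.uniform(0.0, 1.0)
        else:
            truth = 1.0 - sens[pos - 1] * protein.exchangeability[(wt, "A")]
            residues[(int(pos), wt)] = a * (truth + rng.normal(0.0, config.as_noise_sd)) + b
    if mode == "pure_noise":
        wt_anchor, non_anchor = 1.0, 0.0
    else:
        wt_anchor, non_anchor = a * 1.0 + b, a * 0.0 + b
    return ASDataset(
        dataset_id=dataset_id,
        protein_id=protein.protein_id,
        assay_category=category,
        residues=residues,
        wt_score=wt_anchor,
        nonsense_score=non_anchor,
        orientation=config.orientation,
    )


def simulate_msa_profile(
    protein: SyntheticProtein,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> MSAProfile:
    """Profile whose column entropy decreases with position sensitivity."""
    freqs: dict[int, np.ndarray] = {}
    aa_index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for pos in range(1, protein.length + 1):
        sens = protein.position_sensitivity[pos - 1]
        if config.conservation_noise_sd > 0:
            sens = float(np.clip(
                sens + rng.normal(0.0, config.conservation_noise_sd), 0.0, 1.0
            ))
        p_wt = 0.05 + 0.93 * sens  # conserved when sensitive
        rest = rng.dirichlet(np.ones(19)) * (1.0 - p_wt)
        vec = np.empty(20)
        wt_i = aa_index[protein.sequence[pos - 1]]
        others = [i for i in range(20) if i != wt_i]
        vec[wt_i] = p_wt
        vec[others] = rest
        freqs[pos] = vec / vec.sum()
    return MSAProfile(protein.protein_id, freqs, depth=config.msa_depth)


def simulate_corpus(config: GeneratorConfig):
    """Full raw corpus: proteins, DMS sets, AS sets, profiles.

    Deterministic in ``config`` (including the seed).  Returns
    ``(corpus, proteins)`` where the corpus holds raw (unnormalized)
    datasets and ``proteins`` the ground-truth objects keyed by protein id.
    """
    rng = np.random.default_rng(config.seed)
    exchangeability = draw_exchangeability(rng, config.uniform_exchangeability)
    proteins: dict[str, SyntheticProtein] = {}
    scoresets, as_datasets, profiles = [], [], {}
    for i in range(config.n_proteins):
        pid = f"SYNP{i + 1}"
        protein = simulate_protein(config, rng, pid, exchangeability)
        proteins[pid] = protein
        profiles[pid] = simulate_msa_profile(protein, config, rng)
        for j in range(config.dms_per_protein):
            scoresets.append(simulate_dms(
                protein, config, rng, dataset_id=f"{pid}-dms{j + 1}",
            ))
        for j in range(config.as_per_protein):
            if config.as_categories:
                cat = AssayCategory(
                    config.as_categories[j % len(config.as_categories)]
                )
            else:
                cat = AssayCategory(config.dms_category)
            as_datasets.append(simulate_as(
                protein, config, rng, dataset_id=f"{pid}-as{j + 1}", category=cat,
            ))
    return Corpus(scoresets, as_datasets, profiles), proteins


def simulate_normalized_corpus(config: GeneratorConfig):
    """Simulate and normalize in one step (the usual test-time entry point)."""
    corpus, proteins = simulate_corpus(config)
    corpus.scoresets = [normalize_scoreset(s) for s in corpus.scoresets]
    corpus.as_datasets = [normalize_asdataset(a) for a in corpus.as_datasets]
    return corpus, proteins
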