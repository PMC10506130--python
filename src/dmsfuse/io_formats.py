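"""Reading and writing mutational-scan data in plain tabular/FASTA formats.

Scores from deep mutational scanning (DMS) arrive as one row per protein
variant, with the variant written either as an HGVS protein string
(``p.Cys28Trp``) or as explicit wild-type / position / mutant columns.
Alanine-scanning (AS) tables carry one row per assayed residue.  Multiple
sequence alignments come as aligned FASTA (first record = target) or as a
precomputed per-position frequency table.

Positions are 1-based and refer to the target protein sequence.  All
vectors and matrices over amino acids use the fixed alphabetical one-letter
ordering :data:`AA_ORDER`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Canonical amino acids, alphabetical by one-letter code.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ORDER)
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Markers for non-missense variant classes.
SYNONYMOUS = "SYNONYMOUS"
NONSENSE = "NONSENSE"

THREE_TO_ONE = {
    "Ala": "A", "Cys": "C", "Asp": "D", "Glu": "E", "Phe": "F",
    "Gly": "G", "His": "H", "Ile": "I", "Lys": "K", "Leu": "L",
    "Met": "M", "Asn": "N", "Pro": "P", "Gln": "Q", "Arg": "R",
    "Ser": "S", "Thr": "T", "Val": "V", "Trp": "W", "Tyr": "Y",
}

ASSAY_CATEGORIES = frozenset({
    "binding_affinity", "enzyme_activity", "protein_abundance",
    "cell_survival", "pathogen_infection", "drug_response",
    "novel_function", "other_specific",
})


class FormatError(ValueError):
    """Raised for malformed input files or variant strings."""


@dataclass(frozen=True)
class AssayCategory:
    """Functional assay class, optionally qualified (e.g. ligand identity)."""

    value: str
    qualifier: str | None = None

    def __post_init__(self) -> None:
        if self.value not in ASSAY_CATEGORIES:
            raise FormatError(
                f"unknown assay category {self.value!r}; "
                f"expected one of {sorted(ASSAY_CATEGORIES)}"
            )


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single amino-acid substitution (or synonymous / nonsense marker)."""

    protein_id: str
    position: int
    wt_aa: str
    var_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")
        if self.wt_aa not in AA_SET:
            raise FormatError(f"non-canonical wild-type amino acid {self.wt_aa!r}")
        if self.var_aa in (SYNONYMOUS, NONSENSE):
            return
        if self.var_aa not in AA_SET:
            raise FormatError(f"non-canonical variant amino acid {self.var_aa!r}")
        if self.var_aa == self.wt_aa:
            raise FormatError(
                f"variant equals wild-type at position {self.position}; "
                "use the synonymous form"
            )

    @property
    def is_missense(self) -> bool:
        return self.var_aa in AA_SET


@dataclass
class ScoreSet:
    """One DMS dataset: variant -> raw (or normalized) functional score."""

    dataset_id: str
    protein_id: str
    assay_category: AssayCategory
    orientation: str  # "higher_is_functional" | "inverted"
    scores: dict[VariantKey, float]
    wt_score: float | None = None
    nonsense_score: float | None = None
    normalized: bool = False
    study_id: str | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_is_functional", "inverted"):
            raise FormatError(f"unknown orientation {self.orientation!r}")
        for key in self.scores:
            if key.protein_id != self.protein_id:
                raise FormatError(
                    f"variant {key} does not belong to protein {self.protein_id}"
                )
        if self.study_id is None:
            self.study_id = self.dataset_id

    def missense(self) -> dict[VariantKey, float]:
        return {k: s for k, s in self.scores.items() if k.is_missense}

    def synonymous_scores(self) -> list[float]:
        return [s for k, s in self.scores.items() if k.var_aa == SYNONYMOUS]


@dataclass
class ASDataset:
    """One alanine-scanning dataset: (position, wt_aa) -> substitution score."""

    dataset_id: str
    protein_id: str
    assay_category: AssayCategory
    residues: dict[tuple[int, str], float]
    wt_score: float | None = None
    nonsense_score: float | None = None
    extreme_value_rule: bool = False
    orientation: str = "higher_is_functional"
    normalized: bool = False
    study_id: str | None = None

    def __post_init__(self) -> None:
        for pos, wt in self.residues:
            if wt == "A":
                raise FormatError(
                    f"residue {pos} has wild-type alanine; "
                    "alanine-to-alanine is not a substitution"
                )
            if wt not in AA_SET or pos < 1:
                raise FormatError(f"invalid residue ({pos}, {wt!r})")
        if self.study_id is None:
            self.study_id = self.dataset_id


@dataclass
class MSAProfile:
    """Per-position amino-acid frequencies from a multiple sequence alignment."""

    protein_id: str
    frequencies: dict[int, np.ndarray]  # position -> 20-vector in AA_ORDER
    depth: int

    def __post_init__(self) -> None:
        for pos, vec in self.frequencies.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (20,) or (vec < 0).any():
                raise FormatError(f"invalid frequency vector at position {pos}")
            if not np.isclose(vec.sum(), 1.0, atol=1e-6):
                raise FormatError(
                    f"frequencies at position {pos} sum to {vec.sum():.6f}, not 1"
                )
            self.frequencies[pos] = vec


# --- variant string parsing -------------------------------------------------

_ONE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z]|=|\*)$")
_THREE = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|=|\*)$")


def parse_variant(variant_string: str, protein_id: str) -> VariantKey:
    """Parse an HGVS-style protein substitution into a :class:`VariantKey`.

    Accepts three-letter (``p.Cys28Trp``) and one-letter (``C28W``) forms;
    ``=`` marks a synonymous variant and ``Ter``/``*`` a nonsense variant.
    Multi-substitution strings are rejected.
    """
    s = variant_string.strip()
    m = _ONE.match(s)
    if m:
        wt, pos, var = m.group(1), int(m.group(2)), m.group(3)
    else:
        m = _THREE.match(s)
        if not m:
            raise FormatError(f"unparseable variant string {variant_string!r}")
        wt3, pos, var3 = m.group(1), int(m.group(2)), m.group(3)
        if wt3 not in THREE_TO_ONE:
            raise FormatError(f"unknown amino-acid code {wt3!r}")
        wt = THREE_TO_ONE[wt3]
        if var3 == "=":
            var = "="
        elif var3 == "Ter":
            var = "*"
        elif var3 in THREE_TO_ONE:
            var = THREE_TO_ONE[var3]
        else:
            raise FormatError(f"unknown amino-acid code {var3!r}")
    if var == "=":
        var_aa = SYNONYMOUS
    elif var == "*":
        var_aa = NONSENSE
    else:
        var_aa = var
    return VariantKey(protein_id=protein_id, position=pos, wt_aa=wt, var_aa=var_aa)


def format_variant(key: VariantKey) -> str:
    """One-letter HGVS-style rendering, the inverse of :func:`parse_variant`."""
    if key.var_aa == SYNONYMOUS:
        suffix = "="
    elif key.var_aa == NONSENSE:
        suffix = "*"
    else:
        suffix = key.var_aa
    return f"p.{key.wt_aa}{key.position}{suffix}"


# --- tabular readers --------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise FormatError(f"empty file: {path}")
    return df


def read_scoreset(path, metadata: dict) -> ScoreSet:
    """Read a DMS score set from CSV/TSV.

    The file must carry either a ``variant`` column (HGVS protein strings)
    or ``wt``, ``pos``, ``mut`` columns, plus a numeric ``score`` column.
    ``metadata`` supplies ``dataset_id``, ``protein_id``, ``assay_category``,
    ``orientation`` and optional anchors; ``merge_policy`` may be ``"error"``
    (default) or ``"mean"`` for duplicated variants.
    """
    df = _read_table(path)
    if "score" not in df.columns:
        raise FormatError(f"{path}: missing required 'score' column")
    protein_id = metadata["protein_id"]
    if "variant" in df.columns:
        keys = [parse_variant(v, protein_id) for v in df["variant"]]
    elif {"wt", "pos", "mut"}.issubset(df.columns):
        keys = []
        for wt, pos, mut in zip(df["wt"], df["pos"], df["mut"]):
            mut = str(mut)
            if mut in ("=", SYNONYMOUS):
                var = SYNONYMOUS
            elif mut in ("*", "Ter", NONSENSE):
                var = NONSENSE
            else:
                var = mut
            keys.append(VariantKey(protein_id, int(pos), str(wt), var))
    else:
        raise FormatError(
            f"{path}: need a 'variant' column or 'wt','pos','mut' columns"
        )
    scores_raw = pd.to_numeric(df["score"], errors="coerce")
    n_dropped = int(scores_raw.isna().sum())
    merge_policy = metadata.get("merge_policy", "error")
    scores: dict[VariantKey, list[float]] = {}
    for key, score in zip(keys, scores_raw):
        if pd.isna(score):
            continue
        scores.setdefault(key, []).append(float(score))
    dupes = [k for k, v in scores.items() if len(v) > 1]
    if dupes and merge_policy == "error":
        raise FormatError(
            f"{path}: duplicate variants {sorted(format_variant(k) for k in dupes)} "
            "and no merge policy configured"
        )
    if merge_policy not in ("error", "mean"):
        raise FormatError(f"unknown merge policy {merge_policy!r}")
    merged = {k: float(np.mean(v)) for k, v in scores.items()}
    category = metadata["assay_category"]
    if not isinstance(category, AssayCategory):
        category = AssayCategory(**category) if isinstance(category, dict) else AssayCategory(category)
    return ScoreSet(
        dataset_id=metadata.get("dataset_id", str(path)),
        protein_id=protein_id,
        assay_category=category,
        orientation=metadata.get("orientation", "higher_is_functional"),
        scores=merged,
        wt_score=metadata.get("wt_score"),
        nonsense_score=metadata.get("nonsense_score"),
        study_id=metadata.get("study_id"),
        n_dropped=n_dropped,
    )


def write_scoreset(scoreset: ScoreSet, path) -> None:
    """Write variants and scores as CSV (``variant,score``), sorted by key."""
    rows = sorted(scoreset.scores.items())
    df = pd.DataFrame(
        {"variant": [format_variant(k) for k, _ in rows],
         "score": [f"{s:.17g}" for _, s in rows]}
    )
    df.to_csv(path, index=False)


def read_as_table(path, metadata: dict) -> ASDataset:
    """Read an alanine-scanning table (columns ``pos``, ``wt``, ``score``)."""
    df = _read_table(path)
    missing = {"pos", "wt", "score"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    residues: dict[tuple[int, str], float] = {}
    for pos, wt, score in zip(df["pos"], df["wt"], df["score"]):
        score = pd.to_numeric(score, errors="coerce")
        if pd.isna(score):
            raise FormatError(f"{path}: non-numeric score at residue {pos}")
        key = (int(pos), str(wt))
        if key in residues:
            raise FormatError(f"{path}: duplicate residue {key}")
        residues[key] = float(score)
    category = metadata["assay_category"]
    if not isinstance(category, AssayCategory):
        category = AssayCategory(**category) if isinstance(category, dict) else AssayCategory(category)
    return ASDataset(
        dataset_id=metadata.get("dataset_id", str(path)),
        protein_id=metadata["protein_id"],
        assay_category=category,
        residues=residues,
        wt_score=metadata.get("wt_score"),
        nonsense_score=metadata.get("nonsense_score"),
        extreme_value_rule=metadata.get("extreme_value_rule", False),
        orientation=metadata.get("orientation", "higher_is_functional"),
        study_id=metadata.get("study_id"),
    )


def write_as_table(as_data: ASDataset, path) -> None:
    rows = sorted(as_data.residues.items())
    df = pd.DataFrame(
        {"pos": [p for (p, _), _ in rows],
         "wt": [w for (_, w), _ in rows],
         "score": [f"{s:.17g}" for _, s in rows]}
    )
    df.to_csv(path, sep="\t", index=False)


# --- MSA profiles -----------------------------------------------------------

def read_msa_profile(path, protein_id: str | None = None) -> MSAProfile:
    """Build an :class:`MSAProfile` from aligned FASTA or a frequency table.

    For FASTA the first record is the target; alignment columns that are a
    gap in the target are skipped so positions index the ungapped target
    sequence.  Gaps and non-canonical symbols in other sequences are excluded
    from the counts before renormalization.  A TSV with a ``pos`` column and
    one column per amino acid is accepted as a precomputed alternative.
    """
    path = str(path)
    if path.endswith((".tsv", ".tab", ".csv")):
        df = _read_table(path)
        if "pos" not in df.columns or not set(AA_ORDER).issubset(df.columns):
            raise FormatError(f"{path}: frequency table needs 'pos' + 20 aa columns")
        depth = int(df["depth"].iloc[0]) if "depth" in df.columns else 1
        freqs = {
            int(row["pos"]): np.array([row[aa] for aa in AA_ORDER], dtype=float)
            for _, row in df.iterrows()
        }
        return MSAProfile(protein_id or path, freqs, depth)

    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FormatError(f"{path}: empty alignment")
    target = str(records[0].seq).upper()
    if all(c == "-" for c in target):
        raise FormatError(f"{path}: target sequence contains only gaps")
    columns = [str(r.seq).upper() for r in records]
    freqs: dict[int, np.ndarray] = {}
    pos = 0
    for col_idx, target_char in enumerate(target):
        if target_char == "-":
            continue
        pos += 1
        counts = np.zeros(20)
        for seq in columns:
            aa = seq[col_idx]
            if aa in AA_INDEX:
                counts[AA_INDEX[aa]] += 1
        total = counts.sum()
        if total > 0:
            freqs[pos] = counts / total
    return MSAProfile(protein_id or records[0].id, freqs, depth=len(records))


def write_msa_profile(profile: MSAProfile, path) -> None:
    rows = []
    for pos in sorted(profile.frequencies):
        row = {"pos": pos, "depth": profile.depth}
        row.update(
            {aa: f"{f:.17g}" for aa, f in zip(AA_ORDER, profile.frequencies[pos])}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_predictions(rows: list[tuple[str, VariantKey, float]], path) -> None:
    """Write ``protein_id,variant,predicted_score`` CSV."""
    df = pd.DataFrame(
        {"protein_id": [p for p, _, _ in rows],
         "variant": [format_variant(k) for _, k, _ in rows],
         "predicted_score": [s for _, _, s in rows]}
    )
    df.to_csv(path, index=False)
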