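# Methods

## Normalization

Each dataset (DMS or AS) is rescaled affinely, `s' = (s - s_wt)/(s_wt -
s_non) + 1`, mapping the wild-type anchor to 1 and the nonsense-like anchor
to 0. Anchor resolution:

- wild type: declared value if the study reports one, else the median of
  synonymous-variant scores;
- DMS nonsense-like: declared value, else the median of the `k =
  ceil(0.01·m)` missense scores (floor 1) farthest in the loss-of-function
  direction, where `m` is the missense count. The direction comes from the
  per-dataset `orientation` flag (`higher_is_functional` or `inverted`).
  Ties at the cutoff are resolved by taking exactly `k` values in sorted
  order with a stable tie-break on the variant key;
- AS nonsense-like: declared value, else (when the extreme-value rule is
  enabled) the most extreme observed score in the loss-of-function
  direction.

Normalization is affine-invariant (any `a·s + b` applied to both data and
anchors gives identical output), idempotent at anchors (1, 0), and flips
inverted assays so the normalized scale is always higher-is-functional.

## Matching

Assay pairs are classified high / medium / low compatibility. The default
rule is: same assay category and qualifier → high; same category,
different qualifier (e.g. two different ligands) → medium; different
categories → low. Any pair can be overridden by a user rule table, so an
expert-curated decision tree is expressible as data. The alternative
strategy computes Spearman's ρ between AS scores and the DMS scores of the
corresponding X→A variants, shrinks it by `(n-1)/(n+1)` (the
empirical-copula estimator; `n` = shared alanine substitutions), and keeps
the single AS dataset with the highest regularized value per DMS dataset.
Correlation matching requires a minimum overlap (default 3 residues, the
same floor used when reporting pairwise correlations); ties go to the
larger overlap, then the lexicographically smaller dataset id.

## Features

- **Positional entropy** `H = -Σ p_a ln p_a` (nats) over the 20 canonical
  amino acids of the MSA column. Natural log; the base only rescales one
  linear coefficient.
- **Log variant frequency** `ln((count + c)/(depth + 20c))` with
  pseudocount `c = 0.5` by default (configurable); counts are recovered as
  frequency × alignment depth. Profiles are computed from an aligned FASTA
  (first record = target; columns that are target gaps are skipped; gaps
  and non-canonical symbols excluded before renormalization) or read from
  a precomputed frequency table.
- **Substitution score**: the mean normalized training DMS score per
  ordered (wt, var) pair — up to 380 entries — rebuilt from the training
  fold only, before every cross-validation iteration. Pairs unobserved in
  training fall back to the global training mean (with a full corpus all
  380 pairs are observed and the fallback is never used).
- **AS encoding**: two 20-blocks in fixed alphabetical order
  (A C D E F G H I K L M N P Q R S T V W Y); block 1 carries the AS score
  at the wild-type amino acid's index, block 2 at the variant's; the other
  38 entries are exactly zero. Variants at residues without a matched AS
  measurement receive the global mean of all available AS scores. By
  default that mean is computed over the *training fold's* matched AS
  datasets, which avoids information flowing from the held-out protein;
  `imputation_scope="all_studies"` computes it over every matched study
  instead. Residues whose wild type is alanine can never carry an AS
  measurement and are always imputed.

When one DMS dataset matches several AS studies, each study contributes
its own feature row per variant (`as_combine="per_source"`), and
evaluation is per (DMS, AS) pair; `as_combine="mean"` averages the sources
instead.

## Model

Weighted ordinary least squares with intercept, no regularization. Row
weights are `1 / (number of training rows for the identical variant)`,
the key including the protein, so every distinct variant contributes unit
total weight regardless of how many datasets or AS sources cover it. The
fit is closed-form (lstsq) and deterministic.

The AS encoding makes the design rank-deficient by exactly one dimension
(each 20-block sums to the AS value per row); additionally, an amino acid
absent from a small training corpus leaves its column identically zero.
Both deficiencies are benign — predictions live in the column span and the
minimum-norm solution is unique and deterministic — so the fit tolerates
them and raises only on any further collinearity, reporting the singular
columns.

## Cross-validation and evaluation

Leave-one-protein-out: every dataset (DMS and AS) of one protein is
withheld per fold; the substitution matrix and the AS imputation mean are
rebuilt from the remaining data only. Two models are fitted per fold, with
and without the AS columns. For each (DMS, AS) pair of the held-out
protein, the evaluation variant set `V` contains all missense DMS variants
whose residue carries an AS measurement — residue-level matching, not just
the X→A substitutions (the alanine-only reading is available via
`alanine_only_eval`). Reported per pair: `ρ_V^A` (with AS), `ρ_V`
(without), `Δρ_V = ρ_V^A − ρ_V`, and the Spearman correlation between the
observed DMS scores and the AS score at each variant's residue (the
score-correlation axis). Pairs with ≤ 1 distinct residue, < 2 variants, or
constant vectors (undefined correlation) are counted and excluded.
Optional replicate merging averages normalized scores across datasets from
the same study and assay category before the run.

Statistics: two-sided Welch unequal-variance t-tests between strategies,
two-sided paired t-tests of Δρ against zero, Holm–Šidák step-down
correction of p-value families, and the Gaussian asymptotic CI for medians
via order-statistic ranks `n/2 ± z√n/2` (z = 1.96 at 95%, rounded half away
from zero, clipped to [1, n]). All tests are two-sided. Per-amino-acid
tables pool variant-level predictions across pairs and report ρ with and
without AS per wild-type group (alanine marked not applicable) and per
variant group; groups under 2 variants are dropped.

## Synthetic data

The generator draws, per corpus, a shared exchangeability table
`effect(wt, var) ∈ [0.2, 1]` (shared across proteins so substitution
preferences transfer across folds) and, per protein, a random sequence and
per-position sensitivity `∈ [0, 1]`. Ground-truth normalized scores are
`1 − sensitivity[pos]·effect(wt, var)`. Observed data are built on top:

- **DMS**: truth + Gaussian noise (sd 0.1 by default), passed through a
  random affine map per dataset (scale 1–3, offset ±1, sign flipped for
  inverted assays) so normalization is genuinely exercised; synonymous
  variants near the wild-type anchor are included, and the low tail of
  missense scores exercises the worst-1% anchor rule.
- **AS**: a uniform random subset of non-alanine residues (default 50% —
  generous relative to real scans but enough residues to evaluate pairs on
  short test proteins); scores are the ground-truth alanine column plus
  noise (`as_noise_sd` controls the AS–DMS correlation) or pure uniform
  noise. A sensitivity override simulates a low-compatibility assay
  measuring an unrelated property of the same protein.
- **MSA profiles**: wild-type frequency `0.05 + 0.93·sens`, remainder
  Dirichlet-spread, so conserved columns coincide with sensitive
  positions. Conservation tracks sensitivity only through a noisy channel
  (`conservation_noise_sd = 0.3` by default) because real alignments
  reflect assay-specific functional sensitivity imperfectly; with a
  noiseless channel the evolutionary features alone nearly saturate
  prediction and the AS feature has nothing left to add, which is not how
  real corpora behave.

Default corpus for the Δρ experiments: 4 proteins of 40–50 residues, one
DMS and one AS dataset each — small enough that a 50-seed, 4-condition
sweep runs in about a minute, large enough that each fold fits a 43-column
model on ~2,500 rows. What passing these tests shows is that the pipeline
extracts the AS signal when it exists and is honest when it does not; the
generator does not model epistasis, sequencing-count noise, position
correlation along the chain, or the idiosyncrasies of specific proteins,
so absolute ρ values on synthetic corpora do not transfer to real data.

## Numerical choices and degenerate inputs

- Fixed amino-acid ordering everywhere: alphabetical one-letter codes.
- Positions are 1-based and refer to the ungapped target sequence.
- Duplicate variant rows within one file are an error unless the
  per-dataset merge policy is set to `mean` (how published score sets
  handled internal duplicates is generally unstated, so the default is
  conservative).
- Spearman correlation is undefined for n < 2 or constant vectors; such
  pairs are excluded and counted rather than imputed.
- Correlation matching and evaluation operate on normalized scores; ranks
  are affine-invariant, so this matches raw-score behaviour within a
  dataset.
- Multi-substitution HGVS strings are rejected; only single amino-acid
  substitutions, synonymous (`=`) and nonsense (`Ter`/`*`) forms are
  parsed.

## Known limitations

- The compatibility rule table defaults to a category/qualifier heuristic;
  expert curation of specific assay pairs should be supplied as a rule
  file.
- Mean imputation of missing AS scores ignores the uneven coverage of AS
  data; the `as_covered_only` training subset and the DMS-alanine feature
  source are provided as ablations, not improvements.
- The model is linear by design; no interactions, no regularization, no
  nonlinear effects.
- Headline numbers from real curated corpora (e.g. median pairwise
  DMS/AS correlations by compatibility class) require those corpora;
  synthetic results here establish behaviour, not absolute values.
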