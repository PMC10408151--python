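# Methods

This note documents the models and procedures implemented in `cptransfer`,
the conventions and numerical choices behind them, and what the synthetic
fixtures do and do not establish about real data.

## Problem setting

A missense variant is identified by gene, 1-based residue position on the
canonical protein sequence, and wild-type/mutant amino acids. The package
predicts either a continuous functional assay score or the probability that
a variant is functionally abnormal, training only on deep mutational
scanning (DMS) data from a small set of proteins and transferring to
proteins never seen in training. Scores are oriented so that higher model
output means more pathogenic/abnormal.

## Feature definitions

**Alignment frequencies.** For each variant and each shallow alignment
source (a ~100-vertebrate and a ~30-mammal query-anchored alignment), the
wild-type, mutant and gap frequencies at the variant's column are computed
and transformed as log(1 + f). Conventions:

- The denominator is the number of alignment rows *including* the human
  query row, so the wild-type frequency is always positive. The literal
  reading of "frequency at the position" supports either convention; the
  query-exclusive variant is available via `include_query=False`.
- The log offset is applied to the [0, 1] frequency, not to counts, giving
  the range [0, ln 2]. It is strictly monotone, so variant orderings are
  preserved.
- Nonstandard residues and ambiguity codes count toward the denominator but
  never toward wild-type/mutant counts — a conservative, deterministic rule
  for letters whose identity is unknown.
- A related boolean feature records whether the mutant residue appears in
  any *non-query* row at the position (observation of the allele as another
  species' reference residue is strong evidence of benignity).

**Isoform reconciliation.** When the alignment was built on a different
isoform, its ungapped query is locally aligned to the canonical sequence
with affine gaps (match +5, mismatch −4, gap open −4, gap extend −0.5,
via Biopython's PairwiseAligner). Aligned blocks define a column map;
canonical positions outside the aligned fragment are flagged missing and
later imputed. A best local score ≤ 0 flags the whole gene missing rather
than raising — absence of homology is data, not an error.

**Structure-conditioned scores.** Sidechain–sidechain contacts come either
from a precomputed list or from a distance fallback: residues are in
contact when any two sidechain heavy atoms are within 4.5 Å. Glycine has no
sidechain heavy atoms and never forms contacts in fallback mode (a
documented divergence from dot-surface contact software, whose lists can be
supplied precomputed for fidelity). For each position, conditioning
residues are its contacts with pLDDT > 70, ranked by the frequency of the
human residue at the contact column in the deep family alignment; at most
two are used, and a position whose own pLDDT is ≤ 70 gets none. The deep
alignment is filtered to rows matching the human residue at every
conditioning position, and the variant's wild-type/mutant frequencies in
the filtered rows are log-offset transformed. If fewer than
`min_filtered_rows` (default 1) rows survive, the scores are missing and
flow to cross-gene imputation. With an empty conditioning list the scores
equal the unconditioned column frequencies exactly. Ties in the frequency
ranking break toward the lower residue index; fragment structures resolve
per position to the fragment with maximal pLDDT there, ties to the lower
fragment id.

**External predictor adapters.** Precomputed log-probability columns are
normalized as log p(mut) − log p(wt); non-finite inputs become missing.
Density-model log-probabilities are passed through unchanged (not rescaled
to [0, 1]). For proteins beyond a model's direct context limit (1022
residues), scores are computed in 1000-residue windows with starts 250
apart; the final window is right-aligned to end at the C-terminus so the
tail keeps full context (the stride rule alone leaves the tail handling
open; right alignment is the package's choice and is configurable). Each
variant takes the score from the covering window whose center — the
half-integer midpoint for even-length windows — is nearest its position,
ties to the earlier window.

**Descriptor deltas.** Component-wise mutant-minus-wild-type differences of
amino-acid scales. Two published tables are bundled (five-component
Z-scales; hydropathy/volume/pI); any 20-row CSV can be supplied.

## Weighted KNN imputation

For one target column in one gene: helpers are the five columns with
highest |Spearman ρ| against the target over mutually observed rows
(zero-variance columns are excluded; an undefined ρ counts as 0). Helpers
are standardized and multiplied by |ρ|; the target is standardized with
weight 1. The sign of ρ is irrelevant to Euclidean geometry, so |ρ| and
signed weights give identical distances; the signed option exists for
auditability. Distances are NaN-aware Euclidean: squared differences over
mutually observed dimensions, rescaled by total/observed dimension count.
Each missing cell takes the unweighted mean of the target values of the 10
nearest observed rows (uniform averaging, matching the referenced KNN
imputer's default); distance ties at the boundary admit the lower row
index. Fitting requires at least `n_neighbors + 1` observed target values
in the gene; otherwise the caller falls back to cross-gene imputation, in
which imputers fitted on each training gene predict the column from the
helper features (helper standardization statistics are reused from the
fitting gene) and the per-imputer predictions are averaged. Imputed values
are always within the range of observed target values.

## Transfer model

One linear model per training protein, ensembled by averaging predictions
at test time. Per-protein fitting is the mechanism that absorbs affine
batch effects in assay score distributions across proteins.

- **Binarization (classification).** Scores are ranked ascending with a
  stable sort; the bottom ⌊0.4 n⌋ variants are labeled functionally
  abnormal (1), the top ⌊0.4 n⌋ normal (0), the middle discarded. Stable
  ordering makes counts exact under arbitrary ties. The fractions are
  configurable; downstream results are insensitive to the exact threshold.
- **Rescaling.** Features are divided by a weighted standard deviation in
  which every row of protein *p* carries weight 1/n_p, so each protein
  contributes equally regardless of size. Features are not mean-centered
  (per-protein intercepts absorb location). Frequency-flagged columns —
  the alignment frequencies and the conditioned scores, all log-offset
  frequencies on [0, ln 2] — keep scale 1.
- **Fitting.** Classification uses logistic regression per protein on the
  binarized labels; regression uses least squares on raw assay scores. A
  tiny ridge penalty (10⁻⁶) stabilizes collinear features; tests comparing
  against closed-form least squares set it to 0. Proteins left with a
  single class after binarization are excluded with a warning.
- **Ensembling.** Classification averages predicted probabilities by
  default (log-odds averaging is a config switch — the averaging scale is
  genuinely open); regression averages linear predictions. Prediction
  requires a fully imputed table; missing cells raise with a pointer to
  imputation.
- **Feature selection.** Leave-one-protein-out folds (each protein
  validates exactly once); the metric is mean held-out AUROC
  (classification) or Spearman (regression). Selection always starts from
  the two homology score columns, then walks the fixed category order
  (100-vertebrate, 30-mammal, inverse-folding, conditioned scores),
  choosing per non-empty category the best non-empty subset by exhaustive
  search, then adds descriptor features greedily while the metric strictly
  improves. Subsets are enumerated in a fixed order and ties keep the
  earliest candidate, so selection is deterministic given the data.

Models serialize to versioned JSON with explicit feature names, scale
vector and per-protein coefficients — no binary pickles.

## Evaluation

AUROC uses the rank/Mann–Whitney formulation (ties count ½). Specificity
at sensitivity *s* uses the most stringent threshold achieving sensitivity
≥ *s* (calls are "score ≥ threshold"); the ≥ convention, rather than
nearest-point interpolation, is the package's fixed choice. Per-gene AUROC
is restricted to genes with at least four variants of each class. All rank
metrics are invariant under strictly monotone transforms of the scores.

## Synthetic family generator

The generator emulates the full input universe at desk scale: six genes of
60–90 residues (five train/one held out in LOPO), 100/30-row shallow
alignments, a 200-row deep alignment, contacts from a compact random 3D
chain with confidence high in contact-dense regions, external predictor
columns, per-gene DMS tables (300 variants) and 200 labeled variants per
gene. A per-variant latent fitness is a fixed linear function of the
standardized feature columns; external predictor columns are noisy
monotone functions of the core (non-predictor) part of that latent; DMS
scores are per-protein affine transforms of the latent plus Gaussian noise
(default 20% of the latent SD); labels threshold the noise-free latent at
its 40th percentile. Default missingness mimics real failure modes: ~15%
of density-model scores unavailable and a ~10% unaligned N-terminal
isoform region in the vertebrate alignment. The noise-free configuration
(`GeneratorConfig.noise_free`) additionally sets the missingness fractions
to 0, because exact linear recovery of the generative coefficients is only
defined when the features the model sees are the features the scores were
built from; the default family keeps missingness so imputation is
exercised end to end. All randomness flows from a single seeded generator;
identical seeds give byte-identical fixture trees.

What passing tests on this generator show: the pipeline's bookkeeping,
imputation, per-protein fitting and ensembling recover a known linear
generative process exactly in the noise-free limit and robustly under
noise and batch effects. What they do not show: performance on real
proteins — the generator's alignments are phylogenetically unstructured
(independent rows, no tree), its structures are not biophysical, its
latent is genuinely linear in the features, and its external scores are
far better behaved than real predictor outputs. Real-data performance
claims require real alignments, structures and assay data.

## Problem sizes and runtime

Defaults were chosen so the whole test suite and the acceptance script run
in well under a minute each on one CPU: 6 genes × 400 variants for the
family, 200 random tables for the imputation oracle sweep, a 3000-residue
protein for window stitching, 500 random vectors for the metric oracles.
These sizes are the package's own desk-scale study conditions, not
statements about the scale the method supports.

## Known limitations

- The distance-fallback contact definition is not a dot-surface method;
  precomputed contact lists should be preferred when available.
- Cross-gene imputation assumes helper columns are comparable across genes
  after per-gene standardization of the fitting gene; genes with radically
  different feature distributions will impute poorly.
- The exhaustive subset search is exponential in per-category feature
  counts; it is intended for the small, curated candidate lists the method
  uses (≤ ~10 features per category).
- Logistic sub-models use a large-C (effectively unregularized) fit; with
  perfectly separable binarized data coefficients are capped only by the
  solver's iteration limit.
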