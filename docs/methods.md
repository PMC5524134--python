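# Methods

## Model

`mhcmotif` treats peptide:MHC class I binding as additive over peptide
positions on a log-affinity scale. For a peptide *p* of length *L*,

  log10(IC50) ≈ b + Σ_k W[r_k, k],

where *W* is a 20×*L* scoring matrix (rows in the fixed order
ACDEFGHIKLMNPQRSTVWY), *r_k* the residue at position *k*, and *b* an
intercept. Lower entries mean stronger binding. The additive model
ignores intra-peptide residue coupling; that is a deliberate trade:
matrices are directly interpretable position by position, which is what
the motif representation needs.

### Training

Peptides are one-hot encoded (position-major blocks of 20 indicator
columns) into a design matrix *H*, and affinities transformed to
y = log10(clamp(IC50, 0.1, 50000)). The clamp reflects the dynamic
range of competition binding assays and keeps extreme reported values
from dominating the squared loss. *W* and *b* minimize

  ‖H W + b·1 − y‖² + λ‖W‖²,

with the intercept unpenalized. Because every row of *H* sums to *L*,
the one-hot design is rank-deficient (per-column offsets trade against
the intercept); the ridge term makes the solution unique and damps
assay noise. The solver centers *H* and *y* — which solves the
unpenalized-intercept problem exactly — and eigendecomposes the
centered Gram matrix once per data split, so sweeping the entire λ grid
costs one factorization rather than one solve per λ. Tests verify the
solver against a dense solve of the joint normal equations and against
an established independent ridge implementation.

λ is chosen by *k*-fold cross-validation (default 5 folds, shuffled
with a fixed seed; grid 10⁻³…10², decades). The selected λ minimizes
mean squared validation error; the model is then refit on all data.
Identical seeds give identical folds, λ and matrices.

### Motif rules

* **Spread factor** per column: SF = max − min, the log10 fold-change
  between best and worst residue at that position. All downstream rules
  use only within-column differences, so motifs are invariant to
  per-column constant shifts (and to the intercept convention).
* **Anchors**: SF ≥ `sf_abs` (default 1.0 = 10-fold) and
  SF ≥ `sf_rel` × max-column-SF (default 0.5). Both boundaries are
  closed. The absolute floor encodes "this position matters at least
  10-fold"; the relative gate suppresses moderately spread columns in
  matrices dominated by one or two strong anchors. There is no cap on
  anchor count.
* **Anchor residue classes**: measured from the best (minimum) value;
  within `delta_pref` = 0.5 → preferred, within `delta_tol` = 1.0 →
  tolerated, beyond → deleterious (≈ 3-fold and 10-fold of the best
  residue). The best residue is always preferred by construction. A
  flat column cannot be classified as an anchor and raises.
* **Non-anchor classes**: referenced to the column median (for 20
  values, the mean of the 10th and 11th order statistics); at least
  `delta_del` = 0.5 above the median → deleterious, at least
  `delta_pref_nonanchor` = 0.5 below → preferred, otherwise tolerated.
  Boundary ties resolve toward the more informative class (closed ≥
  comparisons).

These four thresholds plus the two anchor gates are the heuristic core
of motif calling; all are exposed in `MotifConfig` (and the pipeline
config / CLI flags) precisely because they are conventions, not derived
quantities.

* **Length selection**: the length with the most binders
  (IC50 < 500 nM, strict, configurable) is the default motif and is
  always kept; other lengths are viable at ≥ 200 binders. Ties at equal
  binder counts break to the shorter length (fixed, arbitrary). Keeping
  the default unconditionally means very small datasets still produce
  one motif — the alternative (no motif at all below the bar) would
  silently drop exactly the alleles users most need summarized.

### Evaluation

Anchor calls are compared position-by-position against expert reference
motifs, accumulating a 2×2 confusion matrix over all (allele, length)
pairs; sensitivity = 100·TP/(TP+FN) and specificity = 100·TN/(TN+FP)
are reported half-up rounded to one decimal. Preferred-residue overlap
at reference anchors uses Jaccard similarity against the reference
primary ∪ secondary pool. Expert residue strings such as `VL[MIAT]`
parse as primary (unbracketed) and secondary (bracketed) sets;
uppercasing and punctuation-stripping normalize scanning artifacts in
the transcribed tables.

The packaged fixtures provide: per-allele record/binder counts for the
published 18-allele 9-mer benchmark panel; the published anchor
confusion matrix for that panel (32/4/7/119 over 162 positions); and
the expert and published-automatic motif assignments. The peptide-level
training data behind those published matrices live in the IEDB and are
not redistributed, so the package does not claim to regenerate the
published per-allele motifs — the fixtures make the published numbers
checkable and the evaluation machinery exercisable.

## Synthetic data

`planted_anchor_matrix` builds ground-truth matrices with exact
per-column spreads: anchor columns span `anchor_spread` (default 2.5)
and background columns `background_spread` (default 0.3) log10 units,
with seeded uniform residue placement, columns mean-centered.
`generate_dataset` samples peptides uniformly per position, applies the
additive model plus Gaussian noise (default sd 0.1 log10 units ≈
25% CV, a realistic inter-assay scatter), sets the intercept default to
2.0 (100 nM baseline, centering affinities in the assay window) and
clamps IC50 to [0.1, 50000] nM. Default dataset size is 2000 peptides,
mid-scale for well-studied alleles.

What the generator does *not* emulate: biased amino-acid usage of real
proteomes, censored (">50000") measurements, repeat-measurement
structure, inter-lab batch effects, or residue-coupling effects.
Recovery tests on this generator therefore demonstrate correctness of
the estimation and calling machinery under the model's own assumptions,
not performance on real binding data.

Uniform residue sampling is intentional: it makes the one-hot design
well conditioned, so parameter-recovery failures indicate solver or
rule defects rather than identifiability problems.

## Numerical choices

* Ridge solve via eigendecomposition of the centered Gram matrix
  (20·L × 20·L, symmetric): exact for λ > 0 and cheap to sweep; λ = 0
  is rejected because the one-hot system is singular.
* λ-grid ties resolve to the first (smallest) grid value reaching the
  minimum CV error; folds come from a seeded shuffled K-fold split.
* Matrix files store floats at 17 significant digits so write→read is
  bit-lossless; rendered HTML shows 2 decimals (display precision only).
* Duplicate peptides are kept as independent regression rows by
  default (they carry real measurement weight); optional collapse uses
  the geometric mean of IC50s.
* Renders are pure string construction — no timestamps, no randomness —
  so fixed inputs give byte-identical SVG/HTML.

## Benchmark problem sizes

The recovery benchmark (`anchor_recovery_benchmark`) uses 100
replicates of 2000 peptides with fresh planted matrices and seeds per
replicate; the solver-oracle check uses 500 peptides. These sizes make
the estimation problem comfortably identifiable while keeping the full
suite fast on a single core.

## Known limitations

* The additive model cannot express anchor interdependence (e.g.,
  compensatory pairs); motifs inherit that blindness.
* Anchor/classification thresholds were fixed once as field-plausible
  conventions and exposed as configuration; they are not re-optimized
  against gold standards by this package.
* Multi-allele evaluation requires matching (allele, length) pairs in
  the reference file; there is no fuzzy allele-name resolution.
* MHC class II (open groove, variable register) is out of scope: the
  fixed-length one-hot encoding presumes a closed class I groove.
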