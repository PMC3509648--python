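# Methods

This note records the models implemented in `phenoliq`, the conventions and
parameter choices behind them, and what the tests do and do not establish.

## Molecular representation and descriptors

Molecules are ordered atom lists (element, 3D position in Å) with a bond
list. Structure parsing, writing, and 3D embedding (ETKDG with a fixed
seed, MMFF cleanup) are delegated to RDKit. Molecules parsed from SMILES
carry no coordinates and are refused by the 3D descriptors until embedded;
coordinates read from MOL/SDF files are used as given — no geometry
optimization is performed, so descriptor values depend on the conformer
supplied.

Atomic weights come from a shipped plain-text table (mass in amu, van der
Waals volume in Å³, Sanderson electronegativity, polarizability in Å³) and
are divided by the carbon value at load time, so weight(C) = 1 in every
scheme. The table follows the standard carbon-referenced convention of the
molecular-descriptor literature; the printed mean-polarizability values for
gallic (0.64), gentisic (0.65) and salicylic acid (0.67) reproduce exactly
under it, which pins down the polarizability column in particular.

Conventions that the descriptor definitions leave open were fixed as
follows:

- **Hydrogen handling.** Graph descriptors (HNar, IDM, GATS) operate on the
  hydrogen-suppressed graph; constitutional (Mp) and 3D descriptors (DISP,
  3D-MoRSE) include hydrogens.
- **Topological distances** use unit edge weights; bond order and
  aromaticity do not affect them.
- **3D-MoRSE numbering.** Signal k corresponds to scattering parameter
  s = k − 1 Å⁻¹ (32 signals, s = 0…31), with sin(0)/0 ≡ 1. Signal 1 is
  therefore the pair-count limit.
- **IDM** is the magnitude-based mean information content: the Shannon
  entropy (bits) of the upper-triangle distance distribution normalized by
  the Wiener index. Commercial implementations have variants; exact
  agreement with any one of them is not claimed and nothing downstream
  depends on it.
- **DISP** uses the plain (unweighted) centroid as the geometric reference,
  matching its description as the displacement between the geometric and
  property-weighted centers.
- **Degenerate Geary autocorrelations** (no atom pair at the lag, or zero
  weight variance) return 0 with a warning rather than NaN, keeping
  descriptor matrices finite for selection.

Pretreatment removes columns that are identically zero, have one value
occupying at least half the rows, or have sample variance (n−1
denominator, raw values) below 5·10⁻⁴. The thresholds are exposed as
parameters; the defaults are the study's settings.

## Unsupervised forward selection

UFS builds a maximal subset of columns whose mutual squared multiple
correlation stays below `r2max` (default 0.90). Columns are centred and
scaled to unit norm; the squared multiple correlation of a candidate
against the selected span is the squared norm of its projection onto an
orthonormal basis of that span, grown by modified Gram–Schmidt with one
re-orthogonalization pass. Selection seeds with the least-correlated pair
(the partner passes through the normal admission check, so an exactly
duplicated pair never both enter), admits the smallest-R² candidate each
round, and permanently rejects candidates above the threshold. Ties break
toward the lower original column index; a residual norm below 1e−10 counts
as exact dependence (R² = 1). Reruns on identical input give identical
traces.

**Known limitation.** With p ≫ n and mutually near-orthogonal noise
columns, the selected span approaches the full row space (expected R² of an
independent Gaussian column against an s-dimensional span is s/(n−1)), so
UFS admits noise until rejections set in and can then reject entire
informative column families against that span. On the synthetic
paper-like scenario (39 rows, ~130 columns) this is the typical outcome,
and the test suite asserts signal recovery on the supervised branch only.
Real descriptor pools are strongly collinear — many near-duplicate columns
per underlying factor — which is the regime the procedure is designed for.

## Stepwise regression

Classical forward stepwise with backward checks: the candidate maximizing
the partial F statistic, `F = (SSE_reduced − SSE_full)/(SSE_full/(n−p−1))`,
enters if F ≥ F_enter (default 6); after each entry, included descriptors
with partial F < F_remove (default 3) leave, smallest first. Entries that
would make the design rank-deficient, or for which n ≤ p + 2, are refused.
Descriptors are standardized to zero mean and unit variance before
fitting; the response stays in minutes. When the running SSE falls below
1e−10·SST the fit is treated as perfect and forward selection stops —
otherwise roundoff-level "improvements" would produce spurious entries
with huge F on noiseless data.

With F_enter = 6 and ~20 candidates, one spurious noise descriptor enters
in roughly a third of random replicates (the maximum of ~18 F(1, 26)
variates clears 6 that often); this is inherent to the threshold, so
"recovery" of a planted signal means the planted descriptors are contained
in the selection, not that the selection is exactly the planted set.

## Linear and network models

`fit_ols` wraps statsmodels OLS and keeps the standardization applied at
fit time, so predictions accept raw descriptor values; standard errors, T
and two-sided p values come from the usual Student-t inference with
n − p − 1 degrees of freedom.

The neural networks are single-hidden-layer perceptrons with hidden and
output activations drawn from {identity, logistic, tanh, exponential}
(exponential means eˣ; logistic 1/(1+e⁻ˣ)). Inputs are min-max scaled to
[0, 1]; the response is min-max scaled into the output activation's
comfortable range ([0.1, 0.9] for logistic and exponential, [−0.8, 0.8]
for tanh, [0, 1] for identity) and inverse-transformed for reporting. The
loss is the sum-of-squares error plus quadratic weight-decay penalties
(default 0.01 on hidden and output weights), minimized with L-BFGS-B
(analytic gradients). A callback snapshots the weights at every iteration;
early stopping restores the iteration with the lowest test-subset error.
The iteration cap (default 300) is a configuration value, not a claim
about the original software's settings.

The ensemble trainer draws `n_networks` (default 500) random
configurations — hidden units uniform in 3…8, activation pair uniform over
the four functions, normal random initial weights — with per-network seeds
derived from the master seed and the network index, so any single network
is reproducible in isolation. Selection defaults to the lowest test-subset
RMSE; a `select_on="validation"` switch reproduces the original protocol
of selecting on external-validation error, with a logged warning, because
that choice leaks the validation set into model selection and the
resulting external statistics are no longer strictly blind.

Sensitivity ranking replaces each input in turn by its mean and ranks
inputs by the ratio of the perturbed to the intact sum-of-squares error;
an ignored input has ratio 1.

## Validation

PRESS and Q² follow the definitions above; internal (leave-one-out,
explicit per-fold refits) and external validation share the training-mean
reference by default so both statistics are on the same yardstick. A flag
switches the external reference to the validation-set mean; on the
embedded dataset the difference is in the third decimal. Pipeline reports
record both.

y-scrambling permutes the response, refits the coefficients of the fixed
descriptor subset (selection is not rerun; rerunning it per permutation is
possible via a custom fitter but is not the default, which matches common
practice and costs 500 refits rather than 500 selection runs), and records
each scrambled model's R² together with |corr(y_permuted, y_observed)|.
The diagnostic is the intercept of the least-squares line of R² on the
absolute correlation: models built on noise should cluster near zero.

## Embedded dataset

The 39-compound table stores experimental retention times, the four
published prediction columns exactly as printed (2 decimals, no
back-correction), and the split: 30 training compounds, of which 5 (the
test subset — salicylic acid, caffeic acid, homovanillic acid, chrysin,
(−)-epicatechin) steer network early stopping, and 9 external validation
compounds. Data files are checksummed at load. Compound structures are
curated SMILES assembled from the compounds' standard nomenclature (the
source prints names only); they serve descriptor computation and the
printed mean-polarizability checks, and are never used to re-derive the
published regression coefficients — those would require the original
commercial descriptor values, which are not printed. For the same reason
the published coefficient sets, the 1519→915 pretreatment count, the
915→22 UFS reduction, internal Q² values, T statistics, and the scrambling
intercepts (0.141/0.172) are stored as reference metadata, not reproduced;
the corresponding algorithms are verified against independent brute-force
oracles instead (see `tests/test_acceptance.py`).

Recomputing training R² and external PRESS/Q² from the stored prediction
columns reproduces all ten printed statistics within ±0.01 (PRESS) and
±0.005 (R², Q²), the slack implied by 2-decimal rounding of the stored
predictions.

## Synthetic data

The generator draws iid standard-normal base columns, plants a sparse
linear signal y = Xβ + N(0, σ²), and adds collinear copies
`parent·√R² + noise·√(1−R²)` so the population copy–parent squared
correlation equals the target. The paper-like scenario uses 39 rows split
25/5/9, 100 base columns with 4 informative (unit coefficients), σ chosen
for a population R² of 0.95 (σ = √(4·0.05/0.95) ≈ 0.46), and 30 copies
over six parents at targets 0.92–0.99. Gaussian marginals are a deliberate
simplification: the modelling layer relies only on second-moment
structure, so passing tests establish correctness of the statistical
machinery, not realism of descriptor distributions — conclusions about
real chromatographic data rest on the embedded dataset, not on the
generator.

## Problem sizes in the test suite

Monte-Carlo style checks use 20–100 replicates and matrices around
30 × 20…50; network-ensemble tests use 6 networks with a 60-iteration cap.
These sizes were chosen so the whole suite exercises every stage, including
500-permutation scrambling and a 100-seed stepwise-recovery experiment, in
well under a minute of numerical work; the defaults of the library itself
(500 networks, 500 scrambles) remain the study's settings.
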