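# Methods

## Model and assumptions

`dtipred` treats DTI prediction as supervised classification over the
complete bipartite grid of targets × drugs. Positives are the known
interacting pairs; *all* other pairs are labelled negative. This
closed-world assumption is standard for the gold-standard benchmark
collections but means "negatives" include undiscovered true interactions;
reported specificity is therefore conservative with respect to the true
biology. No negative subsampling is done before balancing — the imbalance
is carried into the pipeline and quantified as the sample ratio
(negatives/positives).

The unit of cross-validation is the pair. Because a protein (or drug)
appears in many pairs, pair-level splits allow the classifier to
recognise entities seen during training; this is inherent to the
protocol, not an artefact of this implementation, and is the reason the
scan fixtures used in tests put each protein in exactly one pair when
entity memorization would confound the quantity being measured.

## Protein descriptors

**Profile input.** The PSI-BLAST ASCII profile parser consumes the
`-out_ascii_pssm` dialect, reads only the first (log-odds) 20-column
block, and remaps columns by the header letters rather than by position.
The documented upstream command is PSI-BLAST with three iterations and
E-value 0.001 against a large reference proteome; running it is out of
scope and profiles are consumed as files. Rows for non-standard residues
(X, B, Z) are kept unchanged: dropping them would change L and every
downstream feature, and nothing in the descriptor definitions requires
canonical residues.

**Normalization** is the elementwise logistic map 1/(1+e^(−E)); it is
strictly monotone, keeps every value in (0, 1), and is exact for the
integer score domain.

**Pseudo-PSSM** with lag λ (default 3, chosen upstream by accuracy scans
over λ = 0..15) yields 20 + 20λ features. λ = 0 reduces to the plain
column means; λ must be < L.

**DCCA coefficients** with window parameter s (default 36, from scans
over s = 9..81). For two columns, cumulative sums are split into L−s
overlapping windows of s+1 points; each window is detrended by an OLS
straight line per series; per-window residual covariance and variances
use divisor s+1 exactly as the estimator is conventionally printed
(biased, but a fixed convention — only ratios matter); window averages
form f²_xy, f²_xx, f²_yy and ρ = f²_xy/(f_xx f_yy). The 190 pairs are
ordered lexicographically (A,R), (A,N), …, (Y,V); the ordering is a
serialization convention with no effect on the classifier.

Numerical edge cases: a constant column makes ρ undefined (zero
detrended variance up to rounding); it is reported as 0 with a warning so
vectors stay total and bounded. When the covariance equals the geometric
mean of the variances exactly (identical or negated series), ρ is
returned as exactly ±1; otherwise the ratio is clipped to [−1, 1] against
~1e−15 floating-point overshoot. The vectorized implementation shares one
residual-maker matrix across windows (residuals are invariant to the
affine reparametrization of the window index) and is tested to 1e−12
against a literal window-by-window oracle using explicit normal
equations.

## Drug descriptor

The 1024-bit FP2 path fingerprint is consumed as a 256-character hex
string and expanded to 256 nibbles in 0..15, leftmost character first.
Nibble order within the bitstring is a convention; it affects
cross-tool reproducibility of serialized features, not classification.
Fingerprint generation from structures (e.g. Open Babel on SMILES) is a
documented upstream step, never executed here.

## Feature selection and balancing

**Lasso** minimizes the unscaled squared-error objective
Σ_n (y_n − Σ_m x_nm β_m)² + λ_reg Σ_m |β_m| on the 0/1 label — the
regression form, not logistic. Features are standardized internally
(zero mean, unit variance; constant columns get unit scale and a zero
coefficient) and coefficients are reported on the standardized scale;
whether to standardize was an open choice and is adopted because the
pair vector mixes (0,1)-scale profile statistics with 0–15 nibbles.
The fit is delegated to scikit-learn's coordinate-descent Lasso with
alpha = λ_reg/(2N); correctness is pinned by the coordinate-wise
soft-thresholding closed form on orthonormal designs. λ_reg is chosen by
internal K-fold cross-validated squared error on the training portion
only (the choice of selection criterion was open; CV is the field
default), ties toward the sparser model.

**SMOTE** follows the DMwR parameter convention: perc.over = 500 creates
5 synthetic rows per minority row as z_new = z + U·(z̄ − z) with one
U ~ Uniform(0,1) per row and z̄ drawn uniformly from z's k = 5 nearest
minority neighbours (Euclidean metric in the selected feature space,
distance ties broken by row index); perc.under = 120 keeps
1.2 × (synthetic count) majority rows sampled without replacement,
capped at the majority size. With defaults and m minority rows the
output is exactly 6m/6m. Synthetic rows are flagged in a provenance
column. Inside cross-validation, k is capped at minority−1 with a
warning when a small training fold cannot support k = 5; the standalone
operation keeps the strict precondition.

**Scope.** `balance_scope="train_only"` (default) fits Lasso and SMOTE
per training fold; `"global"` applies both before splitting, reproducing
the historical protocol whose held-out folds contain synthetic rows. The
leakage test demonstrates on signal-free data that the global protocol
alone lifts apparent AUC far above chance; results must always name the
mode.

## Classifier and evaluation

The forest uses 500 unpruned trees (tests use 40–100 for speed), mtry =
⌊√Q⌋ candidate features per split, bootstrap resamples, and a fixed seed.
Neither ensemble size nor mtry has a stated upstream value; these are the
conventional classification defaults. Probabilities come from
scikit-learn's per-tree leaf class fractions averaged over trees; with
unpruned trees leaves are (near-)pure, so this coincides with the
vote-fraction definition.

Scalar metrics at threshold 0.5 (a pair is called interacting when its
probability is strictly greater): ACC, SE = TP/(TP+FN), SP = TN/(TN+FP),
F = 2TP/(2TP+FP+FN), precision, recall. Zero-denominator ratios are NaN,
never 0. ROC/AUC by trapezoid over the tie-grouped threshold sweep (AUC
is verified against a normalized Mann–Whitney pairwise oracle); AUPR by
step-wise summation without interpolation, since linear PR interpolation
is optimistic. Cross-validation partitions pairs into near-equal folds
(sizes differ by at most one); folds without positives produce NaN for
positive-class metrics with a warning, and summaries use NaN-aware
means.

## Parameter scans and inference

`scan_lambda`/`scan_s` evaluate candidate values by per-dataset CV
accuracy and select the argmax of the cross-dataset mean, ties to the
smallest value. Infeasible values (λ ≥ some protein's L; s > L_min − 1)
are excluded and logged. Per-value seeds are derived from the master
seed and the value itself, so parallel evaluation order cannot change
results. Scans consume raw inputs (profiles, fingerprints, edges) rather
than assembled datasets because the protein features must be recomputed
at each candidate value.

`predict_new` trains on every pair of the training dataset (selection
and balancing applied to the full table — everything is training data at
inference time), scores the query grid, and returns records above the
probability cutoff (default 0.5) sorted by probability descending, ties
by (drug id, target id), together with the fraction of the grid called.

## Synthetic data

The fixture generator emulates the *shape* of real inputs: integer
profiles with log-odds drawn from a discretized normal (mean −2, SD 3)
clipped to [−9, 11] — realistic profiles concentrate well inside the
conventional range — with lengths defaulting to 83–130 (83 is the
shortest benchmark-like sequence and bounds the feasible DCCA window at
82); uniform random hex fingerprints; and a uniform random edge set.
Default problem sizes for tests are 8 targets × 12 drugs with 16
positives (sample ratio 5), sized so the full stack cross-validates in
about a second.

With `signal_strength > 0`, a minimal block of "active" targets and
drugs is designated, positives are drawn from the active × active block,
and designated raw features of active entities are mean-shifted by that
many within-class SDs (profile scores: SD 3; nibbles: SD of a uniform
nibble), clipped back into legal ranges. Because the logistic map is
nonlinear, a raw-score shift moves the planted column's mean feature
*and* perturbs its lag and DCCA features; "recovering the planted
signal" therefore means retaining any feature derived from a planted raw
input, and the bundle records exactly which names those are.

What the generator does **not** emulate: real substitution-matrix
correlation structure between amino-acid columns, homology between
proteins, chemical similarity structure between fingerprints, and the
extreme imbalance of the enzyme-scale benchmarks (ratio ≈ 100). Passing
tests therefore demonstrate correctness of the machinery and the
protocol-level claims (separability recovery, chance-level behaviour on
null data, leakage direction), not field performance on real benchmark
collections, which additionally requires PSI-BLAST profiles and curated
interaction sets.

## Known limitations

- Pair-level CV overstates generalization to unseen proteins or drugs;
  entity-wise splits are not implemented.
- The squared-error Lasso on 0/1 labels is a selection heuristic, not a
  calibrated classifier; its support can be empty for large penalties, in
  which case the pipeline falls back to all features with a warning.
- Only the random forest is shipped; the evaluation harness accepts any
  classifier exposing fit/predict_proba, but no others are bundled.
- Profiles and fingerprints are consumed, never generated: PSI-BLAST and
  the fingerprinting tool are external, documented dependencies.
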