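# Methods

This note records the models and procedures the package implements, the
conventions and parameter choices behind them, what the synthetic generator
does and does not emulate, and the numerical decisions a maintainer would
otherwise have to reverse-engineer from the code.

## Data model and conventions

A feature table is an `n × d` real matrix of learned-feature activations —
one row per 30-second EEG epoch — with per-row stage label, domain tag
(source/target), subject ID and recording ID. Three conventions hold
everywhere:

- **samples are rows**; linear transforms act on the right, `x̂ = xA`, so a
  transform maps row covariances as `C ↦ AᵀCA`;
- **one rank threshold**: a singular value counts as nonzero iff it exceeds
  `1e−10 · σ_max`; every rank decision (covariance rank, PCA truncation,
  pseudoinverse cutoffs, CORAL's `r`) uses this constant so ranks are
  reproducible across code paths;
- **deterministic PCA signs**: each basis column is flipped so its
  largest-magnitude entry is positive. PCA directions are only defined up
  to sign; fixing them makes every downstream quantity (subspace aligners,
  TDAS similarities) byte-reproducible.

Covariances are unbiased (`1/(n−1)`) except inside the H-score, which uses
the population (`1/n`) convention on both its covariances so the
law-of-total-covariance decomposition is exact; the trace ratio is
insensitive to the common factor.

## CORAL and Per-Class CORAL

CORAL finds `A` minimizing `‖AᵀC_sA − C_t‖²_F`. The implemented closed form
whitens with the inverse square root of the (possibly shrunk) source
covariance and recolors with the square root of the top-`r` spectral part
of the target covariance, `r = min(rank C_s, rank C_t)`. Matrix roots and
pseudoinverses go through symmetric eigendecompositions with the global
rank threshold. The recoloring factor is the *plain* square root of the
target spectrum — an inverse square root there would not minimize the
objective (the identity `AᵀC_sA = C_t` would fail on full-rank input, which
a test checks directly).

Fits apply a default ridge `λ = 1e−6 · trace(C)/d` to both covariances
(pass `shrinkage=0` to disable). The raw estimator stays unregularized; the
ridge exists because downstream inverses (whitening, H-score) need guarding
on rank-deficient activations.

**Mean handling.** The covariance objective says nothing about means, so
`recenter` makes the choice explicit:

- `"none"` — transformed source is left zero-meaned (the literal reading of
  the objective on centered features);
- `"source"` — the source mean is restored; this is the canonical CORAL
  behavior (the transform recolors covariance and does not touch means) and
  is the benchmark default;
- `"target"` — the transformed source is moved onto the target mean, which
  additionally corrects any pure translation component of the shift.

Per-Class CORAL fits one transform per stage present in both domains with
at least `min_class_n = d + 2` samples on each side — below that the class
covariance is necessarily singular. Classes failing the threshold fall back
to the global transform and are flagged on the fit. For the per-class
variant `"none"` behaves like `"source"` (each class keeps its source class
mean): collapsing every class onto the origin would discard exactly the
label geometry the variant exists to preserve.

## Subspace Alignment

Both domains are projected onto their top-`k` PCA bases and the source
basis is aligned with `M = V_sᵀV_t`; source rows map to `(xV_s)M`, target
rows to `xV_t`. `k` defaults to 100 and is truncated to the data rank with
a warning. Projections are applied to raw (uncentered) rows; PCA bases are
computed on centered data as usual. All singular values of `M` lie in
[0, 1] because it is a product of orthonormal-column matrices.

One geometric fact worth recording: at full rank (`k = d`) the aligned
source projection collapses to `xV_t` — projecting source points directly
with the target basis — so SA is only a nontrivial operation when `k` is
below the ambient dimension. Relatedly, when the target is an exact
rotation of the source, the two domains' *own* PCA coordinates already
coincide (PCA coordinates are rotation-invariant) and `M` is precisely that
rotation expressed in the source basis; the test suite asserts these true
invariants rather than pointwise equality of aligned coordinates.

## Head re-training and the DDC reference trainer

The "head" is a multinomial logistic layer on fixed features, trained by
L-BFGS to a 1e−6 tolerance, standing in for re-training the dense layer
adjacent to the output of a frozen network. The L2 penalty defaults to
`10^−6.9` on the squared weight norm added to the mean cross-entropy (the
value the reference training recipe uses throughout); dropout has no
surface on a linear head and is omitted.

DDC trains a network on source and target jointly while penalizing the
maximum mean discrepancy between source and target activations at a chosen
layer. The reference trainer is a one-hidden-layer tanh network (default
width 16) written directly in numpy with manual backpropagation and Adam
(learning rate 0.001), the penalty applied to the hidden layer — the
analogue of penalizing the last feature-extraction layer of a deep model.
Each epoch draws paired source/target batches from independent seeded
shuffles; the per-batch penalty is the linear-time MMD estimator (its
unbiasedness argument assumes i.i.d. batches) with the analytic RBF
gradient, and the kernel bandwidth is re-derived once per epoch from a
fixed 256-sample subsample of pooled hidden activations so it tracks the
evolving activation scale deterministically. With `mmd_weight = 0` the
penalty machinery is skipped entirely and the run is plain supervised
training on the pooled data. The reported `final_mmd2` is the quadratic
estimator on all source vs all target hidden activations after training.

## MMD estimators and bandwidths

With `M` the median *squared* pairwise Euclidean distance of the pooled
evaluation set, the kernel is `k(x,y) = exp(−(scale/(2M))·‖x−y‖²)`;
`scale = 1` is the standard median heuristic (`σ² = M`) and scales 0.1 and
10 probe bandwidth sensitivity. The quadratic estimator is the biased
V-statistic (diagonal terms kept), which is nonnegative and bounded by 4
for a kernel bounded by 1. The linear-time estimator averages
`k(s₁,s₂)+k(t₁,t₂)−k(s₁,t₂)−k(t₁,s₂)` over disjoint quadruples of a seeded
shuffle; both sets are ordered by the *same* seed so that two identical
sets cancel term by term, the larger set is subsampled to the smaller, and
an odd count drops one sample. Bandwidth is computed once on the pooled
evaluation set, not per batch, to keep the measure stable.

## Transferability measures

- **LEEP** builds `P̂(y,z)` as the mean posterior mass of source label `z`
  among target samples with true label `y`, normalizes by `P̂(z)`, and
  returns the mean log-likelihood of the resulting classifier. Logs are
  floored at 1e−300. LEEP ≤ 0 always, with 0 only for a perfect one-hot
  predictor.
- **H-score** uses class-frequency-weighted between-class covariance around
  the global mean; the inverse is a pseudoinverse by default (and whenever
  the total covariance is singular). Under an invertible feature map and a
  true inverse the score is invariant, which the suite checks.
- **Hypothesis margin** and **cross-dataset silhouette** treat dataset
  membership as the class. The margin of a point is half the difference
  between its nearest-other-dataset and nearest-same-dataset distances
  (the query point excluded from its own set), averaged over the union.
  The silhouette of a point is `(B − A)/max(A, B)` with `A` the mean
  distance to its own dataset (excluding itself) and `B` to the other; a
  point with `A = B = 0` contributes 0. Written this way the score is the
  standard two-cluster silhouette — +1 for well-separated domains, ~0 for
  fully overlapping ones — and the implementation is cross-checked against
  a generic silhouette routine in the tests.
- **Downsampling** for the margin is every 10th sample from a seeded
  circular offset, per dataset independently: "downsample by a factor of
  10" with a deterministic scheme.
- **TDAS** compares the aligned-subspace dot product against
  `ε = eps_scale · m` (`m` = median pairwise target distance) exactly as
  defined, units notwithstanding; no normalization is silently applied.
  Full pairwise distances are used for `m`.

## The synthetic study generator

The generator emulates the *shape* of a wearable sleep-staging study:
5 imbalanced stages (default priors W .15, N1 .08, N2 .45, N3 .17, REM .15
— a documented convention approximating a healthy adult night, not fitted
to any dataset), 24 subjects with 1–6 recordings each by default, subject-
level random mean offsets, and Gaussian within-class noise.

Class means are ordered along a **depth/amplitude axis** — the direction of
the baseline activation level (`feature_mean = 0.9` per dimension, a
positive level as for rectified-unit activations): Wake at the high end
(depth +1.0), N3 at the low end (−1.0), N2 at −0.25, and N1 (+0.35) close
to REM (+0.2), so adjacent-stage and N1/REM confusions dominate, as in real
staging. Each class also gets a random offset at half the axis scale
(`class_mean_spread = 1.5` overall) so stages are distinguishable beyond
depth.

The source→target shift displaces all class means by
`shift · within_class_sd` along the **attenuation direction** — the unit
vector from the global feature mean toward the origin, i.e. essentially
down the depth axis. This models the amplitude attenuation of a single
forehead wearable channel relative to a clinical montage, whose well-known
consequence is that attenuated wake resembles light sleep. Two properties
follow and are what the test suite relies on: the shift produces genuine
stage-label conflicts between domains (so classification accuracy degrades
with shift — a shift into empty feature space would not do this), and the
dot-product similarities underlying TDAS decrease monotonically (an
isotropic shift direction would *spread* the similarities instead, and
TDAS would not fall). A rotation in a seeded random 2-plane
(`rotation_angle`) and a target covariance scale (`cov_scale`) are
additional, independent shift components, both off by default.

Because `shift` enters only as a deterministic additive term, configs
differing only in `shift` share every random draw — the shift family is
coupled, which makes the monotonicity checks sharp rather than statistical.

What the generator does **not** emulate: raw EEG or spectra, hypnogram
temporal dynamics (stage transitions are i.i.d. draws), recording-level
drift, heavy-tailed artifacts, and any nonlinear component of a real
clinical-to-wearable feature shift. Tests passing on this family show the
algorithms and measures behave as their theory predicts under a controlled
linear-Gaussian shift; they do not certify performance on real recordings.

Synthetic model posteriors for LEEP draw a predicted label (correct with
probability α, else uniform over the rest) and a Dirichlet row peaked on it
with concentration 20 by default (`∞` gives exact one-hot rows).

## Benchmark protocol

For each held-out target subject: the remaining target subjects form the
training portion; a balanced source subset is drawn by keeping the first
recording of every source subject and then every n-th of those recordings,
`n = ⌊#source recordings / #target training recordings⌋`, truncated to the
target count; each algorithm trains on (transformed) source + target-train
and its head is evaluated on the held-out subject (accuracy and Cohen's κ);
every measure is computed on the balanced source vs the *training* portion
only — never the held-out subject. LEEP's posteriors come from a head
trained on the balanced source only.

Aggregation: per-algorithm mean ± SD of accuracy and κ; best-algorithm
tallies with ties split equally; two-sided paired t-tests of each algorithm
against head re-training (zero-variance differences are reported as
undefined, not as 0); Spearman correlations (average ranks, t-approximation
p-values) of each measure with fold accuracy per algorithm plus an
"overall" column pooling (measure, accuracy) pairs across algorithms.
Bonferroni flags default to a family of `#measures × (#algorithms + 1)`.

In the benchmark, CORAL and Per-Class CORAL default to
`recenter="source"` — classic CORAL, covariance-only. Mean-recentering
(`"target"`) is exposed and fully corrects a pure-translation shift, which
is the correct behavior of that variant but makes its accuracy independent
of the shift magnitude on this family.

## Problem sizes of the shipped studies

The acceptance script and the end-to-end tests use desk-scale versions of
the protocol, chosen once as the package's standard study sizes: the
monotone-shift family uses 10 subjects × 100 epochs (≈1000 epochs per
side) at shifts {0, 0.5, 1, 2, 4}; the correlation study runs 20 LOSO
benchmarks (4 replicate seeds × the 5 shifts) on 5-subject, 80-epoch
studies with all five algorithms (DDC at 40 epochs); the t-test null
calibration runs 10 zero-shift studies with the four head-based algorithms
— DDC is excluded there because its model class differs from the logistic
baseline, so a systematic accuracy offset against head re-training would
reflect capacity, not transfer. The DDC mechanism study uses 10 paired
runs (penalty on vs off, identical seeds) on 4-subject shifted pairs.

## Numerical choices and degenerate inputs

- Rank threshold `1e−10·σ_max` everywhere; PCA sign convention as above.
- Loader rejects non-finite feature cells with the row index; metadata
  length mismatches are schema errors.
- `n = 1` covariance is `shrinkage·I` with rank 0.
- Median-heuristic bandwidth on coincident points, TDAS on a zero-spread
  target, κ with chance agreement 1 but imperfect observed agreement,
  Spearman with constant ranks, and paired t on zero-variance differences
  all raise typed errors rather than returning a silent placeholder.
- LEEP guards its logarithm at 1e−300; silhouette contributes 0 for a
  point with `A = B = 0`.
- The linear MMD estimator on identically ordered identical sets returns
  exactly 0 by construction.

## Known limitations

- The DDC trainer is a reference implementation for studying the loss, not
  a performance-tuned deep model; with a linear-separable synthetic family
  its accuracy trails the L-BFGS logistic head.
- H-score assumes a fixed feature extractor; correlating it with DDC
  performance (which re-trains the extractor) is conceptually strained, and
  the benchmark makes no attempt to repair that.
- TDAS compares a dot product against a distance-derived threshold; the
  unit mismatch is preserved deliberately. An optional cosine-normalized
  variant is not provided; the measure saturates (to 0 or to the target
  count) when `ε` leaves the similarity range.
- The per-fold measure values do not depend on the algorithm, so
  per-algorithm correlation columns share one measure vector and differ
  only through the accuracy vector.
- Across replicated synthetic studies the pooled MMD-accuracy correlation
  is stable (~−0.3) while the TDAS-accuracy correlation is markedly less
  robust and can flip sign between study draws: TDAS's threshold
  `ε = eps_scale·m` inherits the fold's subject composition through the
  median target distance `m`, adding a fold-level component unrelated to
  the domain shift. Treat single-study TDAS correlations with caution.
- The normalized "transferability" variant of H-score and measures outside
  the six implemented (NCE, LogME, …) are out of scope.
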