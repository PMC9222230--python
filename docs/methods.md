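# Methods

## Model and procedure

The experiment is modelled as a 6-mode real tensor `x[i,j,k,m,s,t]`
(probe, time, replicate, treatment, strain, tissue).  Each sample fiber
(fixed `j,k,m,s,t`) is centred over probes and rescaled to sum of squares
N, so samples are exchangeable in scale and the probe loadings of any
singular vector are dimensionless.  The higher-order SVD factorizes the
tensor as a core `G` contracted with one column-orthonormal factor matrix
per mode; factor columns are the left singular vectors of the mode's
unfolding, ordered by singular value.  The decomposition is computed by
dense economy SVDs of materialized unfoldings — at the intended scale
(≈31k probes × 300 samples ≈ 9.3M entries) the largest unfolding is a
31k × 300 matrix, well inside desk-scale memory; there is no out-of-core
path, and no HOOI/ALS refinement (HOSVD alone is the estimator).

Selection proceeds in two stages.  First, one singular vector per
non-probe mode is chosen by an explicit score in [0, 1]:

* constancy `|mean(v)|·√len(v)/‖v‖` — 1 iff the vector is exactly
  constant; used for the tissue and replicate modes (tissue-independent
  expression, exchangeable replicates);
* contrast `|Σ_{g1} v − Σ_{g2} v| / (‖v‖·√len(v))` — 1 iff the vector is
  proportional to the two-group ±1 indicator; used for the treatment and
  strain modes (disease/control distinction);
* free — no constraint; the leading (largest-singular-value) vector is
  taken.  Used for time, whose dependence the analysis leaves open.

Ties break toward the smaller index.  Second, probe-mode vectors are
ranked by `|G(ℓ1, ℓ2*, …, ℓ6*)|` at the chosen non-probe indices and the
top `n_probe_vectors` (default 1) are kept.  Probe *i*'s score is the sum
of its squared loadings on the kept vectors, attributed to a scaled
chi-squared null with df = number of kept vectors.

## SD optimization

The null scale σ is estimated, not assumed: for candidate σ, probes with
BH-adjusted `P[χ²_df > score/σ²] ≥ threshold` are regarded as null, and σ
is chosen to minimize the sample SD of the 100-bin histogram frequencies
of their `1 − p` values — i.e. the σ under which the null p-value
distribution is most uniform.  The search is a deterministic 201-point
log-grid scan over `[s/100, 100s]` (s = RMS component scale
`√(mean(score)/df)`) refined by bounded scalar minimization between the
grid neighbours of the optimum.  The pipeline runs two passes: σ is first
optimized with all probes eligible as null, then re-optimized excluding
probes selected in pass 1; the pass count is configurable and the
procedure converges immediately in practice (pass 2 rarely moves σ).  A
degenerate all-zero score vector is an error, as is any σ leaving fewer
null probes than histogram bins.

Defaults: histogram bins 100, BH threshold 0.01, df = number of kept probe
vectors, one kept probe vector.  Each is a convention of the method
family, exposed as configuration, not a fitted quantity.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design — 5 time points × 5 replicates ×
2 treatments × 2 strains × 3 tissues — with per-probe per-tissue Gaussian
baselines (SD 1), i.i.d. Gaussian noise (SD 1) on a log-like scale, and a
planted fraction (default 10%) of DEG probes shifted by a standardized
effect (default 3) in one treatment arm.  By default the shift applies
only in the disease-model strain (`affected_strain=1`), so the signal
lives in the treatment × strain interaction that the contrast criteria
target; setting `affected_strain=None` plants a strain-uniform treatment
effect.  The shift is identical in all tissues — exactly the
tissue-independent structure the pipeline selects for — and constant over
time unless `time_ramp` is set.  Planted effects share one sign; the
recovery statistics do not depend on sign symmetry.

Real microarray data differ in ways the simulator deliberately ignores:
probe-level artifacts (background, saturation, GC effects), correlated
noise between probes of one gene, heavier-tailed error distributions, and
missing values.  Passing recovery tests therefore demonstrates the
statistical machinery under its own assumptions, not platform-level
robustness.  The written series-matrix files use 6 significant digits
(typical distribution precision); round-trips are exact only at
`fmt="%.17g"`.

## Baselines

Per-tissue methods pool time points and replicates as i.i.d. samples and
compare the two treatment groups: Welch *t* (variance floor 1e-12 with
flagging for degenerate probes), a SAM-style statistic
`d_i = Δmean/(s_i + s0)` with `s0` = median standard error and a pooled
permutation null (all label splits enumerated exactly whenever their count
does not exceed the requested permutations; sampling is seeded), and an
empirical-Bayes moderated *t* whose variance prior is fitted by matching
moments of the log sample variances on the digamma/trigamma scale.  The
SAM-like and moderated-*t* methods are approximations in spirit of the SAM
and limma procedures, not replications of those packages; the moderated
*t* nevertheless agrees with `limma::eBayes` to ~1e-15 on test fixtures.

ComBat-style integration standardizes each probe with batch-size-weighted
grand mean and pooled variance, estimates per-batch location/scale effects,
shrinks them toward batch-level normal / inverse-gamma priors by the
iterative posterior-mean solution (convergence 1e-4), and removes them;
it matches `sva::ComBat` to machine precision on test fixtures.  With
`eb=False` the raw batch location/scale is removed without shrinkage —
this is the variant that removes a pure additive batch offset exactly,
since EB shrinkage at finite sample size intentionally leaves a residual.

Method comparison uses recall at matched empirical FDR: each method's
p-value ranking is cut at the largest prefix whose empirical FDR (against
the planted truth) does not exceed the tensor pipeline's own, so methods
are compared at equal realized error rather than at nominal thresholds.

## Enrichment

Selected probes map to symbols through a user-supplied annotation table
(many-to-one collapsed, unmapped probes counted).  Enrichment is a
one-sided hypergeometric tail per GMT term against a stated universe
(default: all genes in the library), BH-adjusted across terms.  This is a
local stand-in for web enrichment services; it does not reproduce any
particular service's composite ranking statistic.  Venn reports give
exclusive region counts, consistent with inclusion–exclusion by
construction.

## Numerical choices and degenerate inputs

* HOSVD sign convention: each factor column is flipped so its
  largest-magnitude entry is positive; singular-value ties keep the
  underlying SVD's stable order.
* An identically zero core slice at the chosen mode indices warns and
  falls back to index order.
* Zero-variance sample fibers abort normalization with the fiber index;
  missing design cells or duplicated cells abort assembly.
* Probe sets across tissues are intersected in first-table order.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; permutation tests require a seed.

## Problem sizes

Tests and the acceptance script use 2000-probe tensors (10000 for null
calibration checks) under the full 5×5×2×2×3 design — large enough that
singular-vector estimates are stable and recovery is informative, while a
full run of suite plus acceptance completes in about a minute.  The
pipeline itself handles the ≈31k-probe scale of real series matrices by
the same code path.

## Known limitations

* The criteria scores assume two-group contrasts; multi-level contrasts
  require explicit partitions.
* With `n_probe_vectors > 1` the chi-squared attribution treats kept
  vectors as exchangeable (a single combined df); per-vector dfs are not
  modelled.
* The SD optimization needs enough null probes (≥ histogram bins) and a
  unimodal-enough objective; pathological score distributions fall back to
  the grid optimum.
* No missing-value handling beyond rejection; no SOFT/MINiML parsing; no
  network retrieval.
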