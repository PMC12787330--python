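# Methods

This note records the models, the numerical choices, and the design of the
synthetic data, in enough detail that a reader can judge what the passing
test suite does — and does not — demonstrate about real E-nose data.

## Data model

A *recording* is one eviscerated fish in a sealed chamber at 10 °C, sampled
every 0.65 min for ~36 h: 2600 time instances × 35 sensor variables (7 MQ
metal-oxide modules × 5 analyte sensitivities each, columns named
`MQ4_CO`, `MQ6_Alcohol`, …). Sensor values are baseline-normalized
resistance ratios in arbitrary units. Each acquisition method ("gear",
including aquaculture as a rearing class) contributes 10 biological
replicates. Recordings are exchanged as plain CSV (`time_min` column plus
one column per channel; missing cells empty; non-numeric cells coerced to
missing on read).

## Cleaning

Per channel, in order:

1. **Windowed imputation.** For a missing index, take up to γ nearest
   previous and up to ω nearest subsequent *originally valid* observations
   (imputed values are never recycled as donors — the simplest policy that
   keeps the result independent of fill order). With both windows present,
   compare their means through δ = |μ_prev − μ_next| / max(μ_prev, μ_next, ε).
   If δ ≤ τ the neighbourhood is locally stationary and the fill is the
   length-weighted mean of the two window means (reduces to the plain mean
   when both windows are full); otherwise the fill is linear interpolation
   on the index axis between the last previous and first subsequent valid
   observation. One-sided windows use the available mean; a channel with no
   valid observation at all falls back to 0 with a warning (neutral after
   standardization). Defaults γ = ω = 10 (ω unstated in the protocol this
   emulates; symmetry), τ = 0.5, ε = 1e−12.
2. **IQR outlier treatment.** Values strictly outside
   (Q1 − α·IQR, Q3 + α·IQR), α = 1.5, quartiles by linear interpolation
   between order statistics, are set missing and re-imputed by rule 1.
   Bounds are computed once per channel on the post-imputation series and
   not recomputed after replacements; replacements provably stay inside the
   frozen bounds, so the pass is idempotent. Strict inequality means
   zero-IQR channels flag nothing.
3. **Scaling** (see below).

A single 0/1 mask per recording marks every cell filled at either stage.

### Scaling scope — a substantive choice

Z-scoring each channel *within* each recording (`scale="standardize"`,
the textbook per-file treatment) gives every gear slice of the tensor
identical per-channel variance. A short calculation shows what that does to
the impact statistic: for any exact CP representation with unit-norm
factors, the per-gear weighted loading norms are then pinned by the slice
norms, and gears can differ only through cancellation between *correlated*
factor components — a regime in which the best low-rank approximation is
ill-posed (weights diverge in canceling pairs) and seed-to-seed estimates
are unstable. In other words, per-recording z-scoring erases the very
amplitude signal the impact statistic is designed to measure.

The pipeline therefore uses a chemometrics-standard hybrid
(`channel_scale="pooled"`, the default): **center each channel within its
recording** (removes baseline offsets; exactly re-expresses the CP model
through centered temporal factors), then **divide each channel by its
standard deviation pooled across all recordings** (puts the 35 sensors on a
comparable unit without equalizing gear amplitudes; an exact rescaling of
the channel factors). Both steps map a CP tensor to a CP tensor with known
factors, so ground-truth impacts remain closed-form on the analysis scale.
Per-recording z-scoring remains available (`channel_scale="per_recording"`)
for comparison.

## Decomposition

`cp_als` implements CP/PARAFAC by alternating least squares: each factor is
the solution of the normal equations with the Hadamard Gram identity
(ZᵀZ = (BᵀB)∗(CᵀC) for the Khatri-Rao design), a 1e−12 ridge guarding
rank-deficient iterates, MTTKRPs by `einsum`. Initial factors are i.i.d.
uniform(0,1) from a seeded generator; the seed is stored in the model.
After the final sweep columns are normalized to unit norm with magnitudes
absorbed into the weights, and signs are flipped so the largest-magnitude
entry of each time and channel column is positive (compensated in the gear
column, so the reconstruction is unchanged and reports are stable).

Convergence: stop when the change in relative reconstruction error between
sweeps falls below `tol` (default 1e−7) or after `max_iter` (default 500)
sweeps. The error is tracked through the Gram identity
‖X−X̂‖² = ‖X‖² − 2⟨X,X̂⟩ + ‖X̂‖², accurate to ~√machine-epsilon — the ALS
objective itself is non-increasing, and tests assert that up to this
measurement precision. The rank sweep fits every (rank, seed) pair with a
shared seed set (`base_seed + index`); the elbow of the mean VEC curve is
the point of maximum distance to the chord joining the normalized curve's
endpoints, with a fallback rank (default 10) when the curve is linear to
within tolerance.

## Impact and severity

Per fitted model, gear impact is I_k = ‖ω ∘ C_k‖₂. Across the seeds of one
rank, the mean impact and an empirical 95% CI (2.5/97.5 percentiles of the
per-seed values; a normal-approximation variant is available — the
percentile default reflects that the interval is meant to describe
seed-to-seed dispersion of the decomposition, not estimation error of the
mean). The severity scale fixes the baseline at the gear with minimum
*mean* impact (a per-seed baseline would make its own 0% ill-defined),
reports 100·(Ī_k − Ī_base)/Ī_base, and takes CIs from the per-seed relative
differences with the baseline gear's seed series held fixed; negative CI
bounds are reported as-is. Impacts scale linearly with the tensor, so the
severity percentages are scale-invariant.

## Synthetic data

The generator emulates the study design (2600 × 35 × 8 gears × 10
replicates by default) with known CP ground truth:

- **Temporal mode:** a saturating rise (first-order uptake) plus smooth
  release pulses staggered across the window. Widths are floored so that a
  clean series never trips the Tukey fences by its own shape, and the set
  is redrawn while any pairwise correlation is ≥ 0.9 (near-collinear
  kinetics make the decomposition ill-conditioned).
- **Channel mode:** each latent volatile pattern excites its own random
  subset of sensors strongly over a weak cross-sensitive background,
  mirroring partial MQ selectivity and keeping the mode well-conditioned.
- **Gear mode:** unit loading directions vary smoothly with the configured
  impact target (gears of similar severity have similar profiles, which is
  what makes confusion-matrix structure track physiological similarity),
  plus enough per-gear scatter to keep the gear mode identifiable.
- **Calibration:** loading-row scales are fixed-point iterated until the
  *analysis-scale* impacts (after per-recording centering and pooled
  channel scaling, both closed-form factor transformations) equal
  `calibration × impact_targets` to 1e−13. The analysis scale fixes
  absolute impact units, so targets are realized up to one positive
  constant (stored in the truth object); relative severities are realized
  exactly. The raw signal amplitude is pinned so the clean signal's average
  channel sd is 1, making `noise_sd` a signal-relative quantity.
- **Perturbations:** replicate variation is multiplicative Gaussian jitter
  on the loading row (sd 0.02 — the variance structure of real replicates
  is not characterized, so the simplest multiplicative model was chosen);
  measurement noise is i.i.d. Gaussian (sd 0.05); missing cells are MCAR
  (rate 0.01); outlier spikes multiply the stored value by 5 (rate 0.005).
  Injected positions are recorded for mask bookkeeping tests.

Default impact targets follow the built-in severity hierarchy
(longline-lowest 164 a.u. … aquaculture-highest 247 a.u.); the two
lowest-impact methods sit 1.2% apart, and the generator faithfully
reproduces the consequence that they are not reliably distinguishable under
noise. Recovery tests therefore use a variant target set with ~10–13% gaps
when exact ordering is asserted.

**What the generator does not emulate:** sensor drift and heater cycles,
humidity/temperature covariates, autocorrelated (non-white) noise,
replicate-level biological covariates (weight, sex), non-MCAR missingness,
and any departure of real VOC kinetics from smooth low-rank structure.
Passing tests demonstrate the correctness and stability of the *analysis*
under the stated generative assumptions, not the field performance of the
sensor system.

## Classification

One observation per time instance. Splits are stratified by label at
65/25/10 (train/validation/test, floor-rounding residue to train),
deterministic per seed; a group-aware variant assigns whole recordings to
one partition, because row-level splits of time series leak
autocorrelation — the row-level default mirrors the reading-level protocol
this package emulates, and the leakage caveat applies equally to its
headline accuracies.

- **Subspace KNN:** 30 learners, each a k-NN (k = 1) on an independently
  drawn feature subset of size ⌈p/2⌉ (conventional defaults for the preset;
  neighbour search via `scipy.spatial.cKDTree`); majority vote, ties to the
  earlier class in the configured gear order.
- **Kernel naive Bayes:** per class × feature Gaussian KDE, Silverman's
  rule bandwidth (Scott's rule available), floored at 1e−6 of the global
  feature sd for zero-variance cells; argmax of log-prior plus summed
  log-densities.
- **Subspace discriminant:** random-subspace ensemble of pooled-covariance
  linear discriminants with 1e−6·tr(Σ)/d ridge (escalated ×1000 on
  singularity), combined by averaging class posteriors.

Evaluation reports accuracies in percent, K×K confusion matrices (rows =
true, gear order fixed) and macro precision/recall/F1. Feature importance
is Monte-Carlo permutation-sampling Shapley: per observation, the value
function is the model's score for that observation's predicted class, with
absent coalition features replaced from a random background row; reported
as the mean absolute value over observations. The estimator is validated
against brute-force coalition enumeration on a 3-feature additive model.

## Problem sizes

Tests and the acceptance script run the study at reduced scale — 60–300
time instances, 2–3 replicates, rank sweeps to 8 with 5–10 seeds — chosen
so the full suite completes in a few minutes while every structural claim
(recovery, ordering, accuracy bounds) is still exercised end to end; the
defaults of `SimulationConfig`/`RunConfig` remain at the full campaign
scale (2600 instances, 10 replicates, ranks 1…50 × 100 seeds = 5000 fits).

## Known limitations

- The impact statistic depends on the CP normalization convention and, at
  ranks far above the elbow, on weakly identified components; it is
  meaningful only alongside its seed-averaged CI.
- The elbow criterion is a heuristic; curves without curvature fall back to
  a configured default rank.
- Kernel naive Bayes prediction is O(n_train · n_predict · p) and is the
  slowest of the three model families at full scale.
- Classifier accuracies on synthetic data are optimistic wherever real
  recordings would violate the generator's assumptions (see above), most
  notably through row-level split leakage on autocorrelated series.
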