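# Methods

`docmark` implements a two-arm prognostic analysis for acute disorders
of consciousness (DOC): a bedside electrodermal marker of residual
lexical–semantic processing, and a resting-state fMRI marker of local
low-frequency activity, linked by a regression. This note documents the
models, the defaults and why they were chosen, the synthetic-data
design, and the numerical conventions.

## 1. Event-related electrodermal scoring

Subjects hear 30 emotionally salient words and 30 pseudo-words in
random order, one stimulus every 12 s, while skin conductance is
recorded (microsiemens; nominally 500 samples/s in acquisition,
rate-agnostic in analysis).

**Per-trial score (peak-to-base).** For onset *t₀*,

    raw = max{ x(t) : t ∈ (t₀, t₀ + 8 s] } − mean{ x(t) : t ∈ [t₀ − 3 s, t₀) }

The post-stimulus window is open at the onset and closed at +8 s; the
baseline is closed at −3 s and open at the onset, so no sample belongs
to both windows. Negative scores are retained — the z-scoring below
assumes signed values. No filtering or response-latency gating is
applied by default: the 5-Hz low-pass belongs to acquisition, and the
full (0, 8] s search window is used because any minimum-latency rule
would be an extra assumption.

**Within-subject normalisation.** All 60 trial scores are pooled across
both conditions and converted to z-scores with the population
(n-denominator) SD — the trials are a fixed finite set, not a sample
from a superpopulation. Pooling is essential: per-condition z-scoring
would force both condition means to 0 and destroy the contrast.
Subjects whose trial scores have zero variance are flagged as
degenerate and excluded, never silently zeroed.

**SCR delta index.** δ = mean(z | word) − mean(z | pseudo-word). With
equal condition counts the two means are opposite in sign, so δ is
twice the word mean. δ is dimensionless, invariant under any
positive-gain affine transform of the raw trace, and antisymmetric
under swapping the condition labels. Trials with no discernible
response are kept; no response-detection heuristic is applied.

## 2. Prognostic inference

Patients are labelled by 6-month Glasgow Outcome Scale–Extended:
GOS-E ≤ 2 → outcome-negative, > 2 → outcome-positive.

The inferential sequence on the cohort's delta indices:

1. healthy-control median δ̃ (sample median, mean-of-central-two for
   even n) as the reference value;
2. one-sample Wilcoxon signed-rank test of each patient subgroup
   against δ̃;
3. Mann–Whitney U between the two subgroups;
4. for healthy controls, a paired t test of mean word-z vs
   pseudo-word-z, complemented by a JZS Bayes factor.

**Rank tests.** Zero differences are dropped before ranking; tied
absolute differences get average ranks. Two p-value routes are
provided and recorded in the result:

* *exact* — the full permutation null of the observed (average) ranks:
  all 2^m sign assignments for the signed-rank test (computed by
  convolution over trials, identical to literal enumeration; limit
  m ≤ 20) and all C(n+m, n) group assignments for Mann–Whitney
  (limit n + m ≤ 12). Two-sided p = 2·min(lower tail, upper tail),
  capped at 1. Valid under ties.
* *asymptotic* (default) — normal approximation with tie-corrected
  variance. A continuity correction is applied by default;
  `continuity=False` reproduces the SPSS-style Z that small-sample
  clinical reports print (an exact two-sided p at n = 5 cannot fall
  below 1/16, so printed values such as p = 0.043 at Z = −2.02 can
  only come from the uncorrected approximation). The exact route is
  recommended at small n whenever matching legacy software output is
  not the goal.

Fully tied Mann–Whitney inputs put U exactly at its null mean; this is
reported as Z = 0, p = 1 rather than an error. No multiple-comparison
correction is applied across the three subgroup tests.

**JZS Bayes factor.** For a one-sample/paired t value with sample size
n, the alternative places a zero-centred Cauchy prior (scale r = 1/√2,
the common default of Bayesian t-test software; configurable) on the
standardised effect size. BF₁₀ is the noncentral-t likelihood averaged
over the prior by adaptive quadrature, divided by the central-t
likelihood. The result is prior-dependent: with the default scale,
t(34) = 7.52 yields BF₁₀ ≈ 1.31 × 10⁶.

**Spearman correlation.** Pearson correlation of average-ranked data;
p from the t approximation with df = n − 2; one-sided tests halve the
two-sided p on the positive side. The zfALFF-vs-delta association is
one-tailed (a directional hypothesis: more autonomic responsiveness,
more local low-frequency activity); everything else is two-sided.

## 3. fALFF mapping

For each in-mask voxel time series (length ≥ 16; default study scale
200 volumes at TR = 3 s): linear detrend (default), single-taper
discrete-Fourier amplitude spectrum (square root of the periodogram; no
Welch averaging or tapering, matching the standard toolbox convention),
then

    fALFF = Σ amplitudes in [0.01, 0.08] Hz / Σ amplitudes in (0, Nyquist]

The DC bin is excluded from both sums, making the measure
offset-invariant; it is scale-invariant by construction. The ratio is
of amplitudes (root power) by default — the convention of the standard
fALFF implementations — with a raw-power ratio available
(`mode="power"`). The band is configurable because the literature uses
both 0.01–0.08 Hz (the filtering band, our default) and 0.01–0.1 Hz
(the definitional band); the discrepancy is preserved, not silently
resolved. Voxels with (numerically) zero spectral content map to
fALFF = 0 so downstream statistics stay finite; a relative floor of
1e−9 of the DC amplitude absorbs rFFT rounding residue on constant
series.

Maps are z-transformed within the brain mask (in-mask mean 0,
population SD 1) before any group statistic (zfALFF).

White-noise calibration: the expected fALFF of white noise equals the
in-band bin fraction — 43 of 100 positive-frequency bins at TR = 3 s
and 200 volumes (Δf = 1/600 Hz).

## 4. Voxel-wise permutation inference

Both group-level analyses are permutation-based (max-statistic /
SnPM-style), including the group contrast for which parametric
random-field correction would otherwise be typical: RFT needs a
smoothness estimate that is not available here, while permutation only
assumes exchangeability. Connectivity is 18-neighbour by default (the
SPM convention; 6 and 26 available).

**Group contrast.** Pooled-variance two-sample t per voxel
(df = nA + nB − 2), one-sided per contrast direction (each direction
is tested separately). Cluster-forming threshold: the upper t quantile
at p = 0.001. The null distribution of the maximum suprathreshold
cluster extent is built by relabelling subjects across groups —
exhaustively when C(N, nA) ≤ n_perm (results are then order- and
seed-independent), otherwise n_perm seeded draws with the observed
labelling always included, so no corrected p can fall below
1/n_perm. Cluster p_fwe = proportion of null maxima ≥ the observed
extent. Peak coordinates are reported in world (RAS) mm via the
affine.

**Covariate regression.** Per-voxel simple-regression t of zfALFF on
the SCR delta index (df = n − 2), two-sided; voxel-level FWE from the
permutation null of the map-wide max |t| under covariate shuffling.
Both the peak voxel and cluster/ROI means are exposed for follow-up
correlations, since published reports are ambiguous about which is
quoted.

**Calibration regime.** Cluster-extent inference presupposes spatially
smooth fields. The calibration suite therefore simulates null maps at
a Gaussian smoothness of σ = 1 voxel (≈ 7 mm FWHM at 3 mm voxels,
typical of preprocessed BOLD); there both the cluster-level and
voxel-level FWE rates at α = 0.05 fall inside the exact binomial 95%
band around 0.05 (500 simulations × 500 permutations, 16³ lattice,
n = 8 per group). On spatially *independent* noise the suprathreshold
extents at p < 0.001 are almost all 0 or 1 voxel, and the — still
valid — cluster test rejects far below α by discreteness; users
applying the cluster route to unsmoothed data should expect strong
conservatism.

## 5. Synthetic cohorts

The generator produces data with the statistical structure the
analysis assumes, at study scale by default: 35 healthy controls, 10
outcome-positive and 5 outcome-negative patients; GOS-E sampled
uniformly in 3–8 / 1–2 respectively so the threshold classifier is
exercised across its range. Everything is determined by (spec, seed).

**Electrodermal traces.** Tonic level 2 µS plus a slow random-walk
drift (0.02 µS/√s) plus one phasic response per stimulus: a
bi-exponential kernel (rise τ₁ = 0.75 s, decay τ₂ = 4 s,
peak-normalised, ~2 s latency — placing peaks well inside the 8-s
window) scaled by a per-trial amplitude drawn around the condition
mean (fractional SD 0.8, floored at 0), plus white noise (0.05 µS).
Default sampling rate is 50 Hz for test speed; scoring is
rate-agnostic and 500 Hz is supported. Condition means: healthy and
outcome-positive 0.30 µS (word) vs 0.20 µS (pseudo-word);
outcome-negative 0.25/0.25 (no effect). These defaults give healthy
delta indices of ≈ 0.5 ± 0.2 — the same order as published
healthy-control values, with the trial-to-trial variability dominating
the condition gap as real electrodermal data do.

**Resting volumes.** 16³ voxel lattice (down from acquisition size so
permutation suites run in minutes), 200 volumes at TR = 3 s retained
at full length because frequency resolution drives fALFF. AR(1)
temporal noise (φ = 0.3, SD 0.5) inside an ellipsoidal brain mask;
inside a spherical "PCC" blob (radius 3 voxels) a sinusoid at 0.03 Hz
with amplitude `blob_amp_base + coupling · δ` (floored at 0) and a
seeded random phase. Controls: base 1.0, coupling 4.0. Patients:
base 0.0, coupling 2.0 — a group-level loss of baseline low-frequency
amplitude with a delta-proportional residual, so the generator
reproduces both target phenomena: a controls > patients cluster at the
blob, and a positive within-patient zfALFF–delta association.

**What the generator does not model** (hence what passing tests do not
show about real data): hemodynamic convolution, cardiac/respiratory
noise, head motion, spatial autocorrelation of the BOLD noise
(simulated volumes are spatially independent; the calibration suite
adds smoothness explicitly), lesions, electrode artifacts, and
habituation of electrodermal responses over the session.

## 6. Problem sizes and determinism

Default test-suite problem sizes: 60-trial schedules, 50-subject
cohorts, 16³ × 200 volumes, 300–500 permutations, 50 master seeds for
recovery rates, 500 simulations for calibration — chosen so the full
suite runs in a few minutes on one core while keeping Monte-Carlo
error well inside the asserted tolerances. All randomness flows
through explicit integer seeds (NumPy `default_rng` / `SeedSequence`);
repeated runs are bit-identical, and generated cohorts on disk carry a
manifest recording the spec and seed.

## 7. Known limitations

* The exact Mann–Whitney route is enumeration-bound (n + m ≤ 12);
  larger samples use the tie-corrected normal approximation.
* The Bayes factor reproduces standard-software values only under the
  default prior scale; published values rarely state the prior.
* Permutation p-values are Monte-Carlo estimates when not exhaustive;
  doubling n_perm perturbs p_fwe by ~2·√(p(1−p)/n_perm).
* fALFF is computed from a single periodogram; no multitaper variance
  reduction is attempted.
* The pipeline assumes preprocessed, spatially normalised volumes;
  no realignment, nuisance regression, normalisation or smoothing is
  performed.
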