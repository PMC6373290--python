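# Methods

This note documents the models and procedures implemented in `imikin`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Preprocessing

**Despiking.** Electromagnetic trackers occasionally emit single-sample
position spikes. The detector double-differences each coordinate axis
(successive first-order differences, length n−2) and flags samples whose
double-differenced value deviates more than `spike_sd_threshold` (default 3)
SDs from that trace's within-trial mean. A flagged sample is attributed to
the centre of the second difference, and repaired — on all three axes, since
the artifact hits the sensor, not an axis — by linear interpolation bridging
from `interp_halfwidth` (default 3) samples before to the same number after.
An absolute floor of 1e−9 cm on the threshold keeps machine-precision
residue on perfectly smooth traces from registering as spikes. The criterion
is applied per axis with an any-axis trigger; pooling axes first would be a
defensible alternative, and the halfwidth/threshold are config-exposed so
the choice can be audited.

Note a structural property of this (standard) criterion: on noise-free
traces the double-differenced SD collapses and genuine movement curvature
can exceed 3 SD. With realistic sensor noise (≥ 0.01 cm) the noise term
dominates the double-differenced trace and only true spikes are flagged.

**Filtering.** Bidirectional (forward–backward) Butterworth low-pass,
4th order, 12 Hz cutoff at 240 Hz sampling, applied per axis via
second-order sections. Two passes square the single-pass magnitude response
(|H|² = 1/(1+(f/fc)⁸) in the analog prototype, frequency-warped digitally)
and cancel the phase exactly; DC gain is exactly 1. Edges use scipy's
odd-reflection padding (well above 3× the filter order); edge transients
decay within ~100 samples, which matters only for properties asserted near
trace boundaries.

**Exclusion rules.** A trial is excluded when, for either person: the
movement lasted < 400 ms (`too_short`); the movement onset preceded that
person's go tone (`false_start`, displacement-threshold criterion — the
onset is the segmented one, see below); or the speed never settled below the
offset threshold before the recording ended (`unfinished`). A missing wrist
tracker excludes the trial (`missing_tracker`); any unexpected stage error
excludes it (`pipeline_error`). Exclusion only changes validity state —
sample data are never mutated. Residual per-tracker artifacts are handled by
an explicit flag interface (`drop_artifact_trackers`) rather than visual
inspection, for reproducibility; dropping a wrist excludes the trial.

## Movement segmentation and kinematic markers

Scalar speed is the Euclidean norm of the per-axis first derivative
(central differences, one-sided endpoints) of the filtered positions. No
additional smoothing precedes differentiation; the 12 Hz filter already
conditions the trace.

Onset is the first sample where speed exceeds `onset_speed_fraction`
(default 0.05) of the trace's peak speed and stays above for `min_above_ms`
(default 50 ms); offset is the first sample after the global peak where
speed falls below the same threshold and stays below for the same dwell
time (a shorter below-run that reaches the end of the trace counts). The
5%-of-peak rule with a dwell hysteresis is the standard reach-kinematics
convention; published studies rarely state their exact rule, so both
parameters are config-exposed and the sensitivity is testable.

Markers: PV is the speed maximum in [onset, offset]; MT the window duration;
TPV/MT the peak-velocity time as a fraction of MT; TPD/MT likewise for the
minimum of the first derivative of scalar speed in (t_PV, t_offset] — a
speed-profile landmark, deliberately not the norm of the 3D acceleration
vector, which has no sign. Digit PV subtracts the wrist position sample-wise
from each digit, takes each available digit's relative-speed maximum over
the wrist's window, and averages across available digits (absent digits are
absence, not zeros).

## Actor–imitator correspondence

Each person's movement window comes from their own wrist segmentation and is
applied to all of that person's trackers, so every tracker is scored over
the same primary-movement interval. For each shared tracker the Pearson
correlation between the two windowed speed profiles is computed at every
integer lag in ±|n_i − n_a| (the movement-length difference), over the
overlapping region only — zero-padding would bias r toward 0 at large lags.
Ties break toward the smallest |lag|. Lags with < 3 overlapping samples or
zero variance are skipped; if all are skipped the tracker is skipped with a
log entry. r is Fisher-transformed; callers clamp |r| ≥ 1 (noiseless
duplicates) to 1−1e−9 with a logged warning. Per-tracker analyses divide α
by 8, the tracker count.

"Velocity curves" are scalar speed profiles, giving one r per tracker per
trial; correlating concatenated per-axis velocities is a coordinate-frame-
dependent alternative we rejected.

## Inference

All three factors have two levels, so each within-subject effect has 1
numerator df, its error term is the effect × subject interaction (df n−1),
and sphericity is trivial — no Greenhouse–Geisser machinery. For contrast
codes e ∈ {−1,+1}⁸ the implementation uses SS_eff = n·L̄²/8 and
SS_err = Σ(L_s−L̄)²/8 with L_s the per-participant contrast total; each F
equals the squared paired t on the corresponding contrast scores (asserted
to 1e−10 in tests), and the full decomposition conserves SS_total. Sums of
squares below 1e−12 of SS_total are treated as exact zeros so duplicated
factor levels yield F = 0 rather than 0/0 noise. p-values come from the
exact F and t distributions, matching parametric reporting practice. A
missing participant × condition cell raises an error naming the participant
and cell; no imputation.

The paired effect size is the repeated-measures Hedges g given in the
README; the estimator family for "g_rm" varies across the literature, so
the formula is documented and implemented in one place (`hedges_g_rm`).
Its sign follows the t statistic. Identical paired vectors return t = 0,
g = 0; a constant non-zero difference has no variance to test against and
raises instead.

## Synthetic-data generator

The generator's defaults are the study conditions: 12 participants, two
sessions (stimulation sites, order counterbalanced by participant parity),
two action-meaning blocks per session (order counterbalanced), 64 trials
per block with hand/finger pseudorandomly interleaved, 240 Hz, go tone at
1000 ms and stop tone at 3000 ms within each person's 3250 ms epoch.
Per-condition means of PV/MT/TPV (and relative digit PV) follow the
meaningful/meaningless × hand/finger cell structure of the emulated
experiment with small site offsets (e.g. PV 76.6/82.3/55.7/56.7 cm/s, MT
833/897/736/750 ms, TPV .412/.381/.426/.415, digit PV 72.6/66.3 cm/s);
between-participant offsets (SDs ~10.5 cm/s, 70 ms, 0.025) and
trial-to-trial SDs (6 cm/s, 50 ms, 0.02) produce realistic
between-participant standard errors for the condition means. Contamination rates (.08/.07/.08 for too-short/false-start/
unfinished) give an expected retention of 78.7%.

**Speed profiles.** Wrist speed is a beta-family bell
v(s) ∝ sᵃ(1−s)ᵇ with a+b = `shape_k` (default 8, chosen so integrated path
lengths land near 27 cm for hand and 19 cm for finger gestures at the
default PV·MT). `make_speed_profile` supports two referencings: literal
(support exactly [0, MT], peak at tpv·MT) and threshold-referenced (used by
the generator), in which MT and TPV are defined at the segmenter's 5%
crossings and sub-threshold tails extend the support. The latter is what
makes commanded markers recoverable without bias: a threshold segmenter
clips ~25% of a literal bell's support, so a generator that commands
literal-support markers would systematically disagree with any
threshold-based pipeline.

**TPD is emergent**, not commanded: it follows from the bell's asymmetry
(≈ .69 at the default shapes), and shape perturbation adds jitter to it.

**Actor–imitator coupling.** The imitator's profile is the bell for the
imitator's sampled parameters (the actor's profile warped to them), then
decorrelated toward the configured target correlation by two
marker-preserving perturbations: a smooth random time-warp pinned to zero
displacement at the two threshold crossings and the peak (tempo variation),
plus bounded smooth "sub-movement" bumps whose envelope keeps the speed
strictly inside (1.5×threshold, 0.93×PV) wherever it acts. A single scale
drives both and is calibrated per trial by bisection on the quantity the
analysis actually reports — the maximum lagged correlation against the
actor's windowed profile. Because any two single-peaked profiles are
strongly correlated, the family has a floor near r ≈ 0.92; targets below it
saturate, and the realized clean-profile correlation is recorded per trial
in the ground truth (`clean_r`). Additive unconstrained speed noise was
rejected: reaching low correlations additively requires noise power that
drags the threshold crossings and biases MT by tens of ms.

**Lag.** A pure onset delay is invisible to per-movement-window
cross-correlation (each window starts at its own onset), so `lag_mean_ms` /
`lag_sd_ms` (defaults 0/25 ms) shift the imitator's peak within its window —
a soft control. The ground-truth lag is *defined* operationally: the lag at
maximum correlation between the clean (pre-sensor-noise) windowed profiles,
found by exhaustive scan at generation time. Recovery is judged against that
record.

**Noise and artifacts.** Gaussian sensor noise (default 0.05 cm, the
realistic electromagnetic-tracker regime) on every sample; Bernoulli
single-sample spikes (default probability .01 per tracker-trial, 10 cm).
The `low_noise()` preset (0.01 cm, no contamination) is the parameter-
recovery regime: an error-propagation estimate puts threshold-crossing
jitter at ~0.5 samples there, which ±1-sample lag recovery requires.
Contaminated trials are realized physically (short movement, onset before
the tone, movement truncated by the epoch end), so the exclusion rules fire
on real features, not labels.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: multi-peaked gesture trajectories and sub-movement
structure beyond the injected bumps, postural/biomechanical constraints,
orientation channels, actor–imitator spatial mirroring, non-Gaussian sensor
noise, drift, or any neural effect of stimulation (site is a pure label with
configurable effects on condition means). Wrist-level correlations in real
data can be lower than the generator's floor when imitations genuinely
differ in gross structure.

## Problem sizes

The default test suite analyses up to 1536 trials end to end (the
parameter-recovery dataset: 12 participants × 8 conditions × 16 trials) and
runs 2000 null ANOVA replicates; the acceptance script analyses the full
3072-trial design plus the recovery dataset. These sizes were chosen to
give binomial/SE tolerances meaningful power while keeping a complete run
in the minutes range on one CPU.

## Known limitations

- The segmentation rule (5% of peak, 50 ms dwell) is a convention; datasets
  analysed with a different unstated rule will disagree on MT/TPV/TPD at the
  percent level. Both parameters are exposed in `SegmentationConfig`.
- The correlation floor of the marker-preserving perturbation family means
  very poor imitation (r < ~0.9 at the wrist) cannot be synthesized without
  giving up commanded-marker exactness.
- `paired_t_grm`'s g_rm is one member of a family of repeated-measures
  effect sizes; published values computed with a different denominator can
  differ by a scale factor even at identical t.
- The canonical trial CSV stores positions only; orientation channels are
  accepted and carried but unused by every analysis.
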