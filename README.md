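# imikin — kinematics of two-person gesture imitation

`imikin` is a tested, reusable analysis pipeline for dyadic imitation
experiments recorded with multi-tracker motion capture (e.g. an 8-trackers-
per-person electromagnetic system at 240 Hz). One person (the actor)
performs a hand or finger gesture; a second person (the imitator) copies it.
The package turns the raw per-trial position traces into the quantities such
studies report:

- **Correction-time kinematic markers** of the imitator's wrist — movement
  time (MT, ms), peak velocity (PV, cm/s), and the times of peak velocity
  and peak deceleration as fractions of MT (TPV/MT, TPD/MT). The interval
  after peak deceleration is the feedback-driven *correction phase*; lower
  TPV/MT and TPD/MT mean proportionally more of the movement is spent
  correcting.
- **Imitation fidelity** — for every tracker carried by both people, the
  maximum lagged Pearson correlation between the actor's and the imitator's
  scalar speed profiles over their primary movements, with the lag at the
  maximum. With movement lengths `n_a` and `n_i`, every integer lag in
  `±|n_i − n_a|` is scanned and the correlation at each lag is computed over
  the overlapping region. r values are Fisher-transformed,
  `Z = ½ ln((1+r)/(1−r))`, before averaging and testing.
- **Inference** — 2×2×2 within-participant ANOVAs (stimulation site ×
  action meaning × effector) on participant × condition cell means, with
  `F = MS_effect / MS_effect×subject`, partial η² = SS_eff/(SS_eff+SS_err),
  Bonferroni-gated two-tailed paired t tests (α = .05/8), and a
  repeated-measures Hedges g,
  `g_rm = (m₁−m₂)/√(s₁²+s₂²−2·r·s₁·s₂) · √(2(1−r)) · (1 − 3/(4(n−1)−1))`.

Preprocessing follows standard electromagnetic-tracker practice: single-
sample spikes (> 3 SD on the double-differenced trace) are repaired by
linear interpolation bridging three samples either side; traces are filtered
with a bidirectional (zero-phase) 4th-order Butterworth low-pass at 12 Hz;
trials are excluded when either person moved for less than 400 ms, started
before their go tone, or failed to finish before the end of the recording.

A first-class synthetic-data generator emulates the full study design
(12 participants × 2 sites × 2 meaning blocks × 64 trials with hand/finger
interleaved), with per-condition kinematic means, actor–imitator coupling
with controllable correlation and lag, sensor noise, spikes, and
contaminated trials — every trial carries a ground-truth record, so the
whole pipeline is testable end to end with no data download.

## Worked example

```python
from imikin import GeneratorConfig, generate_experiment, run_pipeline

cfg = GeneratorConfig(n_participants=6, trials_per_block=16, seed=7)
trials, truth = generate_experiment(cfg)
result = run_pipeline(trials)

print(f"trials analysed : {len(trials)}, retained {100*result.retention_fraction:.1f}%")
```

prints, with the rest of the summary code in `scripts/acceptance.py`:

```
trials analysed : 384, retained 77.6%
wrist PV : hand    75.8 cm/s, finger    53.4 cm/s
wrist MT : hand   865.0 ms, finger   750.6 ms
effector effect on PV: F(1,5) = 1961.6, p = 1.1e-07, partial eta^2 = 0.997
wrist correspondence: mean r_max = 0.934, mean lag = +1.2 ms over 298 trials
```

Reading the output: 22.4% of trials were rejected by the three movement
rules (the generator injected contamination at matching rates); hand
gestures are faster and longer than finger gestures, so the effector effect
on PV is large; and the imitator's wrist speed profile correlates ~0.93 with
the actor's at a lag near zero.

The same analyses run from the shell:

```
imikin generate --config gen.yaml --out data/
imikin run --data data/ --out results/
imikin report --results results/
```

All outputs are tidy CSVs (per-trial kinematics, per-tracker correspondence,
participant × condition cell means, ANOVA and contrast tables, exclusion
summary).

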