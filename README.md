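# locomod

Space-by-time modular analysis of trial-to-trial variability in infant
locomotor EMG.

## The problem

During early locomotor development (neonatal stepping and kicking through
independent walking), leg-muscle activity is thought to be generated by a
small set of invariant building blocks — *motor primitives* — combined with
cycle-varying gains. `locomod` is for motor-control researchers who want to
quantify, from multi-muscle surface EMG of cyclic flexion–extension
movements, (a) how many primitives are needed to explain the signals,
(b) how variably those primitives are recruited from cycle to cycle, and
(c) how selective the primitives themselves are.

## The model

Each flexion–extension cycle *s* yields a phase-normalized envelope matrix
`m_s` (200 time points × M muscles). The space-by-time decomposition writes

    m_s(t) = Σ_{i=1..P} Σ_{j=1..N}  w_i(t) · a_{i,j,s} · w_j  +  r_s(t)

with `w_i(t)` the P temporal modules (invariant activation waveforms),
`w_j` the N spatial modules (invariant muscle weighting vectors), and
`a_{i,j,s} ≥ 0` the per-cycle activation coefficients — the only
cycle-varying part. Fitting is non-negative tri-factorization by
alternating multiplicative updates, restarted 50 times from random
initializations; goodness of fit is the variance accounted for

    VAF = 1 − Σ_s ‖r_s‖²_F / Σ_s ‖m_s − m̄‖²_F

with `m̄` the grand-mean activity level. The number of modules is the
smallest `P = N` whose VAF crosses 0.75; a fixed `P = N = 4` fit (adult
walking dimensionality) serves as a control.

Derived indices (all defined in `locomod.indices`):

| Index | Meaning |
|-------|---------|
| IEV   | mean pointwise SD of the envelope across the five cycles |
| IRV   | mean SD of activation coefficients across cycles |
| IRS   | mean Hoyer sparseness of each cycle's activation matrix (pair selectivity) |
| SMAI  | mean Hoyer sparseness of spatial modules (few vs many muscles) |
| STAI  | mean Hoyer sparseness of temporal modules (narrow vs wide peaks) |

Preprocessing follows the standard chain for this analysis: 40 Hz
fourth-order Butterworth high-pass (zero-phase), rectification,
moving-median smoothing with an age-scaled window (400/200/100 samples for
newborns / 3-month-olds / toddlers at 2000 Hz), selection of *alternated*
cycles (hip-flexion onset between 10% and 90% of the contralateral cycle,
run edges excluded), time normalization to 80 flexion + 120 extension
points, and per-muscle amplitude normalization over each five-cycle
ensemble. When more than five cycles are available, the analysis runs on
five random combinations of five cycles and averages the indices, so
reported module counts can be decimal.

A synthetic-data generator (`locomod.synthgen`) renders both envelope
tensors and raw-like EMG (band-limited carriers modulated by envelopes
built from known modules) with matching bilateral event streams, so the
whole pipeline is testable against known ground truth.

## Worked example

```python
import numpy as np
import locomod as lm

# synthesize a dataset with 3 known modules and 7 rendered cycles
spec = lm.SynthSpec(n_spatial=3, n_temporal=3, n_cycles=7,
                    activation_jitter=0.3, spatial_sparsity=0.4,
                    temporal_peak_width=0.3, seed=5)
gt = lm.generate_ground_truth(spec)
durations = 1.5 * np.random.default_rng(5).uniform(0.95, 1.05, 7)
recording, events = lm.render_raw_recording(gt, 2000.0, durations,
                                            np.full(7, 0.4))

config = lm.RunConfig(age_group="newborn", master_seed=2,
                      n_restarts=5, max_iter=300, tol=1e-5,
                      rank_range=list(range(1, 6)))
result = lm.run_dataset(recording, events, config)
s = result.summary
print(f"n_modules={s.n_modules:.1f}  VAF={s.vaf:.3f}  IEV={s.iev:.4f}")
print(f"IRV={s.irv:.4f}  IRS={s.irs:.3f}  SMAI={s.smai:.3f}  STAI={s.stai:.3f}")
```

prints

```
n_modules=2.0  VAF=0.764  IEV=0.0722
IRV=1.2488  IRS=0.585  SMAI=0.310  STAI=0.292
```

Seven rendered cycles leave exactly five analyzable ones (the first and
last cycle of an alternating run are never used), so a single five-cycle
combination is analyzed. The VAF crossed the 0.75 threshold at rank 2:
with overlapping temporal bumps, two module pairs already explain more
than 75% of the variance of the planted rank-3 structure. The remaining
numbers describe that rank-2 fit — sizeable cycle-to-cycle recruitment
variability (IRV), moderate pair selectivity (IRS), and fairly dense,
broad modules (low SMAI/STAI), as expected for a generator configured
between the extreme neonatal-like and toddler-like regimes.

The same stages are available from the shell:

```sh
locomod simulate --seed 5 --out data/demo
locomod analyze --recording data/demo/recording.tsv \
                --events data/demo/events.csv --out demo_report.json
```

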