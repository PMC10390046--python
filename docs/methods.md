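# Methods

This note documents the models, numerical choices and limitations of
`locomod`. It is the package's own account; every number quoted here is
computed by the test suite or the example code, not asserted.

## The space-by-time model

A dataset is a set of S flexion–extension cycles, each reduced to a
200 × M non-negative envelope matrix `m_s`. The model is

    m_s = T · A_s · W + r_s

* `T` (200 × P): temporal modules, invariant non-negative activation
  waveforms over the normalized cycle;
* `W` (N × M): spatial modules, invariant non-negative muscle weightings;
* `A_s` (P × N): non-negative activation coefficients, the only part
  allowed to vary from cycle to cycle;
* `r_s`: residual.

The model deliberately confines trial-to-trial variability to the
activations: if the data are well explained with small residuals, the
cycle-to-cycle differences in the EMG are attributable to variable
*recruitment* of invariant primitives rather than to changing primitives.
The tri-factorization has an inherent scale ambiguity (any factor can be
rescaled against the others); solutions are therefore canonicalized with
unit-Euclidean-norm spatial rows and temporal columns, all scale absorbed
into the activations. This convention also makes IRV values comparable
across datasets. A per-cycle index interpretation note: the activation
tensor is stored P × N × S (temporal index first).

## Fitting

Alternating multiplicative updates cycle over (temporal, activations,
spatial). With the other two factors fixed, each subproblem is a linear
non-negative least-squares problem and the update is the standard
Lee–Seung multiplicative rule, so the squared residual is non-increasing
at every step (property-tested). Denominators carry an additive 1e-12
guard against division by zero.

* Initialization: factors uniform on (0.1, 1), then the activations are
  scaled by the closed-form global least-squares gain so the first
  reconstruction matches the data magnitude. Purely multiplicative updates
  cannot revive an exactly-zero entry; the strictly positive
  initialization avoids spurious locked zeros.
* Convergence: relative change of the squared residual below `tol`
  (default 1e-6), or `max_iter` (default 1000), in which case the solution
  is returned flagged `converged=False` with a logged warning.
* Restarts: 50 by default (the standard guard against local minima in
  this literature); the best-VAF solution is kept, ties broken by lowest
  restart index. Restart seeds are spawned from the master seed, so a
  fixed seed reproduces the decomposition bit for bit.
* Model selection: P = N swept upward from 1 until VAF ≥ 0.75 (threshold
  configurable); by default the sweep stops at the first crossing. If the
  threshold is never reached within the rank range, the result carries the
  full VAF trace and no chosen rank; the pipeline then computes indices
  from the largest rank tried and reports `n_modules` as NaN.

VAF is computed about the grand-mean activity level (a scalar over all
samples), so a reconstruction equal to that constant scores exactly 0 and
values can be negative for worse fits.

## Preprocessing

Order: high-pass filter → rectification → moving median → cycle selection
→ time normalization → amplitude normalization.

* Filter: 40 Hz corner, 4th-order Butterworth, applied forward-backward
  (`sosfiltfilt`). Zero-phase filtering avoids shifting envelope features
  relative to the video-coded events; the effective magnitude response is
  the squared single-pass response (the filter test accounts for this).
* Moving median: robust to contact artifacts; windows of 400/200/100
  samples for newborn/3-month/toddler data, i.e. proportional to the
  roughly twofold cycle-duration decrease at each stage. The printed even
  window lengths are used as given with a centered-left window; at the
  edges the window shrinks to the available samples.
* Cycle selection: cycles run BHF→BHF with the BHE inside. A retained
  cycle must (1) be preceded by an extension and succeeded by a flexion in
  the event stream, (2) start between 10% and 90% (inclusive, with a 1e-9
  float guard) of the contralateral BHF→BHF interval containing its onset,
  and (3) not be the first or last cycle of a maximal run of cycles
  passing (1)–(2).
* Time normalization: linear interpolation of the flexion phase to 80
  points (point 80 anchored on the BHE instant) and the extension phase to
  120 points, fixing all cycles to the phase proportions of independent
  walking so kinematic landmarks align across ages and behaviors.
* Amplitude normalization: per-muscle division by the maximum, taken over
  the five-cycle ensemble (default) or over the whole recording (the
  robustness variant). It is applied to the time-normalized ensemble so
  that the per-muscle ensemble maximum is exactly 1; for max-normalization
  this is equivalent to normalizing before time-warping up to
  interpolation-grid round-off. An all-zero muscle channel is a data
  error naming the muscle.
* Cross-talk screen: Pearson r between raw (pre-envelope) signals of
  agonist/antagonist pairs, flagged when r > 0.2 (strict, with a 1e-12
  rounding guard). The screen is advisory — it reports, it never excludes.

## Indices

All sparseness-based indices use the Hoyer measure
`(√n − ‖v‖₁/‖v‖₂)/(√n − 1)`, which is exactly 1 for a single-nonzero
vector, exactly 0 for a uniform one, and invariant to positive rescaling.
Standard deviations use the sample convention (ddof = 1) throughout — IEV,
IRV and the kinematic CV — configurable via the `ddof` argument. IEV is
the mean over all 200 × M pointwise SDs, reducing each ensemble to one
scalar; it is defined only on five-cycle ensembles because the fixed cycle
count is what keeps variability comparable across datasets. IRV is
computed on activations under the unit-norm factor convention and is not
normalized by mean activation. Best-matching-pairs module comparison uses
cosine similarity with greedy pairing (no reuse, ties to the first index);
raw similarities are reported without a "preserved/not preserved"
threshold.

## Pipeline protocol

Datasets with more than five analyzable cycles are analyzed as five random
distinct five-cycle combinations (seeded; fewer when fewer subsets exist),
and every index — including the selected module count — is the arithmetic
mean over combinations, which is why module counts can be decimal. Each
combination gets its own spawned fit seed, so the whole run is
deterministic under the master seed. The fixed P = N = 4 control fit and
its recruitment/shape indices are emitted alongside the threshold-selected
ones for every combination.

## Synthetic data generator

The generator is the forward model plus controllable knobs:

* Spatial modules: random non-negative unit vectors projected (Hoyer's
  alternating projection) to a target sparseness, so the knob sets the
  mean module sparseness essentially exactly.
* Temporal modules: truncated Gaussian bumps, FWHM `temporal_peak_width`
  of the cycle, centers spread evenly; unit-normalized. These match the
  peaked single-burst character of developmental temporal modules without
  claiming their exact shape.
* Activations: a base P × N matrix — one dominant entry per spatial module
  (`one_to_one`, selective recruitment) or dense (`multiplexed`) —
  perturbed per cycle by mean-one lognormal factors with underlying-normal
  SD `activation_jitter`.
* Envelope noise: additive Gaussian, clipped at zero to preserve
  non-negativity.
* Raw rendering: per-channel zero-mean Gaussian noise band-passed to
  60–500 Hz (above the 40 Hz high-pass corner, below Nyquist at 2000 Hz),
  amplitude-modulated by the envelope warped to requested per-cycle
  durations and flexion fractions. Bilateral BHF/BHE streams are emitted
  with the contralateral side offset by a controllable phase so the
  alternation filter can be driven to retain or reject cycles at will.

What the generator does *not* emulate: biomechanics (no musculoskeletal
model), electrode cross-talk, motion artifacts beyond what the median
filter is tested on, non-stationary carriers, and maturation trajectories.
Passing tests therefore demonstrate correctness of the analysis chain and
recoverability of planted structure — not that real infant EMG satisfies
the model.

### Study-condition defaults and the regime simulation

Tests that mimic the developmental contrast use two frozen regimes:
neonatal-like A (P = N = 4, activation jitter 0.7, multiplexed dense
modules with sparsity 0.15, peak width 0.45) and toddler-like B
(P = N = 7, jitter 0.1, one-to-one pairing, sparsity 0.75, peak width
0.12). Envelope noise is 0.005 in both: noise is not part of the contrast,
and it must stay small relative to the envelope modulation because with
wide overlapping temporal peaks the envelope is nearly flat in time, so
larger noise dominates the variance about the grand mean and caps the
attainable VAF below the selection threshold — unlike real datasets, which
cross it at every age. The expected qualitative signature (IEV and IRV
higher in A; selected rank, SMAI and STAI higher in B) is required in at
least 18 of 20 seed pairs.

## Problem sizes

The bundled tests and examples run at the study's natural per-dataset
scale: 5-cycle ensembles of 200 × 10 envelopes, recordings of 7–9 cycles
at 2000 Hz, rank sweeps to 8. Fit budgets are scaled to the need of each
check — full 50-restart/1000-iteration fits where recovery quality is the
point, 5–10 restarts with a few hundred iterations for wiring and ordering
checks, where the extraction is easy and converges quickly.

## Known limitations

* Multiplicative updates converge slowly near the optimum; `converged`
  may be False on hard multiplexed problems even when the VAF is
  essentially final. Increase `max_iter` or loosen `tol` as appropriate.
* The tri-factorization is not identifiable in general (e.g. heavily
  overlapping temporal modules); parameter-recovery guarantees in the
  tests hold for the selective, well-separated regimes they use.
* The alternation rules assume bilaterally coded events; datasets with a
  single coded side cannot be screened for alternation.
* Group-level statistics (e.g. paired nonparametric comparisons across
  ages) are out of scope; the package stops at per-dataset index reports.
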