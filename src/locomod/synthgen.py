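"""Ground-truth generator for modular locomotor EMG.

Builds datasets from the same generative model the factorization assumes:
each cycle's 200 x M envelope matrix is a double linear combination of
invariant non-negative spatial modules (muscle weighting vectors) and
temporal modules (activation waveforms), weighted by a per-cycle matrix of
activation coefficients — the only cycle-varying part.  On top of the
envelope tensor the generator can render raw-like EMG (band-limited noise
carriers amplitude-modulated by the envelopes) together with bilateral
BHF/BHE event streams, so the full preprocessing chain can be exercised
without any recorded data.

Controllable knobs mirror the phenomena of interest: activation jitter
(trial-to-trial recruitment variability), pairing mode (recruitment
selectivity), spatial sparsity (muscle selectivity of modules), temporal
peak width (temporal selectivity), and additive envelope noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .preprocess import (
    N_TIME,
    EMGRecording,
    CycleEvents,
)

PAIRING_MODES = ("one_to_one", "multiplexed")

#: Default muscle labels (10-muscle montage: rectus femoris, tibialis
#: anterior, biceps femoris, soleus, gluteus medius; right then left).
DEFAULT_MUSCLES_10 = [
    "RF_r", "TA_r", "BF_r", "So_r", "GM_r",
    "RF_l", "TA_l", "BF_l", "So_l", "GM_l",
]


# ---------------------------------------------------------------------------
# Specs and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthSpec:
    """Knobs of the generator.

    activation_jitter is the SD of the multiplicative lognormal perturbation
    applied to the base activation matrix in each cycle; pairing_mode
    'one_to_one' gives each spatial module exactly one paired temporal module
    (selective recruitment) while 'multiplexed' activates every pair;
    spatial_sparsity is the target Hoyer sparseness of spatial module rows;
    temporal_peak_width is the FWHM of temporal bumps as a fraction of the
    cycle; noise_sd is additive Gaussian envelope noise (clipped at zero).
    """

    n_spatial: int = 4
    n_temporal: int = 4
    n_cycles: int = 5
    n_muscles: int = 10
    activation_jitter: float = 0.3
    pairing_mode: str = "one_to_one"
    spatial_sparsity: float = 0.5
    temporal_peak_width: float = 0.25
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_spatial", "n_temporal", "n_cycles"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.n_muscles < 2:
            raise ParameterError("n_muscles must be >= 2")
        if self.activation_jitter < 0:
            raise ParameterError("activation_jitter must be non-negative")
        if self.pairing_mode not in PAIRING_MODES:
            raise ParameterError(
                f"pairing_mode must be one of {PAIRING_MODES}, got {self.pairing_mode!r}"
            )
        if not 0.0 <= self.spatial_sparsity <= 1.0:
            raise ParameterError("spatial_sparsity must be in [0, 1]")
        if not 0.0 < self.temporal_peak_width <= 1.0:
            raise ParameterError("temporal_peak_width must be in (0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Known modules and activations behind a synthetic dataset.

    spatial: N x M, unit-Euclidean-norm rows; temporal: 200 x P,
    unit-Euclidean-norm columns; activations: P x N x S (all scale lives in
    the activations).
    """

    spatial: np.ndarray
    temporal: np.ndarray
    activations: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.spatial = np.asarray(self.spatial, dtype=float)
        self.temporal = np.asarray(self.temporal, dtype=float)
        self.activations = np.asarray(self.activations, dtype=float)
        if self.spatial.ndim != 2 or self.spatial.shape[1] < 2:
            raise ParameterError("spatial must be N x M with M >= 2")
        if self.temporal.ndim != 2 or self.temporal.shape[0] != N_TIME:
            raise ParameterError(f"temporal must be {N_TIME} x P")
        if self.activations.shape[:2] != (self.temporal.shape[1], self.spatial.shape[0]):
            raise ParameterError("activations must be P x N x S")
        for arr, name in ((self.spatial, "spatial"), (self.temporal, "temporal"),
                          (self.activations, "activations")):
            if np.any(arr < 0):
                raise ParameterError(f"{name} must be non-negative")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")

    @property
    def n_spatial(self) -> int:
        return self.spatial.shape[0]

    @property
    def n_temporal(self) -> int:
        return self.temporal.shape[1]

    @property
    def n_cycles(self) -> int:
        return self.activations.shape[2]

    @property
    def n_muscles(self) -> int:
        return self.spatial.shape[1]


# ---------------------------------------------------------------------------
# Hoyer projection (used to hit a target sparseness exactly)
# ---------------------------------------------------------------------------

def _hoyer_project(x: np.ndarray, l1: float, l2: float = 1.0) -> np.ndarray:
    """Project ``x`` onto the set {v >= 0, ||v||_1 = l1, ||v||_2 = l2}.

    The alternating projection of Hoyer (2004): move to the L1 hyperplane,
    then to the L2 sphere along the feasible direction, zeroing negative
    coordinates until all remain non-negative.
    """
    s = x.astype(float).copy()
    n = s.size
    mask = np.ones(n, dtype=bool)
    s = s + (l1 - s.sum()) / n
    for _ in range(n + 1):
        m = np.where(mask, l1 / mask.sum(), 0.0)
        w = s - m
        a = float(w @ w)
        if a < 1e-30:
            s = m
        else:
            b = 2.0 * float(w @ m)
            c = float(m @ m) - l2**2
            disc = max(b * b - 4 * a * c, 0.0)
            alpha = (-b + np.sqrt(disc)) / (2 * a)
            s = m + alpha * w
        neg = s < 0
        if not neg.any():
            break
        s[neg] = 0.0
        mask &= ~neg
        k = int(mask.sum())
        if k == 0:
            break
        s[mask] += (l1 - s.sum()) / k
    return np.clip(s, 0.0, None)


def _sparse_nonneg_vector(rng: np.random.Generator, n: int, sparseness: float) -> np.ndarray:
    """Random non-negative unit vector with the requested Hoyer sparseness."""
    l1 = np.sqrt(n) - sparseness * (np.sqrt(n) - 1.0)
    x = rng.uniform(0.05, 1.0, size=n)
    v = _hoyer_project(x, l1=l1, l2=1.0)
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_ground_truth(spec: SynthSpec) -> GroundTruth:
    """Draw spatial/temporal modules and per-cycle activations from a spec.

    Spatial modules are random non-negative unit vectors projected to the
    target Hoyer sparseness.  Temporal modules are truncated Gaussian bumps
    with FWHM ``temporal_peak_width`` of the cycle, centers spread evenly
    over the 200-point base, unit-normalized.  The base activation matrix is
    diagonal-dominant ('one_to_one': exactly one nonzero per spatial module)
    or dense ('multiplexed'), then perturbed per cycle by mean-one lognormal
    factors with underlying-normal SD ``activation_jitter``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    n, p, s, m = spec.n_spatial, spec.n_temporal, spec.n_cycles, spec.n_muscles

    spatial = np.stack([_sparse_nonneg_vector(rng, m, spec.spatial_sparsity) for _ in range(n)])

    t = np.arange(N_TIME)
    centers = (np.arange(p) + 0.5) / p * N_TIME
    sd = spec.temporal_peak_width * N_TIME / 2.3548  # FWHM -> Gaussian sigma
    temporal = np.exp(-0.5 * ((t[:, None] - centers[None, :]) / sd) ** 2)
    temporal /= np.linalg.norm(temporal, axis=0, keepdims=True)

    if spec.pairing_mode == "one_to_one":
        base = np.zeros((p, n))
        for j in range(n):
            base[j % p, j] = rng.uniform(0.7, 1.3)
    else:
        base = rng.uniform(0.2, 1.0, size=(p, n))

    sig = spec.activation_jitter
    factors = np.exp(sig * rng.standard_normal((p, n, s)) - 0.5 * sig**2)
    if sig == 0:
        factors = np.ones((p, n, s))
    activations = base[:, :, None] * factors

    return GroundTruth(
        spatial=spatial,
        temporal=temporal,
        activations=activations,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )


def render_ensemble(gt: GroundTruth) -> np.ndarray:
    """Forward-evaluate the model: S x 200 x M envelope tensor.

    Cycle s is temporal @ activations[:, :, s] @ spatial; Gaussian noise of
    SD ``gt.noise_sd`` is added and the result clipped at zero to preserve
    the non-negativity the factorization requires.
    """
    clean = np.einsum("tp,pns,nm->stm", gt.temporal, gt.activations, gt.spatial)
    if gt.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(gt.seed), 1]))
        clean = np.clip(clean + rng.normal(0.0, gt.noise_sd, size=clean.shape), 0.0, None)
    return clean


def render_raw_recording(
    gt: GroundTruth,
    rate: float,
    cycle_durations: np.ndarray,
    flexion_fractions: np.ndarray,
    contralateral_phase: float = 0.5,
    carrier_band: tuple[float, float] = (60.0, 500.0),
    pad: float = 1.0,
    muscle_labels: list[str] | None = None,
    side_of_analysis: str = "right",
) -> tuple[EMGRecording, CycleEvents]:
    """Render raw-like EMG plus bilateral BHF/BHE event streams.

    Each channel is zero-mean Gaussian noise band-passed to ``carrier_band``
    (above the 40 Hz high-pass corner, so preprocessing passes it intact),
    amplitude-modulated by the ground-truth envelope warped to the requested
    per-cycle durations and flexion fractions.  Contralateral events are
    phase-shifted by ``contralateral_phase`` of each cycle so the downstream
    alternation filter can be exercised (0.5 = perfect alternation; values
    outside [0.1, 0.9] make every cycle fail the rule).
    """
    durations = np.asarray(cycle_durations, dtype=float)
    fracs = np.asarray(flexion_fractions, dtype=float)
    if durations.shape != (gt.n_cycles,) or fracs.shape != (gt.n_cycles,):
        raise ParameterError("cycle_durations and flexion_fractions must have one entry per cycle")
    if np.any(durations <= 0):
        raise ParameterError("cycle durations must be positive")
    if np.any((fracs <= 0) | (fracs >= 1)):
        raise ParameterError("flexion fractions must lie in (0, 1)")
    if rate <= 2 * carrier_band[1]:
        raise ParameterError(
            f"rate {rate} Hz cannot carry a {carrier_band[1]} Hz carrier (Nyquist)"
        )
    if carrier_band[0] <= 40.0:
        raise ParameterError("carrier band must sit above the 40 Hz high-pass corner")
    if not 0.0 < contralateral_phase < 1.0:
        raise ParameterError("contralateral_phase must be in (0, 1)")
    if pad <= contralateral_phase * durations[0]:
        raise ParameterError("pad too short for the requested contralateral phase")

    s_cycles, m = gt.n_cycles, gt.n_muscles
    env = render_ensemble(gt)  # S x 200 x M

    bhf = pad + np.concatenate([[0.0], np.cumsum(durations)])  # S+1 BHFs
    bhe = bhf[:-1] + fracs * durations
    total = bhf[-1] + pad
    n_samp = int(round(total * rate))
    times = np.arange(n_samp) / rate

    # piecewise-linear envelope knots per cycle (80 flexion + 120 extension)
    knot_t = []
    for k in range(s_cycles):
        ft = np.linspace(bhf[k], bhe[k], 80)
        et = bhe[k] + np.arange(1, 121) / 121.0 * (bhf[k + 1] - bhe[k])
        knot_t.append(np.concatenate([ft, et]))
    knot_t = np.concatenate(knot_t)
    pre = np.array([0.0, bhf[0] - 1e-6])
    post = np.array([bhf[-1] + 1e-6, total])

    rng = np.random.default_rng(np.random.SeedSequence([int(gt.seed), 2]))
    sos = sps.butter(4, carrier_band, btype="bandpass", fs=rate, output="sos")
    carrier = sps.sosfiltfilt(sos, rng.standard_normal((n_samp, m)), axis=0)
    carrier /= np.sqrt(np.mean(carrier**2, axis=0, keepdims=True))

    raw = np.empty((n_samp, m))
    for ch in range(m):
        vals = np.concatenate([[0.0, 0.0], env[:, :, ch].ravel(), [0.0, 0.0]])
        tt = np.concatenate([pre, knot_t, post])
        raw[:, ch] = carrier[:, ch] * np.interp(times, tt, vals)

    labels = muscle_labels or (DEFAULT_MUSCLES_10 if m == 10 else [f"m{i + 1:02d}" for i in range(m)])
    recording = EMGRecording(signal=raw, rate=rate, muscle_labels=labels,
                             side_of_analysis=side_of_analysis)

    # ipsilateral events: leading BHE in the pad, BHE within each cycle,
    # trailing BHE after the final BHF
    ipsi_bhe = np.concatenate([[bhf[0] - 0.5 * pad], bhe,
                               [min(bhf[-1] + 0.5 * fracs[-1] * durations[-1], total - 1e-3)]])
    # contralateral: BHFs placed so each ipsilateral BHF falls at
    # ``contralateral_phase`` of the containing contralateral cycle
    d_ext = np.concatenate([durations, [durations[-1]]])
    cbhf = bhf - contralateral_phase * d_ext
    cbhf = np.concatenate([cbhf, [cbhf[-1] + durations[-1]]])
    if np.any(np.diff(cbhf) <= 0) or cbhf[0] < 0:
        raise ParameterError("cycle-duration jitter too large for contralateral phasing")
    cbhe = cbhf[:-1] + np.mean(fracs) * np.diff(cbhf)

    other = "left" if side_of_analysis == "right" else "right"
    events = CycleEvents(
        bhf={side_of_analysis: bhf, other: cbhf},
        bhe={side_of_analysis: ipsi_bhe, other: cbhe},
    )
    return recording, events


def spec_to_dict(spec: SynthSpec) -> dict:
    return asdict(spec)
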