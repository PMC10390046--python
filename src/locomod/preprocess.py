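"""EMG envelope preprocessing and cycle selection.

Turns a raw multi-muscle surface-EMG recording plus video-coded hip events
into amplitude- and time-normalized five-cycle ensembles, the input of the
space-by-time factorization.  The chain is fixed:

    high-pass filter (40 Hz, 4th-order Butterworth, zero-phase)
    -> full-wave rectification
    -> moving-median smoothing (window scaled to the age group)
    -> cycle selection (alternation rules)
    -> time normalization (80 flexion + 120 extension = 200 points/cycle)
    -> amplitude normalization (per-muscle maximum over the ensemble)

Cycles run from one beginning of hip flexion (BHF) to the next, split at the
beginning of hip extension (BHE).  Only *alternated* cycles are analyzed: a
cycle whose BHF falls between 10% and 90% of the contralateral limb's
concurrent cycle, excluding the first and last cycle of every maximal run of
alternating cycles, and requiring a preceding extension and a succeeding
flexion in the event stream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .errors import DataError, InsufficientDataError, ParameterError

# Phase-normalized time base: every cycle is resampled to 200 points,
# 80 for the flexion phase and 120 for the extension phase (the phase
# proportions of independent walking).
N_TIME = 200
FLEXION_SAMPLES = 80
EXTENSION_SAMPLES = 120

#: Moving-median window (samples at 2000 Hz) per age group; the window is
#: scaled to the roughly twofold cycle-duration decrease at each stage.
MEDIAN_WINDOWS = {"newborn": 400, "three_months": 200, "toddler": 100}

AGE_GROUPS = tuple(MEDIAN_WINDOWS)
SIDES = ("left", "right")

#: Contralateral-phase band defining an alternated cycle (inclusive).
ALTERNATION_BAND = (0.10, 0.90)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EMGRecording:
    """Raw multi-channel EMG: ``signal`` is samples x muscles at ``rate`` Hz."""

    signal: np.ndarray
    rate: float
    muscle_labels: list[str]
    side_of_analysis: str = "right"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ParameterError("signal must be a 2-D samples x muscles array")
        if not np.isfinite(self.signal).all():
            raise DataError("signal contains non-finite samples")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if self.signal.shape[1] < 2:
            raise ParameterError("at least 2 muscles are required")
        if len(self.muscle_labels) != self.signal.shape[1]:
            raise ParameterError("muscle_labels length must match signal columns")
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise ParameterError("muscle_labels must be unique")
        if self.side_of_analysis not in SIDES:
            raise ParameterError(
                f"side_of_analysis must be one of {SIDES}, got {self.side_of_analysis!r}"
            )

    @property
    def n_muscles(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.signal.shape[0] / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signal.shape[0]) / self.rate


@dataclass
class CycleEvents:
    """Ordered BHF/BHE event times (seconds) per body side."""

    bhf: dict[str, np.ndarray]
    bhe: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.bhf = {s: np.sort(np.asarray(t, dtype=float)) for s, t in self.bhf.items()}
        self.bhe = {s: np.sort(np.asarray(t, dtype=float)) for s, t in self.bhe.items()}
        for side in self.bhf:
            if side not in SIDES:
                raise ParameterError(f"unknown side {side!r}")
        self.validate()

    def validate(self) -> None:
        """Check strict ordering and BHF/BHE alternation within each side."""
        for side in self.bhf:
            for name, times in (("BHF", self.bhf[side]), ("BHE", self.bhe.get(side, np.array([])))):
                if np.any(np.diff(times) <= 0):
                    raise DataError(f"{name} times on side {side!r} are not strictly increasing")
            merged = np.concatenate([self.bhf[side], self.bhe.get(side, np.array([]))])
            kinds = np.concatenate(
                [np.zeros(len(self.bhf[side]), int), np.ones(len(self.bhe.get(side, ())), int)]
            )
            order = np.argsort(merged)
            k = kinds[order]
            t = merged[order]
            same = np.flatnonzero(np.diff(k) == 0)
            if same.size:
                raise DataError(
                    f"events on side {side!r} violate BHF/BHE alternation near t={t[same[0] + 1]:.4f} s"
                )

    def sides(self) -> list[str]:
        return sorted(self.bhf)


@dataclass(frozen=True)
class Cycle:
    """One flexion-extension cycle: BHF -> BHE -> next BHF (seconds)."""

    bhf_start: float
    bhe: float
    bhf_end: float

    def __post_init__(self) -> None:
        if not (self.bhf_start < self.bhe < self.bhf_end):
            raise ParameterError(
                f"cycle events must satisfy bhf_start < bhe < bhf_end, "
                f"got ({self.bhf_start}, {self.bhe}, {self.bhf_end})"
            )

    @property
    def duration(self) -> float:
        return self.bhf_end - self.bhf_start

    @property
    def flexion_fraction(self) -> float:
        return (self.bhe - self.bhf_start) / self.duration


@dataclass
class CycleEnsemble:
    """Preprocessed ensemble: non-negative ``data`` of shape S x 200 x M."""

    data: np.ndarray
    cycle_meta: list[Cycle] = field(default_factory=list)
    age_group: str = "newborn"
    normalization_scope: str = "ensemble"
    muscle_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != N_TIME:
            raise ParameterError(f"ensemble data must be S x {N_TIME} x M")
        if np.any(self.data < 0) or not np.isfinite(self.data).all():
            raise DataError("ensemble data must be non-negative and finite")

    @property
    def n_cycles(self) -> int:
        return self.data.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# Filtering and smoothing
# ---------------------------------------------------------------------------

def highpass_rectify(
    recording: EMGRecording, corner_hz: float = 40.0, order: int = 4
) -> EMGRecording:
    """High-pass filter then full-wave rectify every channel.

    The filter is a zero-phase (forward-backward) Butterworth high-pass, so
    envelope timing is not shifted relative to the video-coded events.  The
    sampling rate must exceed twice the corner so the corner sits below the
    Nyquist frequency.
    """
    if recording.rate <= 2 * corner_hz:
        raise ParameterError(
            f"sampling rate {recording.rate} Hz too low for a {corner_hz} Hz high-pass corner"
        )
    sos = sps.butter(order, corner_hz, btype="highpass", fs=recording.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=0)
    return dataclasses.replace(recording, signal=np.abs(filtered))


def moving_median_window(age_group: str) -> int:
    """Moving-median window length in samples for an age group.

    400 samples for newborns, 200 at three months, 100 in toddlers —
    proportional to the typical cycle duration at each age.
    """
    try:
        return MEDIAN_WINDOWS[age_group]
    except KeyError:
        raise ParameterError(
            f"unknown age group {age_group!r}; expected one of {AGE_GROUPS}"
        ) from None


def moving_median_smooth(signal: np.ndarray, window: int) -> np.ndarray:
    """Sliding-median smoothing with shrinking windows at the edges.

    For even window lengths the window is centered-left: sample ``i`` is the
    median of ``signal[i - window//2 : i + window - window//2]`` clipped to
    the signal, so the printed 400/200/100 windows are used as given.
    Operates along axis 0 of 1-D or 2-D input.
    """
    x = np.asarray(signal, dtype=float)
    if window < 1:
        raise ParameterError("window must be >= 1")
    n = x.shape[0]
    if window > n:
        raise ParameterError(f"window {window} longer than signal ({n} samples)")
    if window == 1:
        return x.copy()

    left = window // 2
    right = window - 1 - left  # centered-left for even windows
    out = np.empty_like(x)

    # interior: vectorized over full windows, one channel at a time to keep
    # the strided copy inside np.median contiguous and small
    if x.ndim == 1:
        core = sliding_window_view(np.ascontiguousarray(x), window)
        out[left : n - right] = np.median(core, axis=-1)
    else:
        for ch in range(x.shape[1]):
            core = sliding_window_view(np.ascontiguousarray(x[:, ch]), window)
            out[left : n - right, ch] = np.median(core, axis=-1)
    # edges: shrink the window to the available samples
    for i in range(left):
        out[i] = np.median(x[: i + right + 1], axis=0)
    for i in range(n - right, n):
        out[i] = np.median(x[i - left :], axis=0)
    return out


# ---------------------------------------------------------------------------
# Cycle selection
# ---------------------------------------------------------------------------

def _other_side(side: str) -> str:
    return "left" if side == "right" else "right"


def build_cycles(events: CycleEvents, side: str) -> list[Cycle]:
    """All BHF->BHF cycles on ``side`` that contain a BHE."""
    bhf = events.bhf.get(side)
    if bhf is None:
        raise ParameterError(f"no events for side {side!r}")
    bhe = events.bhe.get(side, np.array([]))
    cycles = []
    for k in range(len(bhf) - 1):
        inside = bhe[(bhe > bhf[k]) & (bhe < bhf[k + 1])]
        if inside.size != 1:
            continue
        cycles.append(Cycle(float(bhf[k]), float(inside[0]), float(bhf[k + 1])))
    return cycles


def select_alternated_cycles(
    events: CycleEvents, side: str, min_cycles: int | None = None
) -> list[Cycle]:
    """Retain the analyzable alternated cycles on ``side``.

    Three rules, applied in order:

    1. the cycle must be preceded by an extension (a BHE before its start)
       and succeeded by a flexion (a BHE after its end, confirming the next
       flexion phase completed);
    2. its BHF must fall between 10% and 90% (inclusive) of the
       contralateral BHF->BHF cycle containing it;
    3. the first and last cycle of every maximal run of consecutive cycles
       passing rules 1-2 are discarded.

    If ``min_cycles`` is given and fewer cycles survive, an
    :class:`InsufficientDataError` is raised (the pipeline uses 5).
    """
    if side not in SIDES:
        raise ParameterError(f"side must be one of {SIDES}")
    cycles = build_cycles(events, side)
    other = _other_side(side)
    cbhf = events.bhf.get(other, np.array([]))
    bhe = events.bhe.get(side, np.array([]))

    ok = []
    for cyc in cycles:
        preceded = bool(np.any(bhe < cyc.bhf_start))
        succeeded = bool(np.any(bhe > cyc.bhf_end))
        alternated = False
        if cbhf.size >= 2:
            i = int(np.searchsorted(cbhf, cyc.bhf_start, side="right")) - 1
            if 0 <= i < len(cbhf) - 1:
                phase = (cyc.bhf_start - cbhf[i]) / (cbhf[i + 1] - cbhf[i])
                # inclusive band with a guard against float round-off at the edges
                alternated = (
                    ALTERNATION_BAND[0] - 1e-9 <= phase <= ALTERNATION_BAND[1] + 1e-9
                )
        ok.append(preceded and succeeded and alternated)

    retained: list[Cycle] = []
    i = 0
    while i < len(cycles):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(cycles) and ok[j + 1]:
            j += 1
        retained.extend(cycles[i + 1 : j])  # drop first and last of the run
        i = j + 1

    if min_cycles is not None and len(retained) < min_cycles:
        raise InsufficientDataError(
            f"only {len(retained)} alternated cycles retained; {min_cycles} required"
        )
    return retained


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def time_normalize(
    envelope: np.ndarray, rate: float, cycle: Cycle, t_start: float = 0.0
) -> np.ndarray:
    """Resample one cycle of a multi-channel envelope to the 200-point base.

    The flexion phase [BHF, BHE] is linearly interpolated to 80 points
    (point 80 lands exactly on the BHE instant) and the extension phase
    (BHE, next BHF] to 120 points, so all cycles share the same kinematic
    landmarks regardless of age or behavior.

    ``envelope`` is samples x muscles (or 1-D); ``t_start`` is the time of
    its first sample.
    """
    x = np.atleast_2d(np.asarray(envelope, dtype=float).T).T
    n = x.shape[0]
    t = t_start + np.arange(n) / rate
    if cycle.bhf_start < t[0] - 0.5 / rate or cycle.bhf_end > t[-1] + 0.5 / rate:
        raise DataError("cycle extends beyond the recorded envelope")
    if cycle.bhe - cycle.bhf_start <= 0 or cycle.bhf_end - cycle.bhe <= 0:
        raise DataError("degenerate cycle phase with zero duration")

    flex_t = np.linspace(cycle.bhf_start, cycle.bhe, FLEXION_SAMPLES)
    ext_t = cycle.bhe + np.arange(1, EXTENSION_SAMPLES + 1) / EXTENSION_SAMPLES * (
        cycle.bhf_end - cycle.bhe
    )
    grid = np.concatenate([flex_t, ext_t])
    out = np.empty((N_TIME, x.shape[1]))
    for m in range(x.shape[1]):
        out[:, m] = np.interp(grid, t, x[:, m])
    return out if np.asarray(envelope).ndim == 2 else out[:, 0]


def amplitude_normalize(
    data: np.ndarray,
    scope: str = "ensemble",
    whole_signal_envelope: np.ndarray | None = None,
    muscle_labels: list[str] | None = None,
) -> np.ndarray:
    """Divide each muscle channel by its maximum.

    ``scope='ensemble'`` uses the per-muscle maximum over the S x 200 block
    (the study's default: normalization per ensemble of five cycles);
    ``scope='whole_signal'`` divides by the per-muscle maximum of
    ``whole_signal_envelope`` (samples x muscles), the robustness variant.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 3:
        raise ParameterError("expected an S x T x M ensemble tensor")
    if np.any(x < 0):
        raise DataError("ensemble must be non-negative")
    if scope == "ensemble":
        mx = x.max(axis=(0, 1))
    elif scope == "whole_signal":
        if whole_signal_envelope is None:
            raise ParameterError("whole_signal scope requires whole_signal_envelope")
        mx = np.asarray(whole_signal_envelope, dtype=float).max(axis=0)
        if mx.shape[0] != x.shape[2]:
            raise ParameterError("whole_signal_envelope muscle count mismatch")
    else:
        raise ParameterError(f"unknown normalization scope {scope!r}")
    zero = np.flatnonzero(mx <= 0)
    if zero.size:
        name = muscle_labels[zero[0]] if muscle_labels else f"channel {zero[0]}"
        raise DataError(f"all-zero muscle channel: {name}")
    return x / mx


# ---------------------------------------------------------------------------
# Cross-talk screening
# ---------------------------------------------------------------------------

def crosstalk_screen(
    recording: EMGRecording,
    pairs: list[tuple[str, str]],
    threshold: float = 0.2,
) -> list[dict]:
    """Pearson correlation between raw agonist/antagonist channel pairs.

    A pair is flagged when r strictly exceeds ``threshold`` (a 1e-12 guard
    keeps a pair at exactly the threshold unflagged despite rounding).  The
    screen is computed on raw, pre-envelope signals and is advisory: flagged
    pairs are reported, never auto-excluded.  A constant channel yields
    r = NaN with ``warning=True``.
    """
    label_ix = {lab: i for i, lab in enumerate(recording.muscle_labels)}
    results = []
    for a, b in pairs:
        if a not in label_ix or b not in label_ix:
            raise ParameterError(f"unknown muscle label in pair ({a!r}, {b!r})")
        xa = recording.signal[:, label_ix[a]]
        xb = recording.signal[:, label_ix[b]]
        warning = False
        if np.std(xa) == 0 or np.std(xb) == 0:
            r = float("nan")
            warning = True
        else:
            r = float(np.corrcoef(xa, xb)[0, 1])
        flagged = bool(np.isfinite(r) and r > threshold + 1e-12)
        results.append({"muscle_a": a, "muscle_b": b, "r": r, "flagged": flagged, "warning": warning})
    return results


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def preprocess_envelope(
    recording: EMGRecording,
    age_group: str,
    corner_hz: float = 40.0,
    order: int = 4,
) -> np.ndarray:
    """Filter -> rectify -> moving-median: the envelope of every channel."""
    rectified = highpass_rectify(recording, corner_hz=corner_hz, order=order)
    return moving_median_smooth(rectified.signal, moving_median_window(age_group))


def build_ensemble(
    envelope: np.ndarray,
    rate: float,
    cycles: list[Cycle],
    age_group: str = "newborn",
    normalization_scope: str = "ensemble",
    muscle_labels: list[str] | None = None,
    t_start: float = 0.0,
) -> CycleEnsemble:
    """Time-normalize the given cycles and amplitude-normalize the ensemble."""
    if not cycles:
        raise InsufficientDataError("no cycles supplied")
    data = np.stack([time_normalize(envelope, rate, c, t_start) for c in cycles])
    whole = envelope if normalization_scope == "whole_signal" else None
    data = amplitude_normalize(data, normalization_scope, whole, muscle_labels)
    return CycleEnsemble(
        data=data,
        cycle_meta=list(cycles),
        age_group=age_group,
        normalization_scope=normalization_scope,
        muscle_labels=muscle_labels,
    )
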