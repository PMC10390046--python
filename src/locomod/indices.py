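"""Variability and selectivity indices of the modular decomposition.

Five scalar indices summarize a dataset:

* IEV  — index of EMG variability: pointwise SD of the envelope across the
  five cycles, averaged over all 200 x M points.
* IRV  — index of recruitment variability: SD of each activation
  coefficient across cycles, averaged over all P x N module pairs.
* IRS  — index of recruitment selectivity: Hoyer sparseness of each cycle's
  vectorized activation matrix, averaged over cycles.
* SMAI — selectivity of muscular activations: mean Hoyer sparseness of the
  spatial modules (high = few muscles per module).
* STAI — selectivity of temporal activations: mean Hoyer sparseness of the
  temporal modules (high = narrow activation peaks).

All sparseness-based indices use the Hoyer measure
(sqrt(n) - ||v||_1 / ||v||_2) / (sqrt(n) - 1): 1 for a single-nonzero
vector, 0 for a uniform one, invariant to positive rescaling.  Standard
deviations use the sample convention (n - 1 denominator) throughout,
configurable via ``ddof``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import DataError, ParameterError
from .preprocess import Cycle, CycleEnsemble


# ---------------------------------------------------------------------------
# Sparseness
# ---------------------------------------------------------------------------

def hoyer_sparseness(v: np.ndarray) -> float:
    """Hoyer sparseness of a non-negative vector.

    (sqrt(n) - l1/l2) / (sqrt(n) - 1); 1 iff exactly one nonzero component,
    0 iff all components equal; invariant to positive rescaling.
    """
    x = np.asarray(v, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ParameterError("sparseness requires a vector of length >= 2")
    if np.any(x < 0):
        raise ParameterError("sparseness is defined for non-negative vectors")
    l2 = float(np.linalg.norm(x))
    if l2 == 0.0:
        raise DataError("sparseness of an all-zero vector is undefined")
    l1 = float(x.sum())
    rt = np.sqrt(n)
    return float((rt - l1 / l2) / (rt - 1.0))


# ---------------------------------------------------------------------------
# Variability indices
# ---------------------------------------------------------------------------

def iev(ensemble, ddof: int = 1) -> float:
    """Index of EMG variability of a five-cycle ensemble.

    SD across the 5 cycles at every (time, muscle) point, then the mean over
    all 200 x M points.  Defined on five-cycle ensembles only, matching the
    fixed-cycle-count protocol that keeps variability comparable across
    datasets.
    """
    data = ensemble.data if isinstance(ensemble, CycleEnsemble) else np.asarray(ensemble, float)
    if data.ndim != 3:
        raise ParameterError("expected an S x T x M ensemble tensor")
    if data.shape[0] != 5:
        raise ParameterError(f"IEV is defined on 5-cycle ensembles, got S={data.shape[0]}")
    return float(np.std(data, axis=0, ddof=ddof).mean())


def irv(activations: np.ndarray, ddof: int = 1) -> float:
    """Index of recruitment variability.

    SD of each activation coefficient across the S cycles, averaged over all
    P x N (temporal, spatial) module pairs.
    """
    a = np.asarray(activations, dtype=float)
    if a.ndim != 3:
        raise ParameterError("activations must be a P x N x S tensor")
    if a.shape[2] < 2:
        raise ParameterError("IRV requires at least 2 cycles")
    return float(np.std(a, axis=2, ddof=ddof).mean())


def irs(activations: np.ndarray) -> float:
    """Index of recruitment selectivity.

    Hoyer sparseness of the vectorized P x N activation matrix of each
    cycle, averaged over cycles: 1 when each cycle activates a single
    (temporal, spatial) pair, 0 when all pairs are equally activated.
    """
    a = np.asarray(activations, dtype=float)
    if a.ndim != 3:
        raise ParameterError("activations must be a P x N x S tensor")
    vals = []
    for s in range(a.shape[2]):
        vec = a[:, :, s].ravel()
        if not np.any(vec):
            raise DataError(f"cycle {s} has all-zero activations")
        vals.append(hoyer_sparseness(vec))
    return float(np.mean(vals))


def smai(spatial: np.ndarray) -> float:
    """Selectivity of muscular activations: mean sparseness of spatial modules."""
    w = np.asarray(spatial, dtype=float)
    if w.ndim != 2:
        raise ParameterError("spatial modules must be an N x M matrix")
    return float(np.mean([hoyer_sparseness(w[j]) for j in range(w.shape[0])]))


def stai(temporal: np.ndarray) -> float:
    """Selectivity of temporal activations: mean sparseness of temporal modules."""
    t = np.asarray(temporal, dtype=float)
    if t.ndim != 2:
        raise ParameterError("temporal modules must be a T x P matrix")
    return float(np.mean([hoyer_sparseness(t[:, i]) for i in range(t.shape[1])]))


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def kinematic_summary(cycles: list[Cycle], ddof: int = 1) -> dict:
    """Mean cycle duration, duration CV, and mean phase proportions."""
    if len(cycles) < 2:
        raise ParameterError("kinematic summary requires at least 2 cycles")
    durations = np.array([c.duration for c in cycles])
    flex = np.array([c.flexion_fraction for c in cycles])
    mean_dur = float(durations.mean())
    return {
        "cycle_duration_mean": mean_dur,
        "cycle_duration_cv": float(np.std(durations, ddof=ddof) / mean_dur),
        "flexion_proportion": float(flex.mean()),
        "extension_proportion": float(1.0 - flex.mean()),
    }


# ---------------------------------------------------------------------------
# Module comparison
# ---------------------------------------------------------------------------

def best_matching_pairs(
    modules_a: np.ndarray, modules_b: np.ndarray
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Greedy best-matching-pairs comparison of two module sets.

    Modules are rows (pass ``temporal.T`` for temporal modules).  Pairs are
    formed by descending cosine similarity without reuse, ties broken by
    first (row-major) index.  Returns (pairs, unmatched_a, unmatched_b)
    where each pair is (index_a, index_b, similarity).
    """
    a = np.atleast_2d(np.asarray(modules_a, dtype=float))
    b = np.atleast_2d(np.asarray(modules_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ParameterError("module sets must be non-empty")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise DataError("zero-norm module cannot be matched")
    sim = (a / na[:, None]) @ (b / nb[:, None]).T

    pairs = []
    free_a = list(range(a.shape[0]))
    free_b = list(range(b.shape[0]))
    work = sim.copy()
    while free_a and free_b:
        sub = work[np.ix_(free_a, free_b)]
        flat = int(np.argmax(sub))  # argmax returns the first maximum: tie -> first index
        i, j = divmod(flat, sub.shape[1])
        ia, jb = free_a[i], free_b[j]
        pairs.append((ia, jb, float(sim[ia, jb])))
        free_a.remove(ia)
        free_b.remove(jb)
    return pairs, free_a, free_b


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class IndexReport:
    """Per-dataset index values (possibly averaged over cycle combinations).

    ``n_modules`` can be fractional: it is the mean of the per-combination
    selected ranks.  The ``*_fixed4`` block repeats the recruitment and
    module-shape indices on the P = N = 4 control decomposition.
    """

    iev: float
    irv: float
    irs: float
    smai: float
    stai: float
    vaf: float
    vaf_fixed4: float
    n_modules: float
    irv_fixed4: float = float("nan")
    irs_fixed4: float = float("nan")
    smai_fixed4: float = float("nan")
    stai_fixed4: float = float("nan")
    kinematics: dict = field(default_factory=dict)

    SCALAR_FIELDS = (
        "iev", "irv", "irs", "smai", "stai", "vaf", "vaf_fixed4", "n_modules",
        "irv_fixed4", "irs_fixed4", "smai_fixed4", "stai_fixed4",
    )
    KINEMATIC_FIELDS = (
        "cycle_duration_mean", "cycle_duration_cv",
        "flexion_proportion", "extension_proportion",
    )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IndexReport":
        return cls(**d)

    @classmethod
    def mean(cls, reports: list["IndexReport"]) -> "IndexReport":
        """Arithmetic mean of every index over a list of reports."""
        if not reports:
            raise ParameterError("cannot average an empty list of reports")
        vals = {f: float(np.mean([getattr(r, f) for r in reports])) for f in cls.SCALAR_FIELDS}
        kin = {}
        for key in cls.KINEMATIC_FIELDS:
            if all(key in r.kinematics for r in reports):
                kin[key] = float(np.mean([r.kinematics[key] for r in reports]))
        return cls(kinematics=kin, **vals)
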