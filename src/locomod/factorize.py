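"""Space-by-time non-negative tri-factorization of EMG cycle ensembles.

The model: every cycle's 200 x M envelope matrix m_s is approximated by

    m_s ≈ T @ A_s @ W

with T a 200 x P matrix of temporal modules (columns: invariant activation
waveforms), W an N x M matrix of spatial modules (rows: invariant muscle
weightings), and A_s a P x N matrix of non-negative activation coefficients
— the only cycle-varying part.  Fitting minimizes the summed squared
Frobenius residual over cycles by cycling multiplicative updates over
(temporal, activations, spatial), each a Lee-Seung update of a linear NMF
subproblem with the other two factors held fixed, so the objective never
increases.  The extraction is restarted from many random initializations
(50 by default, matching standard practice against local minima) and the
best-VAF solution kept.

Goodness of fit is the variance accounted for:

    VAF = 1 - sum_s ||m_s - T A_s W||_F^2 / sum_s ||m_s - mbar||_F^2

with mbar the grand-mean activity level over all samples.  Model selection
sweeps P = N upward until VAF crosses a threshold (0.75 by default); a
fixed P = N = 4 fit (the adult-walking dimensionality) serves as control.

Scale convention: the tri-factorization is invariant to rescaling factors,
so solutions are canonicalized with unit-Euclidean-norm spatial rows and
temporal columns, all scale absorbed into the activations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError
from .preprocess import N_TIME, CycleEnsemble

_EPS = 1e-12

logger = logging.getLogger("locomod")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Decomposition:
    """One fitted space-by-time decomposition.

    spatial: N x M (unit-norm rows); temporal: 200 x P (unit-norm columns);
    activations: P x N x S.  ``restart_vafs`` records the VAF of every
    restart; ``loss_history`` the squared-residual trajectory of the best
    restart.
    """

    spatial: np.ndarray
    temporal: np.ndarray
    activations: np.ndarray
    vaf: float
    residual_norm: float
    n_restarts_used: int
    converged: bool
    seed: int | None = None
    n_iter: int = 0
    restart_vafs: list[float] = field(default_factory=list)
    loss_history: np.ndarray | None = None

    @property
    def n_spatial(self) -> int:
        return self.spatial.shape[0]

    @property
    def n_temporal(self) -> int:
        return self.temporal.shape[1]

    @property
    def n_cycles(self) -> int:
        return self.activations.shape[2]


@dataclass
class ModelSelection:
    """Result of the P = N rank sweep against a VAF threshold."""

    chosen_rank: int | None
    vaf_by_rank: dict[int, float]
    threshold: float
    reached: bool
    decompositions: dict[int, Decomposition] = field(default_factory=dict)

    @property
    def best_decomposition(self) -> Decomposition:
        rank = self.chosen_rank if self.reached else max(self.decompositions)
        return self.decompositions[rank]


# ---------------------------------------------------------------------------
# Reconstruction and goodness of fit
# ---------------------------------------------------------------------------

def _as_tensor(ensemble) -> np.ndarray:
    data = ensemble.data if isinstance(ensemble, CycleEnsemble) else np.asarray(ensemble, float)
    if data.ndim != 3:
        raise ParameterError("ensemble must be an S x T x M tensor")
    if np.any(data < 0) or not np.isfinite(data).all():
        raise DataError("ensemble must be non-negative and finite")
    return data


def reconstruct(dec: Decomposition, cycle: int) -> np.ndarray:
    """Model output for one cycle: temporal @ activations[:, :, cycle] @ spatial."""
    if not 0 <= cycle < dec.n_cycles:
        raise ParameterError(f"cycle index {cycle} out of range (S={dec.n_cycles})")
    t, a, w = dec.temporal, dec.activations[:, :, cycle], dec.spatial
    if t.shape[1] != a.shape[0] or a.shape[1] != w.shape[0]:
        raise ParameterError("factor shapes are inconsistent")
    return t @ a @ w


def reconstruct_all(dec: Decomposition) -> np.ndarray:
    """S x 200 x M reconstruction of every cycle."""
    return np.einsum("tp,pns,nm->stm", dec.temporal, dec.activations, dec.spatial)


def compute_vaf(ensemble, reconstruction) -> float:
    """Variance accounted for by a per-cycle reconstruction.

    1 minus the ratio of summed squared Frobenius residual norms to the
    summed squared deviations of each cycle from the grand-mean activity
    level.  Equals 1 for a perfect reconstruction, 0 when the reconstruction
    is the grand-mean constant, and can go negative for fits worse than the
    grand mean.
    """
    data = _as_tensor(ensemble)
    recon = np.asarray(reconstruction, dtype=float)
    if recon.shape != data.shape:
        raise ParameterError(
            f"reconstruction shape {recon.shape} does not match ensemble {data.shape}"
        )
    mbar = data.mean()
    denom = float(((data - mbar) ** 2).sum())
    if denom == 0.0:
        raise DataError("constant ensemble: VAF denominator is zero")
    return 1.0 - float(((data - recon) ** 2).sum()) / denom


# ---------------------------------------------------------------------------
# Multiplicative-update fitting
# ---------------------------------------------------------------------------

def _canonicalize(t: np.ndarray, a: np.ndarray, w: np.ndarray):
    """Unit-norm temporal columns and spatial rows; scale into activations."""
    tn = np.linalg.norm(t, axis=0)
    tn[tn == 0] = 1.0
    t = t / tn
    a = a * tn[None, :, None].transpose(1, 0, 2)  # (P,1,1) broadcast over N,S
    wn = np.linalg.norm(w, axis=1)
    wn[wn == 0] = 1.0
    w = w / wn[:, None]
    a = a * wn[None, :, None]
    return t, a, w


def _fit_single(
    data: np.ndarray,
    n_temporal: int,
    n_spatial: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
):
    """One restart of the alternating multiplicative updates.

    Factors are initialized with uniform random positive entries, globally
    scaled by the closed-form least-squares gain so the first reconstruction
    matches the data magnitude.  Update order per iteration: temporal,
    activations, spatial.
    """
    s, nt, m = data.shape
    p, n = n_temporal, n_spatial
    t = rng.uniform(0.1, 1.0, size=(nt, p))
    w = rng.uniform(0.1, 1.0, size=(n, m))
    a = rng.uniform(0.1, 1.0, size=(s, p, n))  # internal layout: S x P x N

    r0 = np.einsum("tp,spn,nm->stm", t, a, w)
    gain = float((data * r0).sum() / max((r0 * r0).sum(), _EPS))
    a *= max(gain, _EPS)

    # 2-D views used to express the stacked least-squares subproblems as
    # single BLAS calls: D_t is 200 x (S*M), D_w is (S*200) x M.
    d_t = np.ascontiguousarray(data.transpose(1, 0, 2).reshape(nt, s * m))
    d_w = data.reshape(s * nt, m)

    losses = np.empty(max_iter)
    prev = np.inf
    converged = False
    it = 0
    for it in range(max_iter):
        # temporal update: stacked columns subproblem
        y = a @ w  # (S, P, M)
        y2 = y.transpose(1, 0, 2).reshape(p, s * m)
        t *= (d_t @ y2.T) / (t @ (y2 @ y2.T) + _EPS)

        # activation update: independent per cycle
        ttt = t.T @ t
        wwt = w @ w.T
        td = np.matmul(t.T, data)  # (S, P, M)
        a *= (td @ w.T) / (np.matmul(ttt @ a, wwt) + _EPS)

        # spatial update: stacked rows subproblem
        x = np.matmul(t, a)  # (S, 200, N)
        x2 = x.reshape(s * nt, n)
        w *= (x2.T @ d_w) / ((x2.T @ x2) @ w + _EPS)

        resid = d_w - x2 @ w
        loss = float((resid * resid).sum())
        losses[it] = loss
        if prev < np.inf and abs(prev - loss) <= tol * max(prev, _EPS):
            converged = True
            break
        prev = loss
    return t, a, w, losses[: it + 1], converged


def fit_space_by_time(
    ensemble,
    n_temporal: int,
    n_spatial: int,
    n_restarts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
) -> Decomposition:
    """Fit the space-by-time model, keeping the best of ``n_restarts`` runs.

    Convergence within a restart: relative change of the squared residual
    below ``tol`` (or ``max_iter`` reached, in which case the solution is
    returned with ``converged=False``).  Ties across restarts at equal VAF
    go to the lowest restart index for determinism.
    """
    data = _as_tensor(ensemble)
    if n_temporal < 1 or n_spatial < 1:
        raise ParameterError("module numbers must be >= 1")
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")
    if data.mean() == 0 or ((data - data.mean()) ** 2).sum() == 0:
        raise DataError("constant or all-zero ensemble cannot be factorized")

    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    restart_vafs: list[float] = []
    for k in range(n_restarts):
        rng = np.random.default_rng(children[k])
        t, a, w, losses, converged = _fit_single(
            data, n_temporal, n_spatial, rng, max_iter, tol
        )
        vaf = compute_vaf(data, np.einsum("tp,spn,nm->stm", t, a, w))
        restart_vafs.append(vaf)
        if best is None or vaf > best[0]:
            best = (vaf, t, a, w, losses, converged)

    vaf, t, a, w, losses, converged = best
    if not converged:
        logger.warning(
            "best restart did not converge within max_iter=%d (VAF=%.4f)", max_iter, vaf
        )
    a = np.transpose(a, (1, 2, 0))  # -> P x N x S
    t, a, w = _canonicalize(t, a, w)
    recon = np.einsum("tp,pns,nm->stm", t, a, w)
    vaf = compute_vaf(data, recon)  # recompute from canonical factors
    residual_norm = float(np.sqrt(((data - recon) ** 2).sum()))
    return Decomposition(
        spatial=w,
        temporal=t,
        activations=a,
        vaf=vaf,
        residual_norm=residual_norm,
        n_restarts_used=n_restarts,
        converged=bool(converged),
        seed=seed,
        n_iter=len(losses),
        restart_vafs=restart_vafs,
        loss_history=np.asarray(losses),
    )


def select_module_number(
    ensemble,
    threshold: float = 0.75,
    rank_range=None,
    stop_early: bool = True,
    n_restarts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
) -> ModelSelection:
    """Sweep P = N upward and pick the smallest rank with VAF >= threshold.

    With ``stop_early`` the sweep stops at the first crossing (the study's
    procedure); disable it to obtain the full VAF-by-rank trace.  If the
    threshold is never reached within ``rank_range`` the result carries
    ``reached=False`` and ``chosen_rank=None`` together with the trace.
    """
    data = _as_tensor(ensemble)
    if rank_range is None:
        rank_range = range(1, min(data.shape[2], 10) + 1)
    ranks = sorted(set(int(r) for r in rank_range))
    if not ranks or ranks[0] < 1:
        raise ParameterError("rank_range must contain positive ranks")

    if seed is not None:
        children = np.random.SeedSequence(seed).spawn(len(ranks))
        rank_seeds = {r: int(c.generate_state(1)[0] % (2**31 - 2)) for r, c in zip(ranks, children)}
    else:
        rank_seeds = {r: None for r in ranks}

    vaf_by_rank: dict[int, float] = {}
    decomps: dict[int, Decomposition] = {}
    chosen = None
    for r in ranks:
        dec = fit_space_by_time(
            data, r, r, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            seed=rank_seeds[r],
        )
        vaf_by_rank[r] = dec.vaf
        decomps[r] = dec
        if chosen is None and dec.vaf >= threshold:
            chosen = r
            if stop_early:
                break
    return ModelSelection(
        chosen_rank=chosen,
        vaf_by_rank=vaf_by_rank,
        threshold=threshold,
        reached=chosen is not None,
        decompositions=decomps,
    )


def fit_fixed_four(ensemble, seed: int | None = None, **kwargs) -> Decomposition:
    """Control fit at P = N = 4, the dimensionality of standard adult walking."""
    return fit_space_by_time(ensemble, 4, 4, seed=seed, **kwargs)
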