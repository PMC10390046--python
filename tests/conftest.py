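"""Shared fixtures and helpers for the locomod test suite."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import locomod as lm
from locomod.preprocess import CycleEvents

settings.register_profile(
    "locomod",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("locomod")

# the non-convergence warning is expected in fast low-budget fits
logging.getLogger("locomod").setLevel(logging.ERROR)


# ---------------------------------------------------------------------------
# Synthetic event streams with controllable alternation phasing
# ---------------------------------------------------------------------------

def make_event_stream(
    n_cycles: int,
    duration: float = 1.0,
    flexion: float = 0.4,
    phase: float = 0.5,
    t0: float = 2.0,
    side: str = "right",
) -> CycleEvents:
    """Well-formed bilateral BHF/BHE streams of ``n_cycles`` identical cycles.

    Each ipsilateral BHF falls at fraction ``phase`` of the contralateral
    cycle containing it.  Includes a leading BHE and a trailing BHE so every
    cycle is preceded by an extension and succeeded by a flexion.
    """
    bhf = t0 + duration * np.arange(n_cycles + 1)
    bhe = bhf[:-1] + flexion * duration
    ipsi_bhe = np.concatenate([[t0 - 0.5 * duration], bhe, [bhf[-1] + flexion * duration]])
    cbhf = np.concatenate([bhf - phase * duration, [bhf[-1] + (1 - phase) * duration]])
    cbhe = cbhf[:-1] + flexion * np.diff(cbhf)
    other = "left" if side == "right" else "right"
    return CycleEvents(
        bhf={side: bhf, other: cbhf},
        bhe={side: ipsi_bhe, other: cbhe},
    )


# ---------------------------------------------------------------------------
# Developmental regimes: neonatal-like (A) vs toddler-like (B)
# ---------------------------------------------------------------------------

def regime_specs(seed: int) -> tuple[lm.SynthSpec, lm.SynthSpec]:
    """Synthetic regimes mimicking the developmental contrast.

    Regime A (neonatal-like): few modules (rank 4), high activation jitter,
    dense non-selective modules, wide temporal peaks.  Regime B
    (toddler-like): many modules (rank 7), low jitter, sparse selective
    modules, narrow peaks.  Measurement noise (0.005) is small relative to
    the envelope modulation in both regimes so the VAF threshold remains
    crossable, as in real datasets.
    """
    a = lm.SynthSpec(
        n_spatial=4, n_temporal=4, n_cycles=5, n_muscles=10,
        activation_jitter=0.7, pairing_mode="multiplexed",
        spatial_sparsity=0.15, temporal_peak_width=0.45,
        noise_sd=0.005, seed=seed,
    )
    b = lm.SynthSpec(
        n_spatial=7, n_temporal=7, n_cycles=5, n_muscles=10,
        activation_jitter=0.1, pairing_mode="one_to_one",
        spatial_sparsity=0.75, temporal_peak_width=0.12,
        noise_sd=0.005, seed=seed,
    )
    return a, b


def evaluate_regime(spec: lm.SynthSpec, fit_seed: int) -> dict:
    """IEV, IRV, selected rank, SMAI, STAI for one synthetic dataset."""
    gt = lm.generate_ground_truth(spec)
    ensemble = lm.amplitude_normalize(lm.render_ensemble(gt))
    sel = lm.select_module_number(
        ensemble, threshold=0.75, rank_range=range(1, 9), stop_early=True,
        n_restarts=8, max_iter=500, tol=1e-5, seed=fit_seed,
    )
    dec = sel.best_decomposition
    return {
        "iev": lm.iev(ensemble),
        "irv": lm.irv(dec.activations),
        "rank": sel.chosen_rank if sel.reached else max(sel.vaf_by_rank) + 1,
        "smai": lm.smai(dec.spatial),
        "stai": lm.stai(dec.temporal),
    }


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gt() -> lm.GroundTruth:
    """Noiseless rank-3, 5-cycle ground truth used across modules."""
    spec = lm.SynthSpec(
        n_spatial=3, n_temporal=3, n_cycles=5, n_muscles=10,
        activation_jitter=0.4, pairing_mode="one_to_one",
        spatial_sparsity=0.6, temporal_peak_width=0.2, noise_sd=0.0, seed=7,
    )
    return lm.generate_ground_truth(spec)


@pytest.fixture(scope="session")
def small_ensemble(small_gt) -> np.ndarray:
    return lm.render_ensemble(small_gt)
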