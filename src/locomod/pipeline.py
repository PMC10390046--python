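"""Per-dataset orchestration of the full analysis.

One dataset = one recording of one behavior (stepping, kicking, or walking)
at one age.  The flow is: envelope preprocessing -> alternated-cycle
selection -> five random combinations of five cycles -> per-combination
preprocessed ensemble, IEV, rank sweep (P = N until VAF crosses the
threshold), indices on the chosen decomposition, plus the fixed P = N = 4
control fit -> arithmetic averaging of every index over combinations.
Averaging over combinations is why reported module counts can be decimal.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from math import comb

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .preprocess import (
    Cycle,
    CycleEvents,
    EMGRecording,
    build_ensemble,
    moving_median_window,
    preprocess_envelope,
    select_alternated_cycles,
    AGE_GROUPS,
)
from .factorize import fit_fixed_four, select_module_number
from .indices import IndexReport, iev, irs, irv, kinematic_summary, smai, stai

logger = logging.getLogger("locomod")

BEHAVIORS = ("stepping", "kicking", "walking")


@dataclass
class RunConfig:
    """Configuration of a dataset analysis run."""

    age_group: str = "newborn"
    behavior: str = "stepping"
    vaf_threshold: float = 0.75
    n_combinations: int = 5
    combination_size: int = 5
    master_seed: int = 0
    normalization_scope: str = "ensemble"
    rank_range: list[int] | None = None
    n_restarts: int = 50
    max_iter: int = 1000
    tol: float = 1e-6
    highpass_hz: float = 40.0
    filter_order: int = 4
    crosstalk_threshold: float = 0.2

    def validate(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ParameterError(f"age_group must be one of {AGE_GROUPS}")
        if self.behavior not in BEHAVIORS:
            raise ParameterError(f"behavior must be one of {BEHAVIORS}")
        if self.n_combinations < 1:
            raise ParameterError("n_combinations must be >= 1")
        if self.combination_size < 2:
            raise ParameterError("combination_size must be >= 2")
        if self.normalization_scope not in ("ensemble", "whole_signal"):
            raise ParameterError("normalization_scope must be 'ensemble' or 'whole_signal'")
        if not 0 <= self.vaf_threshold <= 1:
            raise ParameterError("vaf_threshold must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        cfg.validate()
        return cfg


@dataclass
class DatasetResult:
    """Averaged report plus the per-combination trace."""

    summary: IndexReport
    per_combination: list[IndexReport]
    combinations: list[tuple[int, ...]]
    n_cycles_available: int
    config: RunConfig = field(repr=False, default_factory=RunConfig)


def draw_combinations(n_available: int, config: RunConfig) -> list[tuple[int, ...]]:
    """Random distinct 5-cycle subsets of the available cycles.

    With exactly five cycles available the single forced combination is
    returned without resampling.  Otherwise ``n_combinations`` distinct
    unordered subsets are drawn (fewer if not enough subsets exist),
    seeded from the master seed.
    """
    k = config.combination_size
    if n_available < k:
        raise InsufficientDataError(
            f"{n_available} cycles available; {k} required per combination"
        )
    if n_available == k:
        return [tuple(range(k))]
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 17]))
    total = comb(n_available, k)
    target = min(config.n_combinations, total)
    combos: list[tuple[int, ...]] = []
    seen = set()
    while len(combos) < target:
        c = tuple(sorted(rng.choice(n_available, size=k, replace=False).tolist()))
        if c not in seen:
            seen.add(c)
            combos.append(c)
    return combos


def _analyze_combination(
    ensemble,
    cycles: list[Cycle],
    config: RunConfig,
    seed: int,
) -> IndexReport:
    """Indices for one five-cycle combination."""
    sel = select_module_number(
        ensemble,
        threshold=config.vaf_threshold,
        rank_range=config.rank_range,
        n_restarts=config.n_restarts,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=seed,
    )
    dec = sel.best_decomposition
    if not sel.reached:
        logger.warning(
            "VAF threshold %.2f not reached within the rank range; "
            "indices use the rank-%d fit and n_modules is NaN",
            config.vaf_threshold, dec.n_spatial,
        )
    dec4 = fit_fixed_four(
        ensemble,
        seed=seed + 1,
        n_restarts=config.n_restarts,
        max_iter=config.max_iter,
        tol=config.tol,
    )
    return IndexReport(
        iev=iev(ensemble),
        irv=irv(dec.activations),
        irs=irs(dec.activations),
        smai=smai(dec.spatial),
        stai=stai(dec.temporal),
        vaf=dec.vaf,
        vaf_fixed4=dec4.vaf,
        n_modules=float(sel.chosen_rank) if sel.reached else float("nan"),
        irv_fixed4=irv(dec4.activations),
        irs_fixed4=irs(dec4.activations),
        smai_fixed4=smai(dec4.spatial),
        stai_fixed4=stai(dec4.temporal),
        kinematics=kinematic_summary(cycles),
    )


def run_dataset(
    recording: EMGRecording,
    events: CycleEvents,
    config: RunConfig,
) -> DatasetResult:
    """Full analysis of one dataset; every index averaged over combinations."""
    config.validate()
    t0 = time.perf_counter()
    envelope = preprocess_envelope(
        recording, config.age_group, config.highpass_hz, config.filter_order
    )
    logger.debug("envelope preprocessing: %.2f s", time.perf_counter() - t0)

    cycles = select_alternated_cycles(
        events, recording.side_of_analysis, min_cycles=config.combination_size
    )
    combos = draw_combinations(len(cycles), config)

    seeds = np.random.SeedSequence([config.master_seed, 29]).spawn(len(combos))
    reports = []
    for ci, combo in enumerate(combos):
        tc = time.perf_counter()
        sel_cycles = [cycles[i] for i in combo]
        ensemble = build_ensemble(
            envelope,
            recording.rate,
            sel_cycles,
            age_group=config.age_group,
            normalization_scope=config.normalization_scope,
            muscle_labels=recording.muscle_labels,
        )
        seed = int(seeds[ci].generate_state(1)[0] % (2**31 - 2))
        reports.append(_analyze_combination(ensemble.data, sel_cycles, config, seed))
        logger.debug("combination %d/%d: %.2f s", ci + 1, len(combos), time.perf_counter() - tc)

    return DatasetResult(
        summary=IndexReport.mean(reports),
        per_combination=reports,
        combinations=combos,
        n_cycles_available=len(cycles),
        config=config,
    )


__all__ = [
    "RunConfig",
    "DatasetResult",
    "draw_combinations",
    "run_dataset",
    "moving_median_window",
]
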