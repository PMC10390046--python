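"""Readers and writers for the on-disk formats.

Formats are deliberately plain: delimited text for recordings (tab-separated,
first column time in seconds, header row of muscle labels) and events (CSV
with columns side, event_type, time_s), JSON for index reports and run
configurations (YAML also accepted for configs), and NumPy ``.npz`` archives
with an embedded JSON manifest for ground truth and decompositions.  Every
writer's output is re-readable by the matching reader; readers validate
shape, ordering and alternation before handing data to the analysis.
Vendor-specific acquisition formats are out of scope; converting them means
producing the delimited layout described here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, ParameterError
from .factorize import Decomposition
from .indices import IndexReport
from .pipeline import DatasetResult, RunConfig
from .preprocess import CycleEvents, EMGRecording
from .synthgen import GroundTruth, SynthSpec, spec_to_dict

SCHEMA_VERSION = "1"
EVENT_TYPES = ("BHF", "BHE")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Paths and metadata tying a recording to its events and analysis side."""

    recording_path: str
    events_path: str
    muscle_labels: list[str]
    side_of_analysis: str = "right"
    age_group: str = "newborn"
    behavior: str = "stepping"
    rate: float | None = None

    def validate(self, base: Path | None = None) -> None:
        base = base or Path(".")
        for p in (self.recording_path, self.events_path):
            if not (base / p).exists():
                raise FormatError(f"manifest references missing file: {p}")
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise ParameterError("manifest muscle labels must be unique")
        if self.side_of_analysis not in ("left", "right"):
            raise ParameterError("side_of_analysis must be 'left' or 'right'")


def load_manifest(path) -> DatasetManifest:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    try:
        return DatasetManifest(**d)
    except TypeError as exc:
        raise FormatError(f"bad manifest {path}: {exc}") from None


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def write_recording(recording: EMGRecording, path) -> None:
    """Tab-separated text: time_s column then one column per muscle."""
    df = pd.DataFrame(recording.signal, columns=recording.muscle_labels)
    df.insert(0, "time_s", recording.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_recording(
    path,
    rate: float | None = None,
    muscle_order: list[str] | None = None,
    side_of_analysis: str = "right",
) -> EMGRecording:
    """Read a delimited recording, validating cells and column order.

    Non-numeric cells are reported with their (1-based) data row; columns are
    reordered to ``muscle_order`` when given.  The sampling rate is taken
    from the time column unless supplied.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed recording file {path}: {exc}") from None
    if df.shape[1] < 3 or df.columns[0] != "time_s":
        raise FormatError(f"{path}: expected a time_s column followed by >= 2 muscle columns")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(f"{path}: non-numeric cell in column {col!r} at row {bad[0] + 1}")
        if df[col].isna().any():
            row = int(df[col].index[df[col].isna()][0]) + 1
            raise FormatError(f"{path}: missing value in column {col!r} at row {row}")
        df[col] = numeric
    labels = list(df.columns[1:])
    if muscle_order is not None:
        missing = [m for m in muscle_order if m not in labels]
        if missing:
            raise FormatError(f"{path}: muscle labels {missing} not found in header")
        df = df[["time_s"] + list(muscle_order)]
        labels = list(muscle_order)
    t = df["time_s"].to_numpy()
    if rate is None:
        dt = np.median(np.diff(t))
        if not np.isfinite(dt) or dt <= 0:
            raise FormatError(f"{path}: cannot infer sampling rate from time column")
        rate = 1.0 / dt
    return EMGRecording(
        signal=df[labels].to_numpy(float),
        rate=float(rate),
        muscle_labels=labels,
        side_of_analysis=side_of_analysis,
    )


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def write_events(events: CycleEvents, path) -> None:
    """CSV with columns side, event_type, time_s, sorted by time."""
    rows = []
    for side in events.bhf:
        rows += [(side, "BHF", t) for t in events.bhf[side]]
        rows += [(side, "BHE", t) for t in events.bhe.get(side, ())]
    df = pd.DataFrame(rows, columns=["side", "event_type", "time_s"]).sort_values("time_s")
    df.to_csv(path, index=False, float_format="%.8g")


def read_events(path) -> CycleEvents:
    """Read and validate an event table (sorting and alternation enforced)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed event file {path}: {exc}") from None
    required = {"side", "event_type", "time_s"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    bad_type = ~df["event_type"].isin(EVENT_TYPES)
    if bad_type.any():
        raise FormatError(
            f"{path}: unknown event_type {df['event_type'][bad_type].iloc[0]!r}"
        )
    df = df.sort_values("time_s")
    bhf = {}
    bhe = {}
    for side, grp in df.groupby("side"):
        bhf[side] = grp.loc[grp.event_type == "BHF", "time_s"].to_numpy(float)
        bhe[side] = grp.loc[grp.event_type == "BHE", "time_s"].to_numpy(float)
    try:
        return CycleEvents(bhf=bhf, bhe=bhe)
    except DataError as exc:
        raise FormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _check_finite(obj, where="report"):
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{where}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{where}[{i}]")
    elif isinstance(obj, float) and not np.isfinite(obj):
        raise DataError(f"non-finite value at {where}; refusing to write")


def write_report(report, path, allow_nan_modules: bool = False) -> None:
    """Serialize an IndexReport or DatasetResult to schema-versioned JSON.

    Non-finite values are refused at write time unless they are the
    documented NaN ``n_modules`` sentinel and ``allow_nan_modules`` is set.
    """
    if isinstance(report, DatasetResult):
        payload = {
            "summary": report.summary.to_dict(),
            "per_combination": [r.to_dict() for r in report.per_combination],
            "combinations": [list(c) for c in report.combinations],
            "n_cycles_available": report.n_cycles_available,
            "config": report.config.to_dict(),
        }
    elif isinstance(report, IndexReport):
        payload = {"summary": report.to_dict()}
    elif isinstance(report, dict):
        payload = dict(report)
    else:
        raise ParameterError(f"cannot serialize report of type {type(report).__name__}")
    if not allow_nan_modules:
        _check_finite(payload)
    payload["schema_version"] = SCHEMA_VERSION
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=allow_nan_modules)


def read_report(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(f"{path}: unknown report schema version {version!r}")
    if "summary" in payload:
        missing = [f for f in IndexReport.SCALAR_FIELDS if f not in payload["summary"]]
        if missing:
            raise FormatError(f"{path}: report summary missing fields {missing}")
    return payload


# ---------------------------------------------------------------------------
# Array archives (ground truth, decompositions)
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, path, spec: SynthSpec | None = None) -> None:
    manifest = {"noise_sd": gt.noise_sd, "seed": gt.seed}
    if spec is not None:
        manifest["spec"] = spec_to_dict(spec)
    np.savez(
        path,
        spatial=gt.spatial,
        temporal=gt.temporal,
        activations=gt.activations,
        manifest=np.array(json.dumps(manifest)),
    )


def read_ground_truth(path) -> tuple[GroundTruth, dict]:
    with np.load(path) as npz:
        manifest = json.loads(str(npz["manifest"]))
        gt = GroundTruth(
            spatial=npz["spatial"],
            temporal=npz["temporal"],
            activations=npz["activations"],
            noise_sd=float(manifest.get("noise_sd", 0.0)),
            seed=int(manifest.get("seed", 0)),
        )
    return gt, manifest


def write_decomposition(dec: Decomposition, path) -> None:
    meta = {
        "vaf": dec.vaf,
        "residual_norm": dec.residual_norm,
        "n_restarts_used": dec.n_restarts_used,
        "converged": dec.converged,
        "seed": dec.seed,
        "n_iter": dec.n_iter,
        "restart_vafs": dec.restart_vafs,
        "norm_convention": "unit-L2 spatial rows and temporal columns; scale in activations",
    }
    np.savez(
        path,
        spatial=dec.spatial,
        temporal=dec.temporal,
        activations=dec.activations,
        meta=np.array(json.dumps(meta)),
    )


def read_decomposition(path) -> Decomposition:
    with np.load(path) as npz:
        meta = json.loads(str(npz["meta"]))
        return Decomposition(
            spatial=npz["spatial"],
            temporal=npz["temporal"],
            activations=npz["activations"],
            vaf=float(meta["vaf"]),
            residual_norm=float(meta["residual_norm"]),
            n_restarts_used=int(meta["n_restarts_used"]),
            converged=bool(meta["converged"]),
            seed=meta.get("seed"),
            n_iter=int(meta.get("n_iter", 0)),
            restart_vafs=list(meta.get("restart_vafs", [])),
        )


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path) -> RunConfig:
    """Run configuration from YAML or JSON key-value files."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise FormatError(f"{path}: expected a mapping of configuration keys")
    try:
        return RunConfig.from_dict(d)
    except TypeError as exc:
        raise FormatError(f"{path}: {exc}") from None
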