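"""Electronic-nose signal handling.

A recording is a 13-channel metal-oxide-semiconductor (MOS) sensor array
time series following a three-phase protocol: 210 s of chamber cleaning with
filtered air, 40 s of fruit headspace exposure, and 60 s of purging, 310 s
in total.  Raw responses are baseline-corrected with the fractional method,
``y = (x - x0) / x0`` where ``x0`` is the per-channel cleaning-phase
baseline, and three features are extracted per channel over the headspace
window (211-250 s): the maximum sensor response (MSR), the area under the
curve (AUC, trapezoidal), and the impregnation time (Tim, seconds from the
window start to the first sample attaining the maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SENSOR_IDS",
    "FEATURE_KINDS",
    "Phases",
    "SensorRecording",
    "NormalizedRecording",
    "EnoseFeatureVector",
    "NormalizationError",
    "FeatureExtractionError",
    "baseline_correct",
    "extract_enose_features",
    "enose_feature_table",
    "feature_names",
    "read_recording_csv",
    "write_recording_csv",
]

#: Canonical sensor panel: eight Hanwei MQ-series and five Figaro TGS-series
#: semi-selective MOS gas sensors.
SENSOR_IDS: tuple[str, ...] = (
    "MQ2", "MQ3", "MQ4", "MQ5", "MQ7", "MQ8", "MQ9", "MQ135",
    "TGS813", "TGS822", "TGS2610", "TGS2602", "TGS2620",
)

FEATURE_KINDS: tuple[str, ...] = ("MSR", "AUC", "TIM")


class NormalizationError(ValueError):
    """Raised when a channel baseline is non-positive or non-finite."""


class FeatureExtractionError(ValueError):
    """Raised for empty feature windows or non-finite samples."""


@dataclass(frozen=True)
class Phases:
    """Acquisition phase boundaries in seconds."""

    clean_end: float = 210.0
    expose_end: float = 250.0
    total: float = 310.0

    def __post_init__(self) -> None:
        if not 0 < self.clean_end < self.expose_end < self.total:
            raise ValueError("phase boundaries must satisfy 0 < clean < expose < total")


@dataclass
class SensorRecording:
    """Raw 13-channel response matrix with its time base and phase marks."""

    response: np.ndarray          # channels x T, raw units
    time_s: np.ndarray            # T
    sensor_ids: tuple[str, ...] = SENSOR_IDS
    phases: Phases = field(default_factory=Phases)
    fruit_id: str | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.response.ndim != 2:
            raise ValueError("response must be channels x samples")
        if len(self.sensor_ids) != self.response.shape[0]:
            raise ValueError("sensor id count does not match channel count")
        if self.time_s.shape != (self.response.shape[1],):
            raise ValueError("time base length does not match sample count")
        if self.time_s[-1] < self.phases.total - 1e-9:
            raise ValueError("time base does not cover the acquisition protocol")


@dataclass
class NormalizedRecording:
    """Fractionally normalized recording with stored per-channel baselines."""

    response: np.ndarray          # channels x T, dimensionless
    baselines: np.ndarray         # channels
    time_s: np.ndarray
    sensor_ids: tuple[str, ...] = SENSOR_IDS
    phases: Phases = field(default_factory=Phases)
    fruit_id: str | None = None


@dataclass
class EnoseFeatureVector:
    """39 features (13 sensors x MSR/AUC/Tim), sensor-major order."""

    values: np.ndarray
    names: tuple[str, ...]
    fruit_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("feature values and names disagree in length")


def feature_names(sensor_ids: Sequence[str] = SENSOR_IDS) -> tuple[str, ...]:
    """Sensor-major feature names: ``<SENSOR>_MSR``, ``<SENSOR>_AUC``, ``<SENSOR>_TIM``."""
    return tuple(f"{sid}_{kind}" for sid in sensor_ids for kind in FEATURE_KINDS)


def baseline_correct(
    recording: SensorRecording,
    baseline_window: tuple[float, float] = (200.0, 210.0),
) -> NormalizedRecording:
    """Fractional baseline correction ``(x - x0) / x0`` per channel.

    ``x0`` is the mean raw response over ``baseline_window``, which must lie
    inside the cleaning phase (default: the last 10 s of cleaning).
    """
    lo, hi = baseline_window
    if not (0 <= lo < hi <= recording.phases.clean_end):
        raise ValueError("baseline window must lie inside the cleaning phase")
    sel = (recording.time_s >= lo) & (recording.time_s <= hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    baselines = recording.response[:, sel].mean(axis=1)
    bad = np.flatnonzero(~np.isfinite(baselines) | (baselines <= 0))
    if bad.size:
        names = ", ".join(recording.sensor_ids[i] for i in bad)
        raise NormalizationError(f"non-positive or non-finite baseline for sensor(s): {names}")
    normalized = (recording.response - baselines[:, None]) / baselines[:, None]
    return NormalizedRecording(
        normalized, baselines, recording.time_s,
        recording.sensor_ids, recording.phases, recording.fruit_id,
    )


def extract_enose_features(
    normalized: NormalizedRecording,
    window: tuple[float, float] = (211.0, 250.0),
) -> EnoseFeatureVector:
    """Per-channel MSR, AUC and Tim over the headspace window (inclusive ends).

    MSR is the maximum normalized response in the window; Tim is the elapsed
    time from the window start to the *first* sample attaining the maximum
    (earlier sample wins ties); AUC is the trapezoidal integral of the
    normalized curve over the window.
    """
    lo, hi = window
    sel = (normalized.time_s >= lo) & (normalized.time_s <= hi)
    if sel.sum() < 2:
        raise FeatureExtractionError("feature window must contain at least two samples")
    t = normalized.time_s[sel]
    y = normalized.response[:, sel]
    if not np.all(np.isfinite(y)):
        raise FeatureExtractionError("non-finite samples inside the feature window")
    msr = y.max(axis=1)
    tim = t[y.argmax(axis=1)] - lo            # argmax returns the first maximum
    auc = np.trapezoid(y, t, axis=1)
    values = np.column_stack([msr, auc, tim]).reshape(-1)
    return EnoseFeatureVector(values, feature_names(normalized.sensor_ids), normalized.fruit_id)


def enose_feature_table(
    recordings: Iterable[SensorRecording],
    baseline_window: tuple[float, float] = (200.0, 210.0),
    window: tuple[float, float] = (211.0, 250.0),
) -> pd.DataFrame:
    """Baseline-correct and featurize a batch of recordings.

    Returns a fruits x 39 table indexed by ``fruit_id`` and sorted by it, so
    the result does not depend on input order.  All recordings must share a
    sensor ordering.
    """
    rows: dict[str, np.ndarray] = {}
    ids: tuple[str, ...] | None = None
    for rec in recordings:
        if ids is None:
            ids = rec.sensor_ids
        elif rec.sensor_ids != ids:
            raise ValueError(
                f"heterogeneous sensor orderings: {rec.sensor_ids} vs {ids}"
            )
        fv = extract_enose_features(baseline_correct(rec, baseline_window), window)
        key = fv.fruit_id if fv.fruit_id is not None else f"fruit{len(rows):04d}"
        rows[key] = fv.values
    columns = feature_names(ids if ids is not None else SENSOR_IDS)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "fruit_id"
    return table.sort_index()


def write_recording_csv(path: str | Path, recording: SensorRecording) -> None:
    df = pd.DataFrame(recording.response.T, columns=list(recording.sensor_ids))
    df.insert(0, "time_s", recording.time_s)
    df.to_csv(path, index=False, float_format="%.9g")


def read_recording_csv(path: str | Path, fruit_id: str | None = None) -> SensorRecording:
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError("recording CSV must start with a time_s column")
    sensor_ids = tuple(df.columns[1:])
    if fruit_id is None:
        fruit_id = Path(path).stem
    return SensorRecording(
        df.iloc[:, 1:].to_numpy().T, df["time_s"].to_numpy(),
        sensor_ids=sensor_ids, fruit_id=fruit_id,
    )
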