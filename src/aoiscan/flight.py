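"""Flight-performance scoring: RMSE against instructed targets and
dual-task callout omissions.

Flight-parameter traces (speed, vertical speed, heading) sampled at 1 Hz
are scored against the instructed values with a root-mean-square error

    RMSE = sqrt( sum_i (O_i - P_i)^2 / n )

where O_i is the observed value and P_i the target.  A *point* target
(e.g. 130 kt) scores every deviation; a *band* target (e.g. vertical speed
between -800 and +500 ft/min) scores only excursions outside the band, as
the distance to the nearest bound.

The dual task asks for a spoken distance callout at fixed distance marks
on the approach; an omission is an expected mark with no produced call
within a distance tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

#: Scenario defaults: hold 130 kt, heading 143 deg, vertical speed within
#: (-800, +500) ft/min on the approach.
DEFAULT_TARGETS: dict[str, "TargetSpec"]

#: 1 Hz flight sampling against 60 Hz gaze sampling.
DEFAULT_FLIGHT_RATE_HZ = 1.0


@dataclass(frozen=True)
class TargetSpec:
    """An instructed flight target: a point value or a tolerance band."""

    kind: Literal["point", "band"]
    value: float | tuple[float, float]
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind == "band":
            low, high = self.value  # type: ignore[misc]
            if not low < high:
                raise InputError("band target needs low < high")
        elif self.kind != "point":
            raise InputError(f"unknown target kind {self.kind!r}")


DEFAULT_TARGETS = {
    "speed": TargetSpec(kind="point", value=130.0, units="kt"),
    "vertical_speed": TargetSpec(kind="band", value=(-800.0, 500.0), units="ft/min"),
    "heading": TargetSpec(kind="point", value=143.0, units="deg"),
}


@dataclass(frozen=True)
class ParameterTrace:
    """One flight parameter sampled at 1 Hz (233 samples for the standard
    four-minute approach segment)."""

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if ts.shape != vals.shape or ts.ndim != 1:
            raise InputError("timestamps and values must be equal-length 1-D")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)


def aligned_frame_count(
    n_gaze_frames: int,
    gaze_rate: float = 60.0,
    flight_rate: float = DEFAULT_FLIGHT_RATE_HZ,
) -> int:
    """Whole flight frames spanning a gaze recording.

    14 000 gaze frames at 60 Hz span 233 whole 1 Hz flight frames.
    """
    if n_gaze_frames < 0 or gaze_rate <= 0 or flight_rate <= 0:
        raise InputError("frame count and rates must be positive")
    return int(n_gaze_frames / gaze_rate * flight_rate)


def rmse_deviation(trace: ParameterTrace, target: TargetSpec) -> float:
    """Root-mean-square deviation of a trace from its instructed target.

    Point targets: error is ``O_i - value``.  Band targets: error is zero
    inside ``[low, high]`` and the distance to the nearest bound outside.
    """
    if len(trace) == 0:
        raise InputError("empty trace")
    if target.kind == "point":
        err = trace.values - float(target.value)  # type: ignore[arg-type]
    else:
        low, high = target.value  # type: ignore[misc]
        err = np.maximum(trace.values - high, 0) + np.minimum(
            trace.values - low, 0
        )
    return float(np.sqrt(np.mean(err**2)))


def count_omissions(
    expected_marks: Sequence[float],
    produced_calls: Sequence[float],
    tolerance: float = 0.1,
) -> int:
    """Expected distance marks with no matching produced callout.

    Marks are matched greedily in approach order to the nearest unused call
    within *tolerance* (nautical miles); each call can satisfy at most one
    mark.
    """
    marks = np.asarray(expected_marks, dtype=float)
    if marks.size and np.any(np.diff(marks) >= 0):
        raise InputError("expected marks must be strictly decreasing")
    calls = list(np.asarray(produced_calls, dtype=float))
    omissions = 0
    for mark in marks:
        if not calls:
            omissions += 1
            continue
        gaps = [abs(c - mark) for c in calls]
        best = int(np.argmin(gaps))
        if gaps[best] <= tolerance:
            calls.pop(best)
        else:
            omissions += 1
    return omissions


def expected_marks(
    start: float = 5.0, step: float = 0.5, end: float = 0.0
) -> np.ndarray:
    """Strictly decreasing callout marks from *start* down to just above *end*
    in decrements of *step* (e.g. 5.0, 4.5, ..., 0.5 for the 0.5 Nm task)."""
    if step <= 0 or start <= end:
        raise InputError("need step > 0 and start > end")
    n = int(round((start - end) / step))
    marks = start - step * np.arange(n)
    return np.round(marks[marks > end + 1e-9], 10)


def read_flight_log(path_or_buf) -> dict[str, ParameterTrace]:
    """Read a 1 Hz flight log (CSV with columns time, speed, vertical_speed,
    heading) into per-parameter traces."""
    df = pd.read_csv(path_or_buf)
    required = {"time", "speed", "vertical_speed", "heading"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"flight log missing columns: {sorted(missing)}")
    t = df["time"].to_numpy(dtype=float)
    return {
        name: ParameterTrace(timestamps=t, values=df[name].to_numpy(dtype=float))
        for name in ("speed", "vertical_speed", "heading")
    }
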