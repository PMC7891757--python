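"""Raw gaze streams -> cleaned dwell sequences -> transition records.

A *dwell* is a maximal contiguous episode of gaze inside one AOI (it may
span several fixations); a *transition* is the shift between two
consecutive dwells in different AOIs.  The cleaning pipeline is:

1. run-length encode per-sample AOI hits into raw dwells
   (:func:`segment_dwells`);
2. discard dwells shorter than a minimum duration (default 200 ms) and
   dwells outside every AOI, then merge adjacent same-AOI dwells
   (:func:`clean_sequence`) — e.g. the label run 1,1,4,4,5,5,5,6 collapses
   to 1,4,5,6;
3. derive one transition record per consecutive dwell pair
   (:func:`build_transitions`), carrying the spatial amplitude of the shift.

The threshold filter runs *before* merging; the two orders produce
different sequences and the filter-first order is the one used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .world_model import OUTSIDE_AOI, WorldModel

#: Standard analysis defaults: 60 Hz sampling, 200 ms dwell filter,
#: 14 000-frame scenario window.
DEFAULT_RATE_HZ = 60.0
DEFAULT_MIN_DWELL_S = 0.200
DEFAULT_N_FRAMES = 14_000


@dataclass(frozen=True)
class GazeSampleStream:
    """Time-stamped gaze samples with per-sample AOI hits.

    ``aoi_hits`` uses 1-based AOI ids with 0 meaning "outside every AOI".
    ``positions`` (N x 2, model units) is optional; when present it refines
    transition amplitudes, otherwise centroid distances are used.
    """

    timestamps: np.ndarray
    aoi_hits: np.ndarray
    rate: float = DEFAULT_RATE_HZ
    positions: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        hits = np.asarray(self.aoi_hits, dtype=int)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "aoi_hits", hits)
        if ts.ndim != 1 or hits.shape != ts.shape:
            raise InputError("timestamps and aoi_hits must be equal-length 1-D")
        if ts.size == 0:
            raise InputError("empty gaze stream")
        if np.any(np.diff(ts) <= 0):
            raise InputError("timestamps must be strictly increasing")
        if self.rate <= 0:
            raise InputError("sampling rate must be positive")
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if pos.shape != (ts.size, 2):
                raise InputError("positions must be (n_samples, 2)")
            object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        """Nominal recording span in seconds (sample count / rate)."""
        return len(self) / self.rate


@dataclass(frozen=True)
class Dwell:
    aoi: int
    onset: float
    duration: float
    mean_position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InputError("dwell duration must be positive")


@dataclass(frozen=True)
class DwellSequence:
    """Chronological dwells of one recording."""

    dwells: tuple[Dwell, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "dwells", tuple(self.dwells))
        onsets = [d.onset for d in self.dwells]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise InputError("dwell onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.dwells)

    def __iter__(self):
        return iter(self.dwells)

    @property
    def labels(self) -> np.ndarray:
        return np.array([d.aoi for d in self.dwells], dtype=int)

    @property
    def durations(self) -> np.ndarray:
        return np.array([d.duration for d in self.dwells], dtype=float)

    @property
    def total_time(self) -> float:
        return float(self.durations.sum()) if self.dwells else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aoi": self.labels,
                "onset": [d.onset for d in self.dwells],
                "duration": self.durations,
            }
        )


@dataclass(frozen=True)
class TransitionRecord:
    """One gaze shift between two different AOIs, with spatial amplitude."""

    from_aoi: int
    to_aoi: int
    amplitude: float

    def __post_init__(self) -> None:
        if self.from_aoi == self.to_aoi:
            raise InputError("a transition must change AOI")
        if self.amplitude < 0:
            raise InputError("transition amplitude must be >= 0")


def segment_dwells(stream: GazeSampleStream) -> DwellSequence:
    """Run-length encode per-sample AOI hits into raw (unfiltered) dwells.

    Each maximal run of identical hits becomes one dwell of duration
    ``run length / rate``; runs outside every AOI become dwells with the
    sentinel id 0 and are removed later by :func:`clean_sequence`.
    """
    hits = stream.aoi_hits
    boundaries = np.flatnonzero(np.diff(hits)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [hits.size]))
    dwells = []
    for s, e in zip(starts, ends):
        pos = None
        if stream.positions is not None:
            pos = tuple(np.nanmean(stream.positions[s:e], axis=0))
        dwells.append(
            Dwell(
                aoi=int(hits[s]),
                onset=float(stream.timestamps[s]),
                duration=(e - s) / stream.rate,
                mean_position=pos,
            )
        )
    return DwellSequence(dwells=tuple(dwells), source_id=stream.source_id)


def _merge_run(run: list[Dwell]) -> Dwell:
    if len(run) == 1:
        return run[0]
    dur = sum(d.duration for d in run)
    pos = None
    if all(d.mean_position is not None for d in run):
        w = np.array([d.duration for d in run])
        xy = np.array([d.mean_position for d in run])
        pos = tuple((xy * w[:, None]).sum(axis=0) / w.sum())
    return Dwell(aoi=run[0].aoi, onset=run[0].onset, duration=dur, mean_position=pos)


def clean_sequence(
    seq: DwellSequence, min_dwell: float = DEFAULT_MIN_DWELL_S
) -> DwellSequence:
    """Apply the dwell filter and the same-AOI merge rule.

    Dwells shorter than ``min_dwell`` and dwells outside every AOI are
    discarded first; adjacent surviving dwells in the same AOI (including
    pairs that become adjacent through the removal) are then merged, summing
    durations.  The result has no two consecutive dwells in the same AOI,
    and the operation is idempotent.
    """
    kept = [
        d for d in seq.dwells if d.aoi != OUTSIDE_AOI and d.duration >= min_dwell
    ]
    if not kept:
        if seq.dwells:
            warnings.warn(
                f"cleaning removed every dwell of {seq.source_id or 'sequence'}",
                stacklevel=2,
            )
        return DwellSequence(dwells=(), source_id=seq.source_id)
    merged: list[Dwell] = []
    run = [kept[0]]
    for d in kept[1:]:
        if d.aoi == run[-1].aoi:
            run.append(d)
        else:
            merged.append(_merge_run(run))
            run = [d]
    merged.append(_merge_run(run))
    return DwellSequence(dwells=tuple(merged), source_id=seq.source_id)


def trim_to_duration(stream: GazeSampleStream, n_frames: int) -> GazeSampleStream:
    """Keep exactly the final ``n_frames`` samples.

    Recordings of a common scenario end at the same event but start at
    slightly different times, so the *beginning* is cut to equalize
    durations across participants.
    """
    if len(stream) < n_frames:
        raise InputError(
            f"stream has {len(stream)} frames, cannot trim to {n_frames}"
        )
    if len(stream) == n_frames:
        return stream
    sl = slice(len(stream) - n_frames, None)
    return GazeSampleStream(
        timestamps=stream.timestamps[sl],
        aoi_hits=stream.aoi_hits[sl],
        rate=stream.rate,
        positions=None if stream.positions is None else stream.positions[sl],
        source_id=stream.source_id,
    )


def build_transitions(
    seq: DwellSequence, model: WorldModel
) -> list[TransitionRecord]:
    """One transition record per consecutive dwell pair of a cleaned sequence.

    Amplitude is the distance between the two dwells' mean gaze positions
    when both are known, else the centroid distance of the two AOIs.
    Returns ``len(seq) - 1`` records.
    """
    labels = seq.labels
    if np.any(labels[:-1] == labels[1:]):
        raise InputError(
            "sequence has consecutive same-AOI dwells; run clean_sequence first"
        )
    records = []
    for a, b in zip(seq.dwells, seq.dwells[1:]):
        if a.mean_position is not None and b.mean_position is not None:
            amp = float(np.hypot(*(np.subtract(a.mean_position, b.mean_position))))
        else:
            amp = model.distance(a.aoi, b.aoi)
        records.append(TransitionRecord(from_aoi=a.aoi, to_aoi=b.aoi, amplitude=amp))
    return records


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_gaze_log(
    path_or_buf,
    model: WorldModel | None = None,
    rate: float = DEFAULT_RATE_HZ,
    source_id: str = "",
) -> GazeSampleStream:
    """Read a gaze log (CSV) into a :class:`GazeSampleStream`.

    Expected columns: ``time`` plus either a pre-resolved ``aoi`` column or
    ``x``/``y`` gaze coordinates (resolved against *model*).
    """
    df = pd.read_csv(path_or_buf)
    if "time" not in df.columns:
        raise InputError("gaze log needs a 'time' column")
    positions = None
    if "aoi" in df.columns:
        hits = df["aoi"].to_numpy(dtype=int)
        if {"x", "y"}.issubset(df.columns):
            positions = df[["x", "y"]].to_numpy(dtype=float)
    elif {"x", "y"}.issubset(df.columns):
        if model is None:
            raise InputError("x/y gaze log needs a world model to resolve AOIs")
        positions = df[["x", "y"]].to_numpy(dtype=float)
        hits = np.array(
            [
                OUTSIDE_AOI if np.isnan(x) or np.isnan(y) else model.locate(x, y)
                for x, y in positions
            ],
            dtype=int,
        )
    else:
        raise InputError("gaze log needs an 'aoi' column or 'x'/'y' columns")
    return GazeSampleStream(
        timestamps=df["time"].to_numpy(dtype=float),
        aoi_hits=hits,
        rate=rate,
        positions=positions,
        source_id=source_id,
    )


def write_dwell_table(seq: DwellSequence, path_or_buf) -> None:
    """Write a cleaned dwell table as CSV (aoi, onset, duration)."""
    seq.to_frame().to_csv(path_or_buf, index=False)
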