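"""First-order Markov statistics of AOI scanning.

The cleaned dwell sequence of a recording is treated as a realization of a
first-order Markov chain over the AOIs.  This module provides the
transition count/probability matrix, the matrix density (fraction of cells
holding at least one transition — a dispersion index), the stationary
distribution (observed dwell proportions, or the left eigenvector of the
probability matrix), the gaze transition entropy

    GTE = - sum_i p(i) sum_{j != i} p(j|i) log2 p(j|i)   [bits]

which weighs the Shannon entropy of each source AOI's outgoing conditionals
by the stationary probability of that source, and basic dwell statistics.
Zero conventions: 0 * log 0 = 0, and source AOIs with an all-zero
transition row are skipped (no smoothing is applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .errors import DegenerateInputError, InputError
from .preprocessing import DwellSequence, TransitionRecord


@dataclass(frozen=True)
class TransitionMatrix:
    """m x m transition counts in world-model AOI order (row = from AOI i,
    column = to AOI j, both 1-based in user-facing ids)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InputError("counts must be a square matrix")
        if np.any(c < 0):
            raise InputError("counts must be non-negative")
        if np.any(np.diag(c) != 0):
            raise InputError("diagonal counts must be zero (no self-transitions)")
        object.__setattr__(self, "counts", c)

    @property
    def m(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Row-normalized conditionals p(j|i); all-zero rows stay all-zero."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(row_sums > 0, self.counts / row_sums, 0.0)
        return p

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        idx = labels if labels is not None else list(range(1, self.m + 1))
        return pd.DataFrame(self.counts, index=idx, columns=idx)


def transition_matrix(
    transitions: Iterable[TransitionRecord | tuple[int, int]], m: int
) -> TransitionMatrix:
    """Tally transitions into an m x m count matrix.

    Accepts :class:`TransitionRecord` objects or bare ``(from, to)`` pairs
    with 1-based AOI ids in ``1..m``.
    """
    counts = np.zeros((m, m), dtype=int)
    for t in transitions:
        i, j = (t.from_aoi, t.to_aoi) if isinstance(t, TransitionRecord) else t
        if not (1 <= i <= m and 1 <= j <= m):
            raise InputError(f"AOI id out of range 1..{m}: ({i}, {j})")
        if i == j:
            raise InputError(f"self-transition {i}->{j}; sequence not cleaned")
        counts[i - 1, j - 1] += 1
    return TransitionMatrix(counts=counts)


def matrix_density(tm: TransitionMatrix) -> float:
    """Fraction of matrix cells containing at least one transition.

    The denominator is the full m^2 cell count (diagonal included), so a
    cleaned sequence can reach at most m(m-1)/m^2.  High density indicates
    dispersed, wandering scanning; low density a narrow scan.
    """
    return float((tm.counts >= 1).sum() / tm.m**2)


def _labels_of(seq: DwellSequence | Sequence[int]) -> np.ndarray:
    if isinstance(seq, DwellSequence):
        return seq.labels
    return np.asarray(seq, dtype=int)


def stationary_distribution(
    seq: DwellSequence | Sequence[int],
    m: int,
    mode: Literal["dwell-proportion", "eigenvector"] = "dwell-proportion",
) -> np.ndarray:
    """Stationary AOI probabilities p(i) weighting the entropy terms of GTE.

    ``dwell-proportion`` (default) returns observed dwell occurrence
    frequencies.  ``eigenvector`` returns the left stationary vector of the
    empirical probability matrix, which requires the chain restricted to the
    visited AOIs to be irreducible; unvisited AOIs get probability 0.
    """
    labels = _labels_of(seq)
    if labels.size == 0:
        raise InputError("empty dwell sequence")
    if labels.min() < 1 or labels.max() > m:
        raise InputError(f"AOI id out of range 1..{m}")
    if mode == "dwell-proportion":
        counts = np.bincount(labels, minlength=m + 1)[1:]
        return counts / counts.sum()
    if mode != "eigenvector":
        raise InputError(f"unknown mode {mode!r}")

    tm = transition_matrix(list(zip(labels[:-1], labels[1:])), m)
    active = (tm.counts.sum(axis=1) + tm.counts.sum(axis=0)) > 0
    if not active.any():
        raise DegenerateInputError("no transitions; stationary vector undefined")
    sub = tm.probabilities[np.ix_(active, active)]
    n_comp, comp = connected_components(sub > 0, directed=True, connection="strong")
    if n_comp > 1:
        main = np.bincount(comp).argmax()
        stranded = np.flatnonzero(active)[comp != main] + 1
        raise DegenerateInputError(
            f"chain is reducible; AOIs not mutually reachable: {stranded.tolist()}"
        )
    vals, vecs = np.linalg.eig(sub.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.abs(np.real(vecs[:, k]))
    p = np.zeros(m)
    p[active] = v / v.sum()
    return p


def gaze_transition_entropy(tm: TransitionMatrix, p: np.ndarray) -> float:
    """Stationary-weighted Shannon entropy of the transition conditionals.

    Returns bits in ``[0, log2(m - 1)]``.  Higher values mean less
    predictable AOI switching.  Sources with zero stationary weight or an
    all-zero transition row contribute nothing.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (tm.m,):
        raise InputError(f"stationary vector must have length m={tm.m}")
    probs = tm.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(probs > 0, np.log2(np.where(probs > 0, probs, 1.0)), 0.0)
    row_entropy = -(probs * logs).sum(axis=1)
    return float((p * row_entropy).sum())


@dataclass(frozen=True)
class ScanningStatistics:
    """Basic dwell statistics of one cleaned recording."""

    n_dwells: int
    mean_dwell_time: float
    aoi_time_share: dict[int, float]
    outside_share: float | None = None


def scanning_statistics(
    seq: DwellSequence, stream_duration: float | None = None
) -> ScanningStatistics:
    """Dwell count, mean dwell duration and per-AOI time shares.

    With a known ``stream_duration`` the shares are fractions of the whole
    recording and ``outside_share`` is the remainder spent in no retained
    AOI; otherwise shares are fractions of total retained dwell time.
    """
    if len(seq) == 0:
        return ScanningStatistics(0, float("nan"), {}, None)
    durations = seq.durations
    labels = seq.labels
    total = durations.sum()
    denom = stream_duration if stream_duration is not None else total
    shares = {
        int(a): float(durations[labels == a].sum() / denom)
        for a in np.unique(labels)
    }
    outside = None
    if stream_duration is not None:
        if total > stream_duration * (1 + 1e-9):
            raise InputError("total dwell time exceeds stream duration")
        outside = float(max(0.0, 1.0 - total / stream_duration))
    return ScanningStatistics(
        n_dwells=len(seq),
        mean_dwell_time=float(durations.mean()),
        aoi_time_share=shares,
        outside_share=outside,
    )
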