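"""Ambient/focal attention: the coefficient K.

Each dwell duration d_i is paired with the amplitude a_{i+1} of the
transition that follows it, and both channels are standardized:

    kappa_i = (d_i - mu_d) / rho_d  -  (a_{i+1} - mu_a) / rho_a
    K       = mean(kappa_i)

K > 0 means relatively long dwells followed by short shifts (focal
attention, concentrated inspection); K < 0 means short dwells followed by
long shifts (ambient attention, diffuse monitoring).

The standardization scope matters.  Under ``per-recording`` scope the
means/SDs come from that recording alone, which forces the recording mean
K to the exact identity ``K = -z(d_last) / n_pairs`` (the final dwell has
no following transition, so its z-score is the only term that fails to
cancel) — useful for windowed dynamics but structurally near zero as an
aggregate.  Group comparisons therefore default to ``pooled`` scope, where
means/SDs are computed over all recordings of the dataset and recordings
can differ meaningfully in K.  Standard deviations use the sample (n-1)
denominator by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateInputError, InputError

Scope = Literal["per-recording", "pooled"]


@dataclass(frozen=True)
class KResult:
    """Coefficient-K outcome for one recording."""

    k_series: np.ndarray
    k_mean: float
    n_pairs: int
    standardization_scope: str
    sd_ddof: int = 1


def _validate(durations: np.ndarray, amplitudes: np.ndarray) -> None:
    if durations.size < 2:
        raise InputError("a recording needs at least 2 dwells")
    if amplitudes.size != durations.size - 1:
        raise InputError(
            f"expected {durations.size - 1} amplitudes for {durations.size} "
            f"dwells, got {amplitudes.size}"
        )


def _moments(x: np.ndarray, ddof: int, channel: str) -> tuple[float, float]:
    if x.size <= ddof:
        raise InputError(f"too few {channel} values to estimate a sample SD")
    sd = float(np.std(x, ddof=ddof))
    if sd == 0:
        raise DegenerateInputError(
            f"{channel} are constant; K is undefined without variance"
        )
    return float(np.mean(x)), sd


def coefficient_k(
    recordings: Sequence[tuple[Sequence[float], Sequence[float]]],
    scope: Scope = "pooled",
    ddof: int = 1,
) -> list[KResult]:
    """Compute K for each ``(dwell durations, transition amplitudes)`` pair.

    Each recording supplies its n dwell durations and the n-1 amplitudes of
    the transitions between them; pair i is ``(d_i, a_{i+1})``.  All dwells
    (including the final unpaired one) and all amplitudes enter the means
    and SDs of their scope.

    Raises :class:`DegenerateInputError` if either channel is constant over
    its standardization scope, naming the channel — a zero SD is never
    silently substituted.
    """
    if not recordings:
        raise InputError("no recordings given")
    if scope not in ("per-recording", "pooled"):
        raise InputError(f"unknown standardization scope {scope!r}")
    parsed = []
    for d, a in recordings:
        d = np.asarray(d, dtype=float)
        a = np.asarray(a, dtype=float)
        _validate(d, a)
        parsed.append((d, a))

    if scope == "pooled":
        all_d = np.concatenate([d for d, _ in parsed])
        all_a = np.concatenate([a for _, a in parsed])
        mu_d, rho_d = _moments(all_d, ddof, "dwell durations")
        mu_a, rho_a = _moments(all_a, ddof, "transition amplitudes")

    results = []
    for d, a in parsed:
        if scope == "per-recording":
            mu_d, rho_d = _moments(d, ddof, "dwell durations")
            mu_a, rho_a = _moments(a, ddof, "transition amplitudes")
        kappa = (d[:-1] - mu_d) / rho_d - (a - mu_a) / rho_a
        results.append(
            KResult(
                k_series=kappa,
                k_mean=float(kappa.mean()),
                n_pairs=int(kappa.size),
                standardization_scope=scope,
                sd_ddof=ddof,
            )
        )
    return results
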