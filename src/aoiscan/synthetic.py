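"""Seeded synthetic cockpit-scanning cohorts.

No public corpus of cockpit gaze recordings exists, so the package ships a
generator that emulates the statistical structure the analysis assumes:

* AOI switching follows a first-order Markov chain with a group-specific
  transition matrix — the ``expert-like`` preset spreads transition mass
  across all ten AOIs, the ``novice-like`` preset concentrates at least
  70 % of each row's mass on the primary-flight-display regions (AOIs 1-5);
* dwell durations are log-normal (positive, right-skewed) with
  group-specific target means — 1.1 s for the expert-like and 1.51 s for
  the novice-like preset — and a within-recording coefficient of variation
  of 0.5;
* measurement noise: sub-threshold flicker dwells (< 200 ms, removed by the
  cleaning filter), brief off-AOI gaps between dwells, and longer off-AOI
  dropouts carved inside dwells (which split a dwell and exercise the
  remove-then-merge rule);
* flight traces are the instructed target plus AR(1) noise with a
  group-specific stationary SD, and distance callouts are produced at the
  expected marks with a group-specific omission probability.

Everything is reproducible from one master seed; per-recording seeds are
derived and listed in the cohort manifest.  With all noise rates at zero
the cleaned pipeline output equals the stored truth sequence exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .flight import DEFAULT_TARGETS, ParameterTrace, TargetSpec, expected_marks
from .preprocessing import (
    DEFAULT_MIN_DWELL_S,
    DEFAULT_N_FRAMES,
    DEFAULT_RATE_HZ,
    DwellSequence,
    GazeSampleStream,
    clean_sequence,
    segment_dwells,
)

# Target-attraction weights used to build the preset transition matrices.
# Each row of the matrix starts from the weight vector with the self-weight
# zeroed and renormalized.  The expert-like profile distributes mass over
# the whole panel; the novice-like profile concentrates on the PFD
# (AOIs 1-5) with an occasional glance out of the window, mirroring the
# observed contrast between dispersed expert matrices and PFD-bound novice
# matrices.
_EXPERT_WEIGHTS = np.array(
    [0.16, 0.12, 0.11, 0.07, 0.09, 0.08, 0.05, 0.06, 0.10, 0.16]
)
_NOVICE_WEIGHTS = np.array(
    [0.32, 0.22, 0.16, 0.06, 0.10, 0.015, 0.005, 0.005, 0.005, 0.09]
)

# Expert scanning is not merely dispersed: trained pilots share stereotyped
# instrument circuits (windshield -> monitoring display -> attitude,
# windshield -> vertical speed -> attitude, ...).  The expert-like rows
# blend the dispersed weights with this shared-circuit component so the
# group exhibits common multi-AOI patterns, as trained cohorts do.
_EXPERT_CIRCUIT: dict[int, dict[int, float]] = {
    10: {9: 0.30, 3: 0.25, 1: 0.25, 5: 0.20},  # OTW -> ECAM / VS / ATT / HDG
    9: {1: 0.60, 10: 0.40},
    3: {1: 0.60, 10: 0.40},
    5: {1: 0.60, 10: 0.40},
    1: {3: 0.40, 10: 0.35, 2: 0.25},
    2: {1: 0.50, 10: 0.50},
}
_EXPERT_CIRCUIT_MIX = 0.55

_PRESET_DWELL = {"expert-like": (1.1, 0.55), "novice-like": (1.51, 0.755)}


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters of one synthetic population."""

    name: str
    transition_matrix: np.ndarray
    dwell_mean: float  # target arithmetic mean dwell duration, s
    dwell_sd: float  # target arithmetic SD of dwell duration, s
    flicker_prob: float = 0.08  # sub-threshold flicker per eligible dwell
    transit_gap_prob: float = 0.5  # brief off-AOI gap between dwells
    dropout_prob: float = 0.10  # off-AOI dropout carved inside a dwell
    flight_sd: Mapping[str, float] = field(
        default_factory=lambda: {"speed": 4.0, "vertical_speed": 250.0, "heading": 2.0}
    )
    omission_rate: float = 0.1
    callout_step_nm: float = 0.5

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ConfigurationError("transition matrix must be square")
        if np.any(np.diag(P) != 0):
            raise ConfigurationError("transition matrix diagonal must be zero")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
            raise ConfigurationError("transition matrix rows must sum to 1")
        object.__setattr__(self, "transition_matrix", P)
        if self.dwell_mean <= 0 or self.dwell_sd <= 0:
            raise ConfigurationError("dwell mean and SD must be positive")
        for rate in (
            self.flicker_prob,
            self.transit_gap_prob,
            self.dropout_prob,
            self.omission_rate,
        ):
            if not (0 <= rate <= 1):
                raise ConfigurationError("noise rates must be in [0, 1]")

    @property
    def m(self) -> int:
        return int(self.transition_matrix.shape[0])

    def noise_free(self) -> "GroupProfile":
        return replace(
            self, flicker_prob=0.0, transit_gap_prob=0.0, dropout_prob=0.0
        )


def _matrix_from_weights(
    weights: np.ndarray,
    m: int,
    circuit: Mapping[int, Mapping[int, float]] | None = None,
    mix: float = 0.0,
) -> np.ndarray:
    if m != weights.size:
        # resample the weight profile onto m AOIs, keeping its shape
        weights = np.interp(
            np.linspace(0, 1, m), np.linspace(0, 1, weights.size), weights
        )
        circuit = None  # the circuit is defined for the 10-AOI panel only
    P = np.tile(weights / weights.sum(), (m, 1))
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    if circuit:
        C = np.zeros((m, m))
        for i, row in circuit.items():
            for j, w in row.items():
                C[i - 1, j - 1] = w
        has_circuit = C.sum(axis=1) > 0
        C[has_circuit] /= C[has_circuit].sum(axis=1, keepdims=True)
        P[has_circuit] = (1 - mix) * P[has_circuit] + mix * C[has_circuit]
        P /= P.sum(axis=1, keepdims=True)
    return P


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def make_profile(
    preset: str, m: int = 10, **overrides
) -> GroupProfile:
    """Build a named group profile.

    ``expert-like``: dispersed transitions, 1.1 s mean dwell, few callout
    omissions, tight flight tracking.  ``novice-like``: PFD-concentrated
    transitions (>= 70 % of each row's mass on AOIs 1-5), 1.51 s mean
    dwell, more omissions, looser tracking.  Any field of
    :class:`GroupProfile` can be overridden by keyword.
    """
    if preset == "expert-like":
        params = dict(
            name=preset,
            transition_matrix=_matrix_from_weights(
                _EXPERT_WEIGHTS, m, _EXPERT_CIRCUIT, _EXPERT_CIRCUIT_MIX
            ),
            dwell_mean=_PRESET_DWELL[preset][0],
            dwell_sd=_PRESET_DWELL[preset][1],
            flight_sd={"speed": 2.7, "vertical_speed": 160.0, "heading": 2.0},
            omission_rate=0.07,
        )
    elif preset == "novice-like":
        params = dict(
            name=preset,
            transition_matrix=_matrix_from_weights(_NOVICE_WEIGHTS, m),
            dwell_mean=_PRESET_DWELL[preset][0],
            dwell_sd=_PRESET_DWELL[preset][1],
            flight_sd={"speed": 5.5, "vertical_speed": 350.0, "heading": 2.0},
            omission_rate=0.25,
        )
    else:
        raise ConfigurationError(f"unknown preset {preset!r}")
    params.update(overrides)
    return GroupProfile(**params)


@dataclass(frozen=True)
class SyntheticRecording:
    """One generated recording: the rendered 60 Hz stream, the noise-free
    truth dwell sequence (cleaned), flight traces and produced callouts."""

    stream: GazeSampleStream
    truth: DwellSequence
    traces: dict[str, ParameterTrace]
    calls: np.ndarray
    profile_name: str
    seed: int


def simulate_aoi_chain(
    matrix: np.ndarray, n_steps: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw a 1-based AOI label sequence from a first-order Markov chain.

    The start state is drawn uniformly.  Returns ``n_steps`` labels, hence
    ``n_steps - 1`` transitions.
    """
    P = np.asarray(matrix, dtype=float)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    m = P.shape[0]
    cum = P.cumsum(axis=1)
    states = np.empty(n_steps, dtype=int)
    state = int(rng.integers(m))
    states[0] = state
    draws = rng.random(n_steps - 1)
    for t in range(1, n_steps):
        state = int(np.searchsorted(cum[state], draws[t - 1], side="right"))
        states[t] = state
    return states + 1


def _draw_dwell_frames(
    profile: GroupProfile, n: int, rng: np.random.Generator, rate: float
) -> np.ndarray:
    mu, sigma = _lognormal_params(profile.dwell_mean, profile.dwell_sd)
    durations = rng.lognormal(mu, sigma, size=n)
    # keep every truth dwell comfortably above the 200 ms cleaning threshold
    durations = np.clip(durations, 0.25, 6.0)
    return np.maximum(np.round(durations * rate).astype(int), 15)


def simulate_recording(
    profile: GroupProfile,
    n_frames: int = DEFAULT_N_FRAMES,
    seed: int = 0,
    rate: float = DEFAULT_RATE_HZ,
    flight_targets: Mapping[str, TargetSpec] | None = None,
) -> SyntheticRecording:
    """Render one synthetic recording at the gaze sampling rate.

    The Markov chain supplies the AOI itinerary and the log-normal the dwell
    lengths; noise (flicker, transit gaps, dropouts) is injected per the
    profile's rates; the stream is truncated to exactly ``n_frames``.
    Flight traces cover the whole 1 Hz frames spanned by the stream.
    Bit-identical output for identical ``(profile, n_frames, seed)``.
    """
    if n_frames < int(5 * rate):
        raise InputError("n_frames too small to hold a few dwells")
    rng = np.random.default_rng(seed)
    m = profile.m

    # generous dwell budget: mean dwell can't be shorter than 0.25 s
    n_dwells = int(n_frames / (0.25 * rate)) + 8
    labels = simulate_aoi_chain(profile.transition_matrix, n_dwells, rng)
    frames = _draw_dwell_frames(profile, n_dwells, rng, rate)

    truth_hits: list[np.ndarray] = []
    noisy_hits: list[np.ndarray] = []
    truth_total = noisy_total = 0
    prev_aoi = 0
    for idx, (aoi, n_fr) in enumerate(zip(labels, frames)):
        if truth_total < n_frames + 1:
            truth_hits.append(np.full(n_fr, aoi))
            truth_total += n_fr
        if noisy_total >= n_frames + 1:
            continue
        block = np.full(n_fr, aoi)
        # flicker: a sub-threshold glance at a third AOI steals the first
        # frames of the dwell (stays < 200 ms so cleaning drops it)
        if (
            idx > 0
            and rng.random() < profile.flicker_prob
            and n_fr >= 15 + 11
        ):
            steal = int(rng.integers(4, 12))
            choices = [a for a in range(1, m + 1) if a not in (aoi, prev_aoi)]
            block[:steal] = int(rng.choice(choices))
        # dropout: tracker loss inside a long dwell (cleaning removes the
        # gap and re-merges the two halves)
        if rng.random() < profile.dropout_prob and n_fr >= 15 + 15 + 18:
            gap = int(rng.integers(6, 19))
            start = int(rng.integers(15, n_fr - gap - 15 + 1))
            block[start : start + gap] = 0
        # brief off-AOI transit between dwells
        if idx > 0 and rng.random() < profile.transit_gap_prob:
            noisy_hits.append(np.zeros(int(rng.integers(1, 4)), dtype=int))
            noisy_total += len(noisy_hits[-1])
        noisy_hits.append(block)
        noisy_total += n_fr
        prev_aoi = aoi

    truth_arr = np.concatenate(truth_hits)[:n_frames]
    noisy_arr = np.concatenate(noisy_hits)[:n_frames]
    if noisy_arr.size < n_frames:  # extreme noise settings only
        noisy_arr = np.pad(noisy_arr, (0, n_frames - noisy_arr.size))
    timestamps = np.arange(n_frames) / rate

    truth_stream = GazeSampleStream(
        timestamps=timestamps, aoi_hits=truth_arr, rate=rate, source_id="truth"
    )
    truth_seq = clean_sequence(segment_dwells(truth_stream), DEFAULT_MIN_DWELL_S)

    source_id = f"{profile.name}-{seed}"
    stream = GazeSampleStream(
        timestamps=timestamps, aoi_hits=noisy_arr, rate=rate, source_id=source_id
    )

    targets = dict(flight_targets or DEFAULT_TARGETS)
    n_flight = int(n_frames / rate)
    t_flight = np.arange(n_flight, dtype=float)
    traces = {}
    phi = 0.97  # slow AR(1) drift around the instructed value
    innov_scale = math.sqrt(1.0 - phi**2)
    for name, target in targets.items():
        center = (
            float(target.value)
            if target.kind == "point"
            else float(np.mean(target.value))
        )
        sd = float(profile.flight_sd.get(name, 1.0))
        x = np.empty(n_flight)
        x[0] = rng.normal(0.0, 1.0)
        eps = rng.normal(0.0, innov_scale, size=n_flight - 1)
        for t in range(1, n_flight):
            x[t] = phi * x[t - 1] + eps[t - 1]
        traces[name] = ParameterTrace(timestamps=t_flight, values=center + sd * x)

    marks = expected_marks(start=5.0, step=profile.callout_step_nm)
    produced = marks[rng.random(marks.size) >= profile.omission_rate]
    calls = produced + rng.normal(0.0, 0.02, size=produced.size)

    return SyntheticRecording(
        stream=stream,
        truth=truth_seq,
        traces=traces,
        calls=calls,
        profile_name=profile.name,
        seed=int(seed),
    )


@dataclass(frozen=True)
class SyntheticCohort:
    """A seeded collection of recordings plus its reproducibility manifest."""

    recordings: tuple[SyntheticRecording, ...]
    manifest: tuple[dict, ...]
    master_seed: int

    def by_group(self) -> dict[str, list[SyntheticRecording]]:
        groups: dict[str, list[SyntheticRecording]] = {}
        for rec in self.recordings:
            groups.setdefault(rec.profile_name, []).append(rec)
        return groups


def simulate_cohort(
    profiles: Sequence[GroupProfile],
    n_per_group: int = 16,
    n_frames: int = DEFAULT_N_FRAMES,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate ``n_per_group`` recordings per profile.

    Per-recording seeds are derived from the master seed and listed in the
    manifest, so any single recording can be regenerated in isolation.
    """
    if not profiles:
        raise InputError("need at least one profile")
    rng = np.random.default_rng(seed)
    rec_seeds = rng.integers(0, 2**31 - 1, size=len(profiles) * n_per_group)
    recordings = []
    manifest = []
    k = 0
    for profile in profiles:
        for i in range(n_per_group):
            rec_seed = int(rec_seeds[k])
            recordings.append(simulate_recording(profile, n_frames, rec_seed))
            manifest.append(
                {
                    "profile": profile.name,
                    "index": i,
                    "seed": rec_seed,
                    "n_frames": n_frames,
                }
            )
            k += 1
    return SyntheticCohort(
        recordings=tuple(recordings),
        manifest=tuple(manifest),
        master_seed=int(seed),
    )
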