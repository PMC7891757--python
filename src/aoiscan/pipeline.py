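"""End-to-end orchestration: recordings -> per-recording metric reports ->
group summaries (common n-grams, classification).

A single configuration mapping drives everything; the defaults block
carries the standard analysis parameters (200 ms dwell filter, 60 Hz, a
14 000-frame scenario window, n-grams of length 3-6, 5 folds, 35 PCA
components, 10 neighbours).  Reports are plain JSON validated against the
bundled pydantic schema.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .attention import coefficient_k
from .classify import build_feature_table, crossvalidated_knn
from .errors import ConfigurationError, InputError
from .flight import (
    DEFAULT_TARGETS,
    count_omissions,
    expected_marks,
    rmse_deviation,
)
from .markov import (
    TransitionMatrix,
    gaze_transition_entropy,
    matrix_density,
    scanning_statistics,
    stationary_distribution,
    transition_matrix,
)
from .patterns import common_ngrams, lempel_ziv_complexity, ngram_counts
from .preprocessing import (
    GazeSampleStream,
    build_transitions,
    clean_sequence,
    read_gaze_log,
    segment_dwells,
    trim_to_duration,
)
from .synthetic import SyntheticCohort, make_profile, simulate_cohort
from .world_model import WorldModel, default_world_model, load_world_model

log = logging.getLogger("aoiscan")

DEFAULTS: dict = {
    "min_dwell": 0.200,
    "rate": 60.0,
    "n_frames": 14_000,
    "ngram_lengths": [3, 4, 5, 6],
    "ngram_support": 1.0,
    "k_scope": "pooled",
    "folds": 5,
    "neighbors": 10,
    "components": 35,
    "callout_tolerance_nm": 0.1,
    "seed": 0,
}


class RecordingReport(BaseModel):
    """Schema of one per-recording JSON report."""

    model_config = ConfigDict(extra="forbid")

    source_id: str
    group: str
    n_dwells: int
    mean_dwell_time: float
    outside_share: float | None
    matrix_density: float
    gte_bits: float
    lzc: int
    k_mean: float | None
    k_scope: str
    rmse: dict[str, float]
    omissions: int | None


class GroupSummary(BaseModel):
    model_config = ConfigDict(extra="forbid")

    group: str
    n_recordings: int
    mean_dwell_time: float
    mean_n_dwells: float
    mean_gte_bits: float
    mean_lzc: float
    mean_k: float | None
    common_ngrams: dict[int, int]


class RunReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    package_version: str
    seed: int
    n_recordings: int
    groups: list[GroupSummary]
    classification: dict | None


def load_config(path_or_mapping) -> dict:
    """Merge a user configuration (YAML path/text or mapping) over DEFAULTS."""
    if isinstance(path_or_mapping, Mapping):
        user = dict(path_or_mapping)
    else:
        text = Path(path_or_mapping).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, Mapping):
            raise ConfigurationError("configuration must be a mapping")
    cfg = dict(DEFAULTS)
    cfg.update(user)
    return cfg


def analyze_recording(
    stream: GazeSampleStream,
    model: WorldModel,
    cfg: Mapping | None = None,
):
    """Run the gaze pipeline for one recording.

    Returns ``(metrics dict, cleaned DwellSequence, TransitionMatrix)``;
    the coefficient K is filled in later at dataset level (its default
    standardization scope pools all recordings).
    """
    cfg = {**DEFAULTS, **(cfg or {})}
    if len(stream) >= cfg["n_frames"]:
        stream = trim_to_duration(stream, cfg["n_frames"])
    seq = clean_sequence(segment_dwells(stream), cfg["min_dwell"])
    if len(seq) < 2:
        raise InputError(f"{stream.source_id}: too few dwells after cleaning")
    transitions = build_transitions(seq, model)
    tm = transition_matrix(transitions, model.m)
    p = stationary_distribution(seq, model.m, mode="dwell-proportion")
    stats = scanning_statistics(seq, stream_duration=stream.duration)
    metrics = {
        "source_id": stream.source_id,
        "n_dwells": stats.n_dwells,
        "mean_dwell_time": stats.mean_dwell_time,
        "outside_share": stats.outside_share,
        "matrix_density": matrix_density(tm),
        "gte_bits": gaze_transition_entropy(tm, p),
        "lzc": lempel_ziv_complexity(seq.labels.tolist()),
    }
    return metrics, seq, tm


def run_pipeline(config, out_dir) -> RunReport:
    """Execute the full analysis described by *config* and write reports.

    The configuration either names an input directory of gaze logs (keyed
    by group) or a ``synthesis`` block; outputs are one JSON report per
    recording, a cohort CSV, per-group summaries and a run report.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if "world_model" in cfg and cfg["world_model"] not in (None, "default"):
        model = load_world_model(Path(cfg["world_model"]).read_text())
    else:
        model = default_world_model()

    recordings: list[tuple[str, GazeSampleStream, object]] = []
    if "synthesis" in cfg:
        syn = cfg["synthesis"]
        profiles = [
            make_profile(name, m=model.m) for name in syn.get(
                "profiles", ["expert-like", "novice-like"]
            )
        ]
        cohort = simulate_cohort(
            profiles,
            n_per_group=int(syn.get("n_per_group", 16)),
            n_frames=int(syn.get("n_frames", cfg["n_frames"])),
            seed=int(syn.get("seed", cfg["seed"])),
        )
        (out / "manifest.json").write_text(
            json.dumps(list(cohort.manifest), indent=1)
        )
        for rec in cohort.recordings:
            recordings.append((rec.profile_name, rec.stream, rec))
    elif "inputs" in cfg:
        in_dir = Path(cfg["inputs"]["directory"])
        files = sorted(in_dir.glob("*.csv"))
        if not files:
            raise ConfigurationError(f"no gaze logs found in {in_dir}")
        for f in files:
            group = f.stem.split("_")[0]
            stream = read_gaze_log(
                f, model=model, rate=cfg["rate"], source_id=f.stem
            )
            recordings.append((group, stream, None))
    else:
        raise ConfigurationError("config needs a 'synthesis' or 'inputs' block")

    per_rec: list[dict] = []
    sequences = []
    matrices = []
    groups = []
    for group, stream, syn_rec in recordings:
        try:
            metrics, seq, tm = analyze_recording(stream, model, cfg)
        except (InputError, ConfigurationError) as exc:
            log.error("skipping %s: %s", stream.source_id, exc)
            continue
        metrics["group"] = group
        if syn_rec is not None:
            metrics["rmse"] = {
                name: rmse_deviation(trace, DEFAULT_TARGETS[name])
                for name, trace in syn_rec.traces.items()
            }
            profile_step = 0.5
            metrics["omissions"] = count_omissions(
                expected_marks(step=profile_step),
                syn_rec.calls,
                tolerance=cfg["callout_tolerance_nm"],
            )
        else:
            metrics["rmse"] = {}
            metrics["omissions"] = None
        per_rec.append(metrics)
        sequences.append(seq)
        matrices.append(tm)
        groups.append(group)

    if not per_rec:
        raise InputError("no recording survived preprocessing")

    # dataset-level K (pooled standardization by default)
    k_scope = cfg["k_scope"]
    pairs = []
    for seq, tm, metrics in zip(sequences, matrices, per_rec):
        transitions = build_transitions(seq, model)
        pairs.append(
            (seq.durations, np.array([t.amplitude for t in transitions]))
        )
    k_results = coefficient_k(pairs, scope=k_scope)
    for metrics, kr in zip(per_rec, k_results):
        metrics["k_mean"] = kr.k_mean
        metrics["k_scope"] = k_scope

    for metrics in per_rec:
        report = RecordingReport(**metrics)
        (out / f"{metrics['source_id']}.json").write_text(
            report.model_dump_json(indent=1)
        )
    pd.DataFrame(
        [
            {k: v for k, v in m.items() if k not in ("rmse",)}
            | {f"rmse_{p}": v for p, v in m["rmse"].items()}
            for m in per_rec
        ]
    ).to_csv(out / "cohort_metrics.csv", index=False)

    group_names = sorted(set(groups))
    summaries = []
    for gname in group_names:
        idx = [i for i, g in enumerate(groups) if g == gname]
        common = {}
        if len(idx) >= 2:
            for n in cfg["ngram_lengths"]:
                tables = [
                    ngram_counts(sequences[i].labels.tolist(), n) for i in idx
                ]
                common[n] = len(common_ngrams(tables, cfg["ngram_support"]))
        sub = [per_rec[i] for i in idx]
        summaries.append(
            GroupSummary(
                group=gname,
                n_recordings=len(idx),
                mean_dwell_time=float(
                    np.mean([m["mean_dwell_time"] for m in sub])
                ),
                mean_n_dwells=float(np.mean([m["n_dwells"] for m in sub])),
                mean_gte_bits=float(np.mean([m["gte_bits"] for m in sub])),
                mean_lzc=float(np.mean([m["lzc"] for m in sub])),
                mean_k=float(np.mean([m["k_mean"] for m in sub])),
                common_ngrams=common,
            )
        )

    classification = None
    if len(group_names) >= 2:
        table = build_feature_table(matrices, groups)
        try:
            report = crossvalidated_knn(
                table,
                k_folds=cfg["folds"],
                neighbors=cfg["neighbors"],
                n_components=cfg["components"],
                seed=cfg["seed"],
            )
            classification = {
                "overall_accuracy": report.overall_accuracy,
                "fold_accuracies": list(report.fold_accuracies),
                "confusion": report.confusion.tolist(),
                "classes": list(report.classes),
                "chance_level": report.chance_level,
                "n_components": report.n_components,
            }
        except Exception as exc:  # classification failing must not void reports
            log.error("classification skipped: %s", exc)

    run = RunReport(
        package_version=__version__,
        seed=int(cfg["seed"]),
        n_recordings=len(per_rec),
        groups=summaries,
        classification=classification,
    )
    (out / "run_report.json").write_text(run.model_dump_json(indent=1))
    return run
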