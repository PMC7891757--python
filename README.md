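# aoiscan

Analysis of *visual scanning strategies* over a panel of named areas of
interest (AOIs) — typified by how airline pilots monitor cockpit
instruments. Given time-stamped gaze samples, the package segments them
into AOI dwells, derives the transition sequence, and computes the metric
families used to characterize and compare scanning behaviour between
groups (e.g. expert pilots vs. novices):

- **Markov metrics** — transition count/probability matrices, matrix
  density (fraction of cells with at least one transition), stationary
  distributions, and **gaze transition entropy**
  `GTE = -Σᵢ p(i) Σ_{j≠i} p(j|i) log₂ p(j|i)` (bits);
- **attentional mode** — the ambient/focal **coefficient K**,
  `κᵢ = z(dᵢ) − z(aᵢ₊₁)`, the mean standardized contrast between each
  dwell duration and the following transition amplitude (K > 0: focal,
  K < 0: ambient);
- **pattern metrics** — **Lempel-Ziv complexity** (distinct phrases in the
  left-to-right parse of the AOI sequence) and **n-gram mining** with
  group-common pattern counts;
- **expertise classification** — PCA + cosine-distance KNN on flattened
  transition-probability matrices (100 features for the 10-AOI cockpit
  model) under stratified cross-validation, judged against an exact
  binomial chance level;
- **flight-performance scoring** — RMSE of speed / vertical-speed /
  heading traces against instructed targets, and dual-task callout
  omission counts;
- a **seeded synthetic cohort generator** (first-order Markov scanpaths
  with group-specific matrices and log-normal dwells, tracker noise,
  flight traces, callouts) so the whole pipeline is testable end to end
  without any proprietary recordings.

Intended users: human-factors and eye-tracking researchers working with
AOI-level scanpaths (aviation, driving, ATC, medical imaging).

## Worked example

Analyse a synthetic 16 + 16 cohort (14 000 gaze frames per recording at
60 Hz, the standard four-minute approach window):

```
$ cat demo.yaml
synthesis:
  profiles: [expert-like, novice-like]
  n_per_group: 16
  n_frames: 14000
  seed: 7
seed: 7

$ aoiscan run --config demo.yaml --out demo_run
{
 "package_version": "0.1.0",
 "seed": 7,
 "n_recordings": 32,
 "groups": [
  {
   "group": "expert-like",
   "n_recordings": 16,
   "mean_dwell_time": 1.072063377126296,
   "mean_n_dwells": 209.9375,
   "mean_gte_bits": 2.3160111993746373,
   "mean_lzc": 85.5,
   "mean_k": -0.556985393985394,
   "common_ngrams": {"3": 9, "4": 0, "5": 0, "6": 0}
  },
  {
   "group": "novice-like",
   "n_recordings": 16,
   "mean_dwell_time": 1.4595778905777779,
   "mean_n_dwells": 155.5625,
   "mean_gte_bits": 2.077601707206224,
   "mean_lzc": 62.5625,
   "mean_k": 0.7567955225320815,
   "common_ngrams": {"3": 6, "4": 1, "5": 0, "6": 0}
  }
 ],
 "classification": {
  "overall_accuracy": 0.96875,
  ...
  "chance_level": 0.6875,
  "n_components": 20
 }
}
```

Reading the numbers: the expert-like group shows the signatures of trained
scanning — more dwells (210 vs. 156) that are shorter (1.07 s vs. 1.46 s),
higher transition entropy (2.32 vs. 2.08 bits, less predictable switching
across more instruments), higher Lempel-Ziv complexity (more varied
patterns), more shared trigram patterns within the group (9 vs. 6), and a
more ambient attentional mode (lower K). A cosine-KNN on the flattened
transition matrices separates the groups at 96.9 % accuracy, well above
the exact binomial chance level of 68.75 % for 32 samples and two classes
at α = 0.05. The run directory contains one validated JSON report per
recording, a cohort CSV, the seed manifest and the group summary above.

The same works library-first:

```python
from aoiscan import (default_world_model, make_profile, simulate_recording,
                     clean_sequence, segment_dwells)
from aoiscan.pipeline import analyze_recording

model = default_world_model()          # the 10-AOI cockpit layout
rec = simulate_recording(make_profile("expert-like"), 14_000, seed=3)
metrics, seq, tm = analyze_recording(rec.stream, model)
print(metrics["n_dwells"], metrics["gte_bits"], metrics["lzc"])
# 205 2.7927368606958935 92   (seed 3; dispersion varies with the profile)
```

Gaze logs are plain CSV (`time` plus `aoi`, or `time,x,y` resolved
against a world model); world models are small YAML documents (see
`src/aoiscan/data/default_world_model.yaml`).

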