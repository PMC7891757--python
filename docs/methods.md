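# Methods

## Scope and data model

The package analyses *AOI-level* scanpaths: gaze positions already
discretized into a small set of named areas of interest. The unit of
analysis is the **dwell** — a maximal contiguous episode of gaze inside
one AOI, possibly spanning several fixations — and the **transition**
between consecutive dwells in different AOIs. Fixation/saccade event
detection from raw eye velocity is deliberately out of scope; streams
enter either with a pre-resolved AOI id per sample or with planar
coordinates that are resolved against a world model.

The world model is an ordered registry of regions; its order fixes the
row/column order of every matrix downstream. The bundled default lays the
ten cockpit regions (five primary-flight-display sub-regions, navigation
display and its distance read-out zone, flight control unit, systems
display, windshield) out on a schematic millimetre panel. The source data
give no region coordinates, so the layout is chosen for plausible relative
geometry only: every metric except the coefficient-K amplitudes is
geometry-free, and K uses amplitudes only through within-dataset z-scores,
so only the relative arrangement of centroids matters. Samples inside no
region carry the sentinel id 0; they are excluded from all metrics and
surface only as the reported "outside share" of recording time.

## Preprocessing

Per-sample hits are run-length encoded into raw dwells (duration =
run length / sampling rate; default rate 60 Hz). Cleaning then
(1) discards dwells shorter than `min_dwell` (default 0.200 s, the
conventional minimum for a deliberate instrument check) together with all
outside dwells, and (2) merges adjacent same-AOI dwells, summing
durations. Filtering runs *before* merging; the reverse order yields
different sequences (a short interruption would otherwise protect its
neighbours from merging). A consequence worth knowing: an off-AOI dropout
inside a long dwell splits it, and after gap removal the two halves merge
back — so brief tracker losses do not fragment the sequence. No
gap-bridging tolerance is applied beyond this. `clean_sequence` is
idempotent and its output never contains two consecutive dwells in the
same AOI, which every downstream metric assumes.

Recordings of a common scenario are equalized by cutting the *beginning*
(the end is anchored at a common event such as touch-down); the default
window is 14 000 frames, i.e. 233⅓ s, spanning 233 whole 1 Hz flight
frames.

## Metrics

**Transition matrix and density.** Counts are tallied over ordered AOI
pairs; probabilities are row-normalized with all-zero rows left zero.
Density divides active cells by the full m² cell count (diagonal
included), so cleaned sequences cap at m(m−1)/m² = 0.9 for m = 10.

**Stationary distribution.** Default is the observed dwell-occurrence
proportion (the common choice when entropy weights are estimated from the
same recording); a model-based left-eigenvector mode is provided and
demands irreducibility of the visited-state subchain, raising an error
naming the unreachable AOIs otherwise.

**Gaze transition entropy.** `−Σᵢ p(i) Σ_{j≠i} p(j|i) log₂ p(j|i)` bits,
bounded by log₂(m−1). Conventions: 0·log 0 = 0; sources with zero
stationary mass or an empty row are skipped; no smoothing is applied
(documented because smoothing choices silently move entropy values).

**Coefficient K.** Pairs each dwell duration with the *following*
transition amplitude and averages the difference of z-scores. All dwells
(including the final, unpaired one) and all amplitudes enter the moments;
SDs use the sample (n−1) denominator; both choices are configurable and
recorded in the result. The standardization scope defaults to **pooled**
across the dataset: under per-recording scope the z-scores telescope and
the recording mean collapses to the exact identity
`K = −z(d_last)/n_pairs` (asserted in the tests), which is structurally
near zero and useless for group comparison — pooled scoping is what makes
distinct group means possible. Degenerate inputs (a constant channel)
raise an error naming the channel rather than substituting a zero SD.

**Lempel-Ziv complexity.** Distinct-phrase counting of the left-to-right
parse: the current word extends while it matches an already-recorded
phrase and is recorded the moment it does not; a trailing incomplete word
counts as a phrase. This is the variant fixed by the reference parse
`101001010010111 → 1|0|10|01|010|0101|11` (7 phrases). Note it differs
from the exhaustive-history production parse, under which the same string
yields 4 phrases; the worked parse above is the contract, pinned by test.
Under this variant a constant run follows triangular phrase growth
(`a|aa|aaa|…`), also pinned by test.

**N-grams.** Overlapping windows at stride 1 (totals = L − n + 1).
"Common" patterns default to the strict intersection across group members
(support 1.0); a support fraction is exposed because majority-based
definitions are also in use. A filter for n-grams with pairwise-distinct
AOIs separates multi-instrument routines from back-and-forth
redundancies.

**Classification.** Transition-probability matrices are flattened
row-major (feature (i−1)·m+(j−1) = p(i→j), 100 features at m = 10), PCA
is fitted *inside each training fold* by default (leakage-free; the
requested 35 components are capped at the training-fold rank, e.g. ≤ 24
for 25-row folds), and a cosine-distance 10-nearest-neighbour vote is
cross-validated with seeded stratified 5-folds. Vote ties break to the
class with the smallest summed neighbour distance, then to the lowest
class label — fully deterministic given the seed. The chance level is the
smallest accuracy whose exact Binomial(n, 1/c) upper-tail probability is
below α, computed with integer arithmetic (no normal approximation):
68.75 % for n = 32, c = 2, α = 0.05.

**Flight scoring.** RMSE against a point target scores every deviation;
against a band target it scores only excursions, as distance to the
nearest bound — the only reading that makes an RMSE against a tolerance
range well defined. The default vertical-speed band is (−800, +500)
ft/min with speed 130 kt and heading 143°. Callout omissions use greedy
nearest matching of produced calls to expected marks within a tolerance
(default 0.1 Nm); each call satisfies at most one mark.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
representing a 16 + 16 expert/novice design at 14 000 frames:

- **AOI switching**: first-order Markov. The *novice-like* matrix
  concentrates ≥ 70 % of every row's mass on the PFD regions (AOIs 1–5).
  The *expert-like* matrix blends dispersed attraction weights with a
  shared scan-circuit component (windshield → systems display / vertical
  speed / heading → attitude loops, mix 0.55): dispersion alone would
  make the expert group share *fewer* common n-grams than novices,
  whereas trained cohorts are dispersed *and* stereotyped.
- **Dwell durations**: log-normal (positive, right-skewed, standard for
  dwell data), parameters solved from target mean/SD — mean 1.1 s
  (expert-like) vs. 1.51 s (novice-like), CV 0.5 within recording,
  clipped to [0.25, 6] s so every truth dwell survives the 200 ms filter.
- **Noise**: sub-threshold flicker dwells (4–11 frames, probability 0.08
  per eligible dwell), 1–3-frame off-AOI transit gaps between dwells
  (probability 0.5), and 6–18-frame off-AOI dropouts carved inside long
  dwells (probability 0.10). All three are built to be removed by the
  cleaning rules, so the cleaned label sequence matches the truth
  sequence; total outside time lands near the few-percent level typical
  of cockpit recordings. With all rates zero the cleaned output equals
  the truth exactly (tested).
- **Flight traces**: instructed target + AR(1) noise (φ = 0.97) with
  group-specific stationary SDs (expert tighter); callouts at 0.5 Nm
  marks skipped with probability 0.07 (expert-like) / 0.25 (novice-like).
- **Seeding**: one master seed; per-recording seeds are derived once and
  listed in the manifest, so any recording regenerates in isolation.

What passing recovery tests do and do not show: the cohort tests
demonstrate that the *pipeline* recovers the generator's contrasts
(dwell count and duration, GTE, LZC orderings; classification above the
exact chance level; chance-level behaviour for identical generators) in
≥ 90 % of 20 master seeds. Because the generator is first-order Markov
with independent log-normal dwells, this says nothing about oculomotor
realism (saccade dynamics, pupil, fixation microstructure) or about
higher-order sequential structure in real scanning beyond the injected
circuits.

A known statistical limitation, kept deliberately: the novice-like preset
almost never dwells on NDz/FCU/ECAM (stationary mass ≈ 0.006), so in a
10⁵-transition chain those matrix rows receive only a few hundred visits
and their empirical conditionals cannot beat their own binomial standard
error (≈ 0.02). Convergence of the matrix estimator at the ±0.02 / 10⁵
level is therefore verified on generating matrices whose rows are all
adequately visited (the expert-like preset, dense random matrices), and
on the novice preset's adequately sampled rows; diluting the novice tails
to gain row visits was rejected because it inverts the entropy contrast
the cohort is meant to exhibit.

## Numerical and degenerate-input choices

- Row normalization leaves unvisited sources as zero rows; GTE skips
  them; the eigenvector mode refuses reducible chains instead of
  returning an arbitrary vector.
- Empty cleaned sequences warn and return empty rather than raising, so a
  cohort run survives a single bad recording; the pipeline logs and skips
  such recordings.
- PCA component requests are capped at the feasible rank with a warning
  (a 32-row table supports at most 31; a 25-row training fold at most 24).
- All randomness flows through `numpy.random.default_rng` from explicit
  integer seeds; reports record the seed, the K standardization scope and
  SD convention, and whether PCA was fold-local.
- Problem sizes in the test suite (16 + 16 recordings, 14 000 frames,
  20 master seeds, 10⁵-step chains) match the defaults above; they are
  the study-scale conditions the generator was designed around.
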