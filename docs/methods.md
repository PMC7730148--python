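# Methods

This note documents the models implemented in `gazemine`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Preprocessing

**Fixation detection (I-VT).** Gaze samples (`t_ms, x_px, y_px, valid`)
are classified by angular velocity: consecutive samples whose
displacement stays below a threshold form fixation runs; faster gaps are
saccadic and split runs. Velocity is computed sample-to-sample by
default; a `velocity_window` parameter allows a wider displacement
window for noisy trackers. Pixel displacements convert to visual angle
through the screen geometry (physical diagonal, resolution, viewing
distance) with the arctangent formula; the defaults describe a 27-inch
1920×1080 display viewed from 60 cm, giving ≈ 33.6 px/deg near the
screen centre.

- `velocity_threshold` — 20 deg/s. The conventional I-VT cutoff for
  separating fixations from saccades at 60 Hz sampling.
- `min_dwell` — 100 ms. Runs shorter than this are discarded; complex
  image interpretation rarely extracts information from briefer stops.
- Invalid samples (blinks, tracking loss) split runs rather than being
  interpolated — conservative, at the cost of occasionally splitting one
  physiological fixation in two. A fixation's dwell is the time span of
  its member samples and its centroid their mean position.

**ROI assignment.** Every fixation receives exactly one label from the
image's ROI polygon set: (1) inside exactly one polygon → that label;
(2) inside several overlapping polygons → the minimal-area polygon, i.e.
the most specific region; (3) inside none → the nearest boundary.
Boundary points count as inside. Ties break deterministically (smaller
area, then lexicographic label) so repeated runs agree bit for bit.

**Binning and pooling.** Each fixation is expanded into
`ceil(dwell / bin_window)` repeated tokens (window 150 ms). The ceiling
guarantees at least one token per fixation and reproduces the reference
behaviour that a 445 ms fixation yields three tokens. All contiguous
token windows with length in `[min_len, max_len]` (defaults 4 and 16)
form the case's subsequence pool, deduplicated within a case — support
counts cases, not occurrences, so within-case multiplicity is
irrelevant. Exhaustive windows are used rather than goal-based
segmentation: they are the implementable superset of any segmentation a
viewer's sub-goals might induce. `max_len = 16` bounds the window
combinatorics at roughly 2.4 s of dwell, the scale of the longest
patterns worth reading as a single unit.

## Spatial representation and distance

The graph keeps one vertex per visited ROI (fixation count, total
dwell) and one undirected edge per observed direct transition;
self-transitions and duplicate edges are trimmed. Edge weights
`(dwell(u)+dwell(v)) × transitions(u,v)` are retained for export and
inspection but deliberately do not enter the distance, which counts
unmatched edges only.

The distance has three components with weights `w_e = w_n = w_g = 1/3`
(equal emphasis unless the analyst wants otherwise) and `w_f = w_d =
1/2` inside the node component:

- `d_struct = (unmatched edges of G₁) / |E₁|` — an edge is matched when
  both endpoints are mapped and their images are adjacent in G₂. Empty
  `E₁` returns 0 by convention (a one-ROI case has no structure to
  mismatch).
- `d_node` — over mapped nodes, absolute fixation-count differences
  normalized by G₁'s total fixation count plus absolute dwell
  differences normalized by G₁'s total dwell. Both denominators come
  from G₁, paralleling the structural normalization; zero totals return
  0 with a warning.
- `d_node_gaps` — mean gap penalty of unmapped G₁ nodes. Penalties
  default to 1 and can be set per ROI by domain experts to encode
  semantic importance.

The node mapping matches identical labels first, then pairs leftover
nodes sharing an `ontology_class` (choosing the candidate with the
closest total dwell; ties by label). The mapping is injective. An edge
can be unmatched because an endpoint is unmapped *and* that endpoint
simultaneously incurs a gap penalty; the two components deliberately
measure different things (structure vs presence) and are reported
separately, but analysts should be aware of the coupling when weighting.

The distance is asymmetric (G₁ is the reference); distance matrices use
the mean of both directions so downstream pooling does not depend on
case order. Raw directed values remain available.

## Temporal representation and distance

The n-th order Markov model (n ≤ 5, consistent with the ≈4-item span of
visual working memory) stores, per observed history `h` of n labels,
`A[h→j] = count(h→j)/count(h→·) × dwell(last(h))/Σ dwell`. Rows sum to
the dwell weight of the history's last ROI — the structure is a
dwell-weighted transition profile, not a stochastic matrix, which is
exactly why the distance renormalizes. `π` is a point mass on the first
fixation's ROI (first n-gram for n > 1; for sequences shorter than n the
available prefix is used, and sequences shorter than n+1 produce a
π-only model). Group comparisons default to order 1; the order is a
parameter everywhere.

The temporal distance flattens each model over the union of both key
sets (transition entries concatenated with π), adds `α = 1e-6` to every
coordinate, renormalizes both vectors to probability simplices and
applies KL divergence with natural logarithms (values in nats). The
smoothing is applied symmetrically to both vectors: KL is undefined on
zeros, and smoothing only the reference would make the distance depend
on which model happens to be first. `α` trades sensitivity to
never-observed transitions against numerical robustness; at 1e-6 the
smoothing mass is negligible relative to any observed weight.

## Pattern mining

Support of window `p` in a group: the fraction of cases whose pool
contains at least one window within Levenshtein distance θ of `p`
(θ = 2 by default — tolerating roughly one stray fixation and one dwell
mis-bin). A case counts once however many similar windows it holds.
Growth of `p` against the other group: its own support divided by the
*maximum* support among θ-similar windows of the other group's pool —
equivalently the minimum support ratio over all similar matches — and
infinite when no similar window exists there. Common patterns need
support ≥ ρ (0.2) in both groups and growth < ε (2) in both directions;
contrast patterns for a group are drawn from that group's own pool with
support ≥ ρ there and growth ≥ ε. Drawing contrast candidates from the
source group's own pool keeps every mined pattern a verbatim subsequence
of a real scanpath in its group.

Pattern sets are deduplicated by exact token string only; θ-similar
patterns remain distinct entries. An analyst wanting one representative
per similarity neighbourhood can cluster post hoc; the mined sets are
the raw, canonical answer.

Summary statistics per set: count, mean/max token length, mean pairwise
Levenshtein and bag-of-ROI cosine distance over unordered pairs
(unweighted — patterns are not weighted by support), mean own-group
support, and the percentage of patterns with infinite growth ("unique"
to the group). The bag-of-ROI distance (1 − cosine of token-count
vectors) measures which regions a pattern visits regardless of order.

**Exactness of the fast paths.** Levenshtein runs through `edlib` on
byte-packed tokens (alphabets are limited to 255 labels). Three
shortcuts accelerate mining without changing any result: (a) windows
whose length differs from the candidate's by more than θ are skipped —
the length difference lower-bounds the edit distance; (b) per-case
presence is screened with an infix alignment of the candidate against
the whole binned string — the unconstrained infix distance lower-bounds
every window-constrained distance, and a reported in-bounds span is
itself a certificate; the rare ambiguous outcome falls back to an exact
window scan; (c) growth denominators scan the other pool in descending
support order with a symbol-count feasibility bound (one edit moves the
count vector by at most 2 in L1) and stop at the first verified similar
match, which attains the maximum. Equivalence with exhaustive
enumeration is asserted in the test suite on randomized instances.

## Group comparison

For each task, all unordered case pairs receive symmetrized spatial and
temporal distances. The default protocol tests the within-group
distances of a reference group against its between-group distances to
each comparison group with the two-sided Mann–Whitney U test (exact
null distribution when both sides have ≤ 8 values and no ties; normal
approximation with continuity correction otherwise). Raw p-values are
reported; a Benjamini–Hochberg column is optional extra output.

**Caveat — dependence.** Pairwise distances within a distribution share
cases and are positively correlated; the U test assumes independent
samples. The protocol is applied to the pooled pairs as-is, which is
the standard practice for this kind of analysis, so p-values are
descriptive rather than exactly calibrated. In null simulations with
two groups drawn from one strategy (12 cases per group, 500 replicates)
the empirical rejection rate at α = 0.05 is ≈ 0.16 for the spatial
metric and ≈ 0.06 for the temporal metric: the smooth spatial distance
propagates a single atypical case coherently into all of its pairs,
inflating the test, while the heavy-tailed KL distance is close to
nominal. Conclusions drawn from small spatial p-values should therefore
rest on effect sizes and on the mined patterns, not on the p-value
alone.

## Synthetic generator

The generator emulates the target recording conditions: 15 s sessions
at 60 Hz over an annotated layout on a 27-inch display at 60 cm. A
group's `StrategyProfile` holds a categorical ROI-visit distribution,
lognormal per-group dwells (mean 420 ms, CV 0.45 — typical of complex
image inspection), a stray-fixation rate (5% of fixations land at a
uniform random screen point), a saccade speed (250 deg/s), and planted
token subsequences with per-case inclusion probabilities.

Realization choices are made so that preprocessing inverts generation
exactly: saccades are linear sweeps whose per-sample velocity exceeds
the I-VT threshold (when two targets are too close for a detectable
sweep a single invalid sample is emitted instead, splitting the runs);
planted runs of k tokens get dwell `(k − 0.5) × bin_window` (midpoint
of the k-token bin, and 125 ms for k = 1 to clear the 100 ms minimum),
so binning recovers exactly k tokens despite sampling jitter. Planted
blocks are spliced between filler fixations at positions whose planned
time leaves room before the session ends, and the ground-truth sidecar
records which blocks were fully realized. Per-case RNG streams derive
from `SeedSequence(entropy=(seed, group_index, case_index))`, so a case
regenerates identically regardless of library size and library files
are byte-identical across runs.

Three canned conditions define the simulation studies: *planted
contrast* (identical filler behaviour; group 1 carries a 6-token
pattern over two ROIs the other group never deliberately visits, 80%
inclusion), *distinct strategies* (disjoint ROI focus, 550 vs 320 ms
dwells), and *identical strategies* (the null). The default study size
is 2 groups × 12 cases.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: oculomotor dynamics (main-sequence
velocity profiles, microsaccades, smooth pursuit), calibration drift
and spatially correlated tracker noise, image-content-driven salience,
and within-group heterogeneity of viewers. Synthetic sessions are
cleaner than real recordings; recovery rates measured here are upper
bounds.

## Known limitations

- At desk scale (12 cases/group, ~100-token sequences) the contrast
  sets contain, besides any genuinely distinctive patterns, a few
  hundred windows that qualify by chance: with ~20k candidate windows
  and support granularity 1/12, fluctuations clear ρ = 0.2 with
  growth ≥ 2 regularly, in both groups symmetrically. Contrast mining
  ranks candidates for expert review; it is not a significance test,
  and its output should be read jointly with the support values.
- The spatial Mann–Whitney protocol is anti-conservative under the
  null (see above).
- The union-key KL distance compares only coordinates observed in at
  least one model; unobserved-in-both transitions contribute nothing.
  On tiny alphabets a dense evaluation differs by the smoothing mass of
  those zero-zero coordinates (≈ α per coordinate), which is negligible
  at α = 1e-6.
- Pairwise pattern statistics are quadratic in the set size; they are
  intended for contrast sets (hundreds of patterns), not for the much
  larger common sets.
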