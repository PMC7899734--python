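# Methods

## Model

A monitoring session is modelled as a dynamic network
`DynN = {N_1, …, N_T}`: the timeline is partitioned into `T` contiguous
half-open intervals `[start, end)` (equal widths by default, or explicit
cut points), and each interval `t` gets a weighted directed graph
`N_t = (V_t, E_t, M_t)`.  The vertex set `V_t` contains exactly the AOI
states fixated during that interval — single targets (`A`) and overlap
states (`(A;B)`, produced when a fixation lands in the intersection of two
or more target regions).  Targets present on the display but never fixated
are absent by construction: including the combinatorially many possible
overlap states that never occur would bloat every matrix without adding
information.  The edge weight `w_ij(t)` counts adjacent ordered pairs
`(i, j)` in the interval's *collapsed* fixation sequence.

Collapsing (merging maximal runs of the same state: `AABCC` → `ABC`) is
applied after off-AOI fixations are dropped, so a run `A, off, A` collapses
to a single `A`.  Consequences worth knowing:

- the count matrix has a zero diagonal, enforced at construction
  (`build_transition_matrix` refuses raw sequences rather than silently
  putting repeat-fixation mass on the diagonal);
- the matrix grand total equals `len(collapsed) − 1`;
- the collapsed sequence is a walk on the graph, so per-vertex
  `|indegree − outdegree| ≤ 1`, with exact equality at every vertex when
  the interval starts and ends on the same state.  Equality is *not* an
  invariant of the model and is not enforced; only the walk-balance bound
  is.

Transitions never span interval boundaries: each interval's sequence is
built independently, so the pair (last state of interval `t`, first state
of `t+1`) is counted nowhere.  A fixation belongs to the interval containing
its onset; a fixation whose duration straddles a boundary is not split.

## Importance measures

Distance between AOIs is the inverse transition count,
`d_ij(t) = 1/w_ij(t)`, with `w = 0` meaning no edge (infinite distance).
On this distance:

- `I_j(t)`: column sum of `M_t` (integer);
- `C_j(t) = Σ_{k≠j} 1/d*_jk(t)` where `d*` is the directed shortest-path
  distance; unreachable `k` contribute 0 (the harmonic convention, the only
  one consistent with the reciprocal form when the graph is disconnected);
- `B_j(t) = Σ_{k≠l, both ≠ j} SP_klj(t)/SP_kl(t)`, summing the fraction of
  tied shortest `k→l` paths that use `j` as an intermediate; pairs with
  `SP_kl = 0` contribute 0.

Edge distances are unit fractions of small integers, so the implementation
does all shortest-path arithmetic in exact rationals
(`fractions.Fraction`): Dijkstra for distances, then shortest-path counting
over the DAG of *tight* edges (`d(s,u) + l_uv = d(s,v)`), with
`SP_klj = σ_k(j)·σ_j(l)` when `d*(k,j) + d*(j,l) = d*(k,l)`.  Exactness
matters because betweenness must *count* ties, and tie detection with
floating-point path lengths (e.g. `1` vs `1/3 + 1/3 + 1/3`) is fragile.
Shortest paths are necessarily simple here since all edge distances are
strictly positive.  Measures are computed per interval on that interval's
vertex set only (`m_t`, not the universe), so an AOI absent from an
interval simply has no record there.

On the worked four-interval example the measures evaluate to, for interval
1: `I_B = 4`, `d*_BE = min[1, 1/3+1/3] = 2/3`, `C_A = 8`, `C_B = 5.7`,
`B_A = 6`, `B_B = 0`; and for interval 2: `I_B = 3`, `C_B = 4.75`,
`B_B = 8`.  A caveat for readers comparing against hand-worked accounts of
this example: a closeness of 2.375 paired with a betweenness of 8 cannot
arise in interval 1 — 8 exceeds the hard ceiling `(m_t−1)(m_t−2) = 6` of a
4-vertex network — while interval 2 yields betweenness 8 exactly and
closeness 4.75, twice 2.375.  This package follows the defining equations
throughout.

## Normalization

Percent normalization divides each indegree by the interval's indegree sum
(shares summing to 1).  It is restricted to indegree — closeness and
betweenness are not shares of a conserved total — and requesting it for
another measure raises rather than computing something meaningless.
Distance normalization `(v − min)/(max − min)` applies to all three
measures and maps each interval's extremes to 0 and 1.  Degenerate
intervals (all values equal, or all-zero indegree) map to all-zeros with a
warning: 0 keeps the "distance below the maximum" reading and avoids a
division by zero.  Both normalizations are strictly within-interval; there
is no cross-interval or cross-participant pooling.

## AOI geometry and hit testing

Each target's AOI at time `t` is the axis-aligned bounding box covering its
icon point and its data-block rectangle, linearly interpolated between
trajectory samples (the emulated scenario updates at 1 s, coarse relative
to fixation timing), inflated on all sides by a margin.  The margin is
specified as a visual angle and converted via
`margin_px = tan(margin_deg) · viewing_distance_cm · pixel_pitch_px_per_cm`;
defaults are 0.75°, 60 cm, and 40.66 px/cm (a 2048 px display spanning
19.83 in), giving ≈ 32 px.  The 0.75° default sits in the middle of the
0.5–1.0° accuracy band typical of remote eye trackers: the margin exists to
absorb tracker error, not to model target extent.  A bounding box is a
deliberate simplification of tight convex dynamic AOI boundaries:
reproducible and parameter-light, at the cost of slightly generous corners.
Hit testing is inclusive of box edges and returns the set of *all*
containing labels, so overlap states emerge directly from geometry.

## Synthetic scenarios

`simulate_targets` emulates an enroute-like picture: by default 39 targets
on a 2048 × 2048 px display over 1200 s, entering and leaving so that
roughly twenty are present per frame (entry uniform in the first half,
presence length 40–60 % of the session), moving with constant velocity
(2–12 px/s, reflected at the display edges), geometry sampled at 1 s.
Declared overlap episodes `(a, b, t0, t1)` reposition target `b` adjacent
to `a` during the span — a step change at the span edges, chosen for
determinism and verifiability over kinematic smoothness — and raise an
error if the pair is not co-present throughout (explicit presence spans are
accepted when control is needed).

`simulate_scanpath` draws planned fixation targets from a first-order
Markov transition matrix; dwell durations are log-normal (median 300 ms,
σ_log 0.5, resampled below the 100 ms fixation-detection floor — typical of
scanning fixations in monitoring tasks), fixations land at the target
region's center plus Gaussian jitter, and an optional off-AOI rate emits
fixations placed outside every region.  A planned target absent at emission
time is resampled among the present ones (logged); if the walk outruns the
scenario, time wraps to the start, which splices independent walk segments
— recovery experiments should therefore size `duration_s` to hold the whole
walk (≈ 0.36 s per fixation at the defaults).

What the generator does *not* emulate: saccade dynamics and landing-site
error models, cognitively driven scanning (conflict anticipation, priority
queues), data-block text, or display clutter.  Passing the recovery tests
shows the pipeline inverts its own generative model — transition structure
in, transition structure out — not that it captures human gaze behaviour.

## Visualization

All panels of one dynamic-network figure share a single grid layout:
states in canonical order (singles first, uppercase block then lowercase,
alphabetical; then overlap states by member count, then lexicographically),
filled row-major from the bottom-left corner rightward then upward, with
`⌈√n⌉` columns (six states → 3 × 2).  A state keeps its cell in every
panel; in intervals where it was not fixated it is drawn ghosted (grey,
minimum size) with its position reserved, preserving the reader's mental
map.  Node area is `min_area + scale · fixations`, node color a sequential
yellow→red map over dwell duration (bounds global across panels by
default, so color is comparable over time; per-interval bounds available),
and edge width is proportional to the transition count.  Absolute scale
constants are arbitrary; only proportionality and monotonicity are
contractual, and every renderer returns its attribute table (positions,
areas, color values, widths, heights) so tests and downstream tools read
numbers, not pixels.  For cross-participant bar plots the caller filters to
the AOI states common to the participants being compared.

## Numerical and design choices

- Exact rational shortest-path arithmetic (above); float comparison with a
  1e-9 relative tolerance would also be defensible, exactness is simply
  stronger and cheap at these graph sizes (`m_t` rarely exceeds a few
  dozen).
- Interval membership is half-open `[start, end)` on fixation onset; the
  final interval's end is nudged by 1e-9 s in the pipeline so the last
  trajectory sample is not orphaned.
- Canonical state order everywhere (matrices, tables, layouts) rather than
  order of first appearance: deterministic output files, byte-identical
  across repeated seeded runs.
- Degenerate inputs: empty window → empty sequence with a warning; empty
  matrix → empty network; single-vertex network → closeness and betweenness
  0; `k = l` shortest-path queries are errors.
- The problem sizes used by the test and acceptance suites (networks of
  ≤ 6 vertices for oracle comparison, 10⁴-fixation recovery runs, 4-target
  full-presence scenarios) were chosen to exercise every code path with
  exhaustive or law-of-large-numbers checks; the pipeline itself has no
  size constants baked in.

## Known limitations

- Bounding-box AOIs overestimate overlap relative to convex outlines,
  especially for diagonal icon–block arrangements.
- No cross-boundary transitions and no time-respecting (temporal-path)
  centralities: each interval is analyzed independently, so the framework
  does not see flows that happen to straddle a cut point.
- The wrap-around behaviour of long simulated walks splices the Markov
  chain (see above).
- Interval choice is the analyst's: nothing here derives event-based
  boundaries from the data.
- Figures are static; no animation or interactive playback.
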