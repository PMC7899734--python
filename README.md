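# dnetgaze

Dynamic-network analysis of eye-movement scanpaths over moving, overlapping,
multi-element targets.

## The problem

In monitoring tasks such as enroute air traffic control, an observer watches
a few dozen labelled targets (an aircraft icon plus its data block) that move
continuously, enter and leave the display, and occasionally overlap.  Static
area-of-interest (AOI) summaries — total fixation count or dwell time per
region — mislead here: a target's importance changes over the session, and
raw fixation mass ignores how attention *flows between* targets.

`dnetgaze` analyzes such sessions as a **dynamic network**.  The session is
split into time intervals; in each interval the collapsed AOI fixation
sequence (adjacent repeats merged, e.g. `AABCC` → `ABC`) is turned into a
weighted directed graph whose edge weight $w_{ij}(t)$ counts gaze
transitions $i \to j$.  A fixation inside the intersection of two target
regions produces an overlap state written `(A;B)`, a first-class vertex.

On each interval network $N_t = (V_t, E_t, M_t)$, with the inter-AOI
distance defined as the inverse transition count $d_{ij}(t) = 1/w_{ij}(t)$,
three time-resolved importance measures are computed:

- **indegree** $I_j(t) = \sum_{k \ne j} w_{kj}(t)$ — direct attention received;
- **closeness** $C_j(t) = \sum_{k \ne j} 1/d^*_{jk}(t)$ — access to the rest
  of the network, where $d^*_{jk}$ is the shortest-path distance
  (unreachable AOIs contribute 0);
- **betweenness** $B_j(t) = \sum_{k \ne l \ne j} SP_{klj}(t)/SP_{kl}(t)$ —
  the share of shortest attention routes between other AOI pairs that pass
  through $j$, counting all tied shortest paths.

Shortest-path arithmetic is exact (rational edge distances), so path-length
ties are detected exactly rather than within a float tolerance.  Measures
are normalized within each interval — indegree as a percentage share
($\bar I_j(t)$, summing to 1) and all three measures by min–max distance
normalization ($\tilde \varnothing_j(t) \in [0,1]$) — and rendered as
mental-map-preserving small-multiples network panels, a dot plot of
attention shares over time, and grouped bar plots for cross-participant or
cross-measure comparison.

A synthetic-scenario module generates enroute-like target trajectories and
Markov-governed scanpaths, so the whole pipeline is testable end to end
without any recorded data.

## Worked example

A hypothetical four-interval scanpath over seven targets, with one fixated
overlap state `(D;G)`, written as a `t<TAB>sequence` file:

```
1	ABABABEBAEAEACACAEA
2	EAEAEAEABABCBC(D;G)C(D;G)
3	C(D;G)C(D;G)C(D;G)CEAEAEFEF
4	EFEFEFCFC(D;G)C(D;G)FC(D;G)
```

```sh
dnetgaze sequences example_seqs.tsv --out demo_out
```

prints `wrote outputs for 4 intervals to demo_out` and writes the
per-interval transition matrices, the measure tables, and the three figures.
The interval-1 transition matrix (`demo_out/matrix_t1.csv`):

```
from,A,B,C,E
A,0,3,2,3
B,3,0,0,1
C,2,0,0,0
E,3,1,0,0
```

The first rows of `demo_out/measures.csv`:

```
interval,aoi,indegree,outdegree,closeness,betweenness,fixations,dwell_ms
1,A,8,8,8.0,6.0,9,0.0
1,B,4,4,5.7,0.0,4,0.0
1,C,2,2,4.4,0.0,2,0.0
1,E,4,4,5.7,0.0,4,0.0
2,A,5,5,6.666666666666667,6.0,5,0.0
2,B,3,3,4.75,8.0,3,0.0
```

Reading these numbers: in interval 1, `A` receives 8 of the 18 transitions
(indegree 8) and lies on every shortest route between the other AOIs
(betweenness 6, the maximum possible for 4 vertices); `B`'s indegree falls
from 4 to 3 between intervals 1 and 2 while its betweenness rises from 0 to
8 — it has become a bridge in the scanning strategy even though it receives
*less* direct attention, exactly the kind of change raw fixation counts
cannot show.  The shortest distance from `B` to `E` in interval 1 is
$d^*_{BE} = \min[1/1,\; 1/3 + 1/3] = 2/3$: the two-hop route through `A`
beats the direct edge.

The full pipeline starts from fixation and trajectory CSVs instead:

```sh
dnetgaze simulate --out sim --n-targets 10 --duration 600 --n-fixations 1500 --seed 7
dnetgaze analyze --fixations sim/fixations.csv --tracks sim/tracks.csv \
    --intervals 4 --out run_out
```

`analyze` resolves each fixation against the time-aligned target geometry
(axis-aligned box over icon + data block, inflated by a visual-angle margin,
default 0.75° at 60 cm), builds the per-interval sequences, and produces the
same output bundle.

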