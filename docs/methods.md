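# Methods

## Counting model

An **induced P4** is a path on four distinct vertices whose three path
edges are present and whose three chords are absent.  A **potential P4**
through an edge is a length-3 non-backtracking walk: the first/last vertex
may coincide with the opposite end and chords are allowed.  The potential
counts are evaluated with their degree closed forms — central
(k_i−1)(k_j−1), terminal Σ(k_l−1) over the far endpoint's other
neighbours — which literally include the walk degeneracies (e.g. the a = b
coincidence in the central count).  The prose notion of "four vertices"
would suggest excluding them, but the closed forms are unambiguous and are
what the counting here implements; the bundled worked example (24 potential
/ 10 induced / score 2/5 on the marked edge) is reproduced exactly under
this reading.

Positional attribution is fixed once: each undirected induced P4
contributes exactly 1 to exactly one positional bucket (left / central /
right) of each of its three edges, with "left" meaning the lower canonical
endpoint of the edge is the path terminal.  The brute-force census
(`brute_force_p4_census`) enumerates directed walks and directed induced
paths under the same attribution and is kept fully independent of the
closed forms; the test suite asserts edge-by-edge, position-by-position
equality on hundreds of seeded random graphs.

Scores are exact `fractions.Fraction`s end to end.  The removal loop
decides ties by exact equality, so floating-point noise can neither create
nor hide a tie; scores are only converted to floats at serialization (6
decimal places) and in the statistical experiments.

Two score variants exist: the degeneracy-free C̄ = PN/(PPN+1) (default,
used by the detector) and the raw ratio C = PN/PPN with 0/0 := 0
(`adjusted=False`).  The centrality-correlation experiment defaults to the
raw ratio: on the karate network that variant reproduces the published
correlation against log-betweenness to all printed digits (0.5245), while
the adjusted score gives 0.5300, so the raw ratio is evidently what the
published correlation table measured.  At LFR densities the two variants
differ by <0.002 in r.

## The detector

`run_each` composes three stages:

1. **Removal loop** — delete the maximal-score edge until the maximum is
   zero.  Ties go to the canonically (lexicographically) smallest edge key;
   determinism was preferred over any degree-based heuristic because the
   removal trace is part of the reproducible output.  After deleting
   (i, j), only edges with an endpoint in N(i) ∪ N(j) (neighbourhoods taken
   before the deletion) are rescored: every count that can change involves
   the degree or adjacency of i or j, and any such edge has an endpoint in
   that union.  The loop asserts nothing about connectivity; components are
   independent throughout.
2. **Component split** — residual components of size ≥ 2 are the
   non-trivial communities; singletons are the isolated vertices.
3. **Isolated-vertex handling** — each isolated vertex joins the
   non-trivial component maximizing |N_v ∩ V_NC|/|V_NC| (neighbourhoods in
   the *original* graph), provided the maximum is positive.  Assignments
   are simultaneous against the pre-attachment components, so the result is
   order-independent.  Closeness ties go to the component with more shared
   neighbours, then to the one containing the smallest vertex.  Vertices
   with zero closeness to every component are grouped by their connectivity
   among themselves in the original graph rather than dropped, so the
   partition always covers V (required by NMI).  Skipping this stage is the
   EAC variant: isolated vertices stay singletons.

Because every P4-free component is a cograph (connected diameter ≤ 2) and
re-attachment adds vertices at distance 1 from some member, each final
community has induced diameter ≤ 4 in the original graph.  The acceptance
suite verifies both bounds on 20 seeded planted-partition graphs.

## Metrics

* **NMI** is computed from the confusion matrix with the 0·log 0 = 0
  convention; the degenerate case of two single-community partitions
  returns 1 (they are identical).  Algebraically this is the
  arithmetic-mean-normalized mutual information; the tests cross-check
  against scikit-learn.
* **Modularity** uses the standard Newman form Q = Σ l_c/M − (d_c/2M)².  A
  published rendering of the formula is typographically ambiguous about the
  2M; the standard form is confirmed by the karate faction split scoring
  exactly 0.3715.
* **Partition density** D = (2/M) Σ m_c[m_c−(n_c−1)]/[(n_c−2)(n_c−1)];
  communities with n_c ≤ 2 contribute 0 (limit convention — the formula is
  indeterminate there).
* **Normalized susceptibility** S̃ = Σ s²·n_s/N over all components except
  exactly one maximal one (a literal reading of "except the largest"); it
  is 0 while the graph is connected and (N−1)/N when only singletons
  remain.
* **Dismantle curves** record (f, RGC, S̃) after every removal, starting
  from the intact graph.  Betweenness and antitriangle dismantle
  highest-first, the clustering coefficient lowest-first, matching the
  divisive use of each score.  Scores are static by default (the
  correlation experiments are static) and recomputed per step with
  `recompute=True` (the algorithmic curves).

The divisive baseline (`divisive_detect`) removes to exhaustion with
per-step rescoring, evaluates all M+1 component partitions against the
original graph, and returns the argmax of Q or D.  Driven by betweenness it
is Girvan–Newman; driven by the clustering coefficient (Radicchi's
degeneracy-avoiding (z+1)/min(k_i−1, k_j−1) by default, plain ratio behind
a flag) it is the ECCA family.

## Synthetic substrates

`planted_partition_graph` (equal-size blocks, Bernoulli p_in/p_out) is the
default test substrate: it has closed-form edge expectations and needs no
iterative generator.  Defaults in the tests are 4 communities of 25,
p_in = 0.3, p_out = 0.05 — dense enough for clear structure, sparse enough
that the removal loop is exercised heavily.

`lfr_graph` delegates to networkx's LFR benchmark generator with degree
exponent 2 and community-size exponent 1.05 (1, the original example
default, is infeasible for the delegate, which requires an exponent
strictly above one).  Two calibrations make the *realized* graph match the
requested conditions, because the delegate's edge-construction loop
overshoots node degrees and places the overshoot on random cross-community
edges:

* the requested average degree is mapped to the generator's minimum-degree
  knob via the truncated power-law mean times an empirically measured
  inflation factor of 1.32 (requesting an average of 15 directly yields a
  realized mean near 22);
* the requested mixing parameter is divided by the measured inflation
  factor 1.45 (requesting μ = 0.5 directly yields realized per-node mixing
  near 0.69).

With these calibrations the default settings realize N = 1000, M ≈ 7500,
k̄ ≈ 15.1, per-node mixing 0.50 ± 0.01 and ~31 communities of size 20–50 —
the published synthetic-network conditions.  What the substrate still does
not emulate: the original benchmark's exact degree floor (realized minimum
degree is 5 rather than ~8) and its configuration-model inter-community
wiring (the delegate picks cross partners uniformly, not
degree-proportionally).  Passing tests on these graphs therefore show
recovery and correlation behaviour under faithful first-order conditions,
not bit-level agreement with the original benchmark implementation.

## Known limitations

* **Karate removal ratio.**  The exact-arithmetic removal loop removes 21
  of 78 edges on the karate club; the published ratio is 19/78.  All
  partition-quality numbers (D, Q, NMI, community count, for both EACH and
  EAC) reproduce the published values exactly, and the two extra removals
  are intra-community edges that do not change the partition.  No tie-break
  policy (lexicographic, numeric, degree-sum, random over 50 seeds) nor any
  plausible scoring variant tested removes exactly 19 while preserving the
  other numbers; the corresponding assertion is left failing rather than
  weakened.
* **LFR betweenness correlation.**  On the calibrated LFR substrate
  r(EA, log EB) ≈ 0.47, below the published 0.68 for the synthetic network,
  while r(EA, EC) ≈ −0.87 matches the published −0.88.  The measurement
  pipeline is validated deterministically on karate (0.5245 to all printed
  digits), and a mixing sweep shows the published pair would be jointly
  realized near mixing 0.3, so the gap is attributed to residual
  generator-level differences; the nominal mixing stays at 0.5 and the
  assertion is left failing.
* Directed and weighted graphs are out of scope; the centrality is defined
  for simple undirected graphs only.
* P4 counting is exact, never sampled; graphs with millions of edges will
  want the incremental rescoring path (the default inside the loop) and
  patience.
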