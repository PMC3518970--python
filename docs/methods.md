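# Methods

This note records the models, conventions and numerical choices behind
`mesoconn`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, and
where a convention had to be chosen because the field does not fix one.

## Data model

A **connection record** is one literature-documented projection: source
and target region id, laterality (`ipsilateral`/`contralateral`), an
ordinal weight code 0..9 (0 = reported absent, 9 = strongest), tracer
substance, transport direction, case id and citation key.  The verbal
semiquantitative vocabulary of tract-tracing reports ("sparse",
"moderate", "dense", ...) is not standardized across studies, so the
label-to-code mapping is the caller's configuration, not an assertion of
this package.

A **connectome** is a simple directed graph over an ordered region
list.  Aggregation across studies keeps `weight = max(code)` and
`n_studies = number of supporting records`: the maximum preserves
"the connection exists at least this strongly" without inventing a
cross-study fusion rule the literature does not define.  Arcs whose
maximum code is 0 are *documented-absent* and excluded, as are
self-projections (the motif, distance and cycle machinery assumes
loop-free graphs).

**Views.**  The region ontology is a rooted "is part" tree.  A view is
a set of collapsed subtrees; the visible leaves, in depth-first document
order (never alphabetical — matrix order is anatomical, fixed by the
curated hierarchy), are the connectome's nodes.  Records attached below
a visible leaf aggregate up to it.  Bilateral graphs mirror the record
set onto `left:`/`right:` node copies; ipsilateral records appear on
both sides, contralateral records cross the midline in both directions.

**Condensation** iteratively removes regions lacking either any input
or any output, to a fixpoint (removal can strip neighbors of their last
input/output, hence the cascade).  All headline analyses run on the
condensed graph so that regions without documented connectivity cannot
distort the parameters.

## Global parameters

- average valency `2E/N`; line density `100·E/(N(N−1))`;
  heterogeneity = population SD of valency / mean valency;
  mean degree centrality `valency/(2(N−1))`.
- average path length: mean unweighted shortest directed path over
  *reachable* ordered pairs; the reachable fraction is reported
  alongside.  Connectomes are not guaranteed strongly connected and no
  infinity convention is universal, so exclusion plus an explicit
  fraction is the least-surprising choice.
- clustering: the classic coefficient on the underlying undirected
  simple graph (directed clustering variants exist but are not the
  cited convention); isolated behind one function for replaceability.
- small-worldness `S = (C/C̄_ER)/(L/L̄_ER)` against `n_rand`
  Erdős–Rényi replicates matched in N and E; seeded, deterministic.
- power-law delta error: least-squares fit of `log P(k)` vs `log k`
  over the observed valency histogram (zero-count bins and valency 0
  excluded); statistic = 100 × mean |empirical − fit|.  Undefined below
  3 distinct positive valencies.
- modularity: unweighted *directed* Newman modularity
  `Q = Σ_m [E_m/E − K_m^out·K_m^in/E²]`, maximized by seeded Louvain
  agglomeration with 8 deterministic restarts (best Q kept; the
  single-module partition, Q = 0, is the floor).  On 100 random 6-node
  digraphs the heuristic matched exhaustive set-partition search ≥ 95
  times in the test suite's fixed-seed run.

## Local parameters

Conventions that needed fixing (the table layout names columns but not
formulas):

- **Katz** status with attenuation `α = 0.9/λ_max` (spectral radius of
  the binary adjacency) and unit exogenous term, solved as
  `(I − αAᵀ)⁻¹1` — in-direction influence, unnormalized (hence large
  magnitudes).  α is configurable in spirit: the choice guarantees
  convergence; the literature prints no value.
- **eigenvector centrality** on the in-direction (`Aᵀ`), absolute
  leading eigenvector, normalized to max 1.
- **closeness** `Co`/`Ci`: harmonic (mean inverse distance, unreachable
  contributes 0), normalized by `n−1`, over out-/in-distances.
- **betweenness/stress**: directed, unweighted, unnormalized;
  geodesic-count combination `σ_st(v) = σ_sv·σ_vt` when
  `d(s,t) = d(s,v)+d(v,t)`.
- **clustering variants**: `CCo`/`CCi` are the directed arc densities
  among the out-/in-neighbor sets; `CCa` the undirected coefficient;
  `CC2` the mean `CCa` over the 2nd-neighbor ring.
- **module roles**: within-module degree z-scores (`Za/Zo/Zi`) and
  participation coefficients (`PCa/PCo/PCi`) in the Guimerà–Amaral
  form, applied to all/out/in degree against the modularity partition.
- **radiality** `Ro`/`Ri`: mean reversed distance
  `(diam + 1 − d)/(n−1)` over reachable targets/sources.
- **centroid values** `Ceno`/`Ceni`: min over opponents of the
  closeness-dominance count (nodes strictly closer to v than to the
  opponent, minus the converse), on out-/in-distances; unreachable
  counts as farther than any finite distance.  Radiality and centroid
  follow the standard centrality-suite definitions; the in/out
  orientation is a documented reading, not a verified convention.
- A column named `LC` appears in the conventional table layout but has
  no discoverable definition; it is intentionally not implemented.

**Shapley rates.**  Coalition value `v(S)` = number of strongly
connected components of the induced subgraph, `v(∅) = 0`.  The Shapley
value is the average marginal contribution over arrival orders; exact
mode (n ≤ 10) uses the subset-weighted sum over all `2^n` coalitions,
Monte-Carlo mode averages over seeded random orders with coalition-value
memoization (bitmask cache for n ≤ 24).  Values sum to the SCC count of
the full graph — exactly in both modes, since per-permutation marginals
telescope.  Negative rates arise when a node's arrival fuses several
components into one; those are the integrative regions.

**Cycle counts** enumerate distinct directed 2- and 3-edge cycles
through an anchor region (a 3-cycle's two orientations are distinct).

## Motif census

Motif classes are isomorphism classes of weakly connected loop-free
digraphs on k nodes, built by exhaustive scan of all `2^(k(k−1))` arc
configurations with canonicalization by minimum adjacency bitstring
over node permutations: 2 classes at k = 2, 13 at k = 3, 199 at k = 4.
Triad ids follow the field's convention and are pinned by a curated
representative table (3-01..03 = divergence/chain/convergence,
3-04/05 = one mutual dyad plus a single arc, 3-06 = feed-forward,
3-07 = directed cycle, 3-09 = two mutual dyads, 3-10 = cycle with one
mutual dyad, 3-13 = fully reciprocal); a within-arc-count ordering by
canonical code alone cannot reproduce those anchors, so the table takes
precedence and is regression-tested.  Tetrad ids are ordered by arc
count, then canonical code (4-199, the fully reciprocal tetrad, is
forced last).

Counting is *induced*: every weakly connected k-subset contributes to
exactly one class, so class totals partition the connected-subset count.
Significance compares the real census with `n_rand` degree-preserving
rewired replicates (double-arc swaps `a→b, c→d ⇒ a→d, c→b`, rejecting
self-loops and duplicates; `swap_multiplier × E` successful swaps per
replicate; graphs with no legal swap are returned unchanged).  For each
class: ensemble mean and population SD, `z = (f_real − mean)/SD` (0
when SD = 0), and `p` = fraction of replicates with a count ≥ the real
one — `p = 0` marks classes strictly more frequent in the real network
than in every replicate, `p = 1` classes at most as frequent.

## Matrices, vulnerability, PCA, pathways

**Communicability** is `exp(A)` of the *binarized* adjacency: the
value range reported for such analyses is consistent with unweighted
walks and no weight scaling is defined; weights are deliberately
ignored.  **Matching** is the Jaccard overlap of two regions' neighbor
sets (in/out/combined), excluding the pair itself (standard matching-
index convention), 0 on an empty union, diagonal 1.

**Vulnerability** uses harmonic closeness because deletions routinely
disconnect the graph: closeness of i = mean over j of `1/d(i,j)` with
unreachable contributing 0, normalized by `n−1`.  Node significance
compares mean closeness before vs after removal, with the post-deletion
mean over the surviving nodes only (the removed region has no
closeness); arc significance keeps the node set fixed.  Arc
significance is non-negative (distances only grow); node significance
may be negative when removing a weakly connected region raises the
survivors' mean.

**PCA** standardizes the six features (they mix raw degrees with [0,1]
coefficients; `standardize=False` disables), drops zero-variance
features with a warning, eigendecomposes the correlation structure,
orders components by variance share (shares sum to 100%), and signs
each component so its largest-magnitude loading is positive.  The
**Parzen** surface is a Gaussian kernel average with per-dimension
Silverman bandwidth `1.06·σ·m^(−1/5)` (unprinted in the source
analyses) on a grid padded 4 bandwidths beyond the data hull; the grid
integral is 1 within ~2% discretization error.  The exact definitions
of locality and 2nd-neighbor clustering live in cited external work;
the implementations here (fraction of neighborhood-incident arcs that
stay inside the closed 1-neighborhood; mean clustering over the
2nd-neighbor ring) are documented readings kept behind single
replaceable functions.

**Pathway search** consumes one graph arc per stage transition (no
multi-hop inside a stage — staged diagrams draw single arcs between
consecutive columns) and is exhaustive over transhierarchically resolved
stage sets; chains report per-hop weights, study counts and
reverse-arc flags.

**Extrinsic tallies**: for each intrinsic region, twelve counts split
by direction (input/output), laterality (contralateral/ipsilateral/sum)
and attachment (D = records attached exactly at the region, S =
anywhere in its subtree); an endpoint is extrinsic when it lies outside
the union of the intrinsic regions' subtrees.  By construction
`D*s = D*c + D*i` and `S ≥ D` componentwise.

## Synthetic generator

The generator states the world the analyses assume rather than tuning
toward any result: 49 leaves under an 8-level hierarchy (breadth-first
b-ary expansion to the exact leaf count, one branch deepened to the
exact depth), density 0.2, reciprocity excess 0.6, 3 contiguous leaf
modules with mixing 0.3 (a minority of arcs cross modules, giving the
moderate modularity regime), Pareto(2.5) attachment propensities for
heavy-tailed valencies, and a geometrically decaying weight-code
distribution on 1..9 (weak connections are reported far more often than
saturating ones).  Mixing and the propensity exponent are the one place
the regime is stated qualitatively rather than numerically; the values
above were chosen once as field-realistic and are not revisited.

Pair sampling: per unordered pair, per-direction probability `q` is
assembled from density, module membership and propensities, iteratively
renormalized (clipping into [0, 0.999] sheds mass that is redistributed)
so the expected arc count equals `density·n(n−1)` exactly; the pair
then draws both directions with probability `q·min(1, q + r)` and each
single direction with the remainder split evenly — the per-arc marginal
stays `q` while the conditional reciprocity is boosted by exactly the
excess `r`.  This is what forces the fully-reciprocal-triad enrichment
the census detects.

What the generator does **not** emulate: spatial embedding, laterality
asymmetries (all synthetic records are ipsilateral), tracer-dependent
reporting bias, and any real anatomical adjacency.  A green test on
synthetic data therefore establishes algorithmic correctness and the
qualitative regime (reciprocity excess, modularity, heavy tails), not
agreement with any real connectome's printed values — the real
underlying adjacency matrices of such meta-studies are generally not
published machine-readably.

## Null models

The ensemble offers five kinds: Erdős–Rényi (uniform, exact N and E),
rewiring (degree-preserving), and directed adaptations of
Watts–Strogatz (ring lattice with arcs both ways round, arc list
trimmed round-robin to exactly E, then per-arc random re-targeting),
Barabási–Albert (growth with (in+out)-degree-preferential far
endpoints, alternating arc direction, stop rule on the global arc
budget), and the ring-interpolation growth model (new nodes insert at a
random ring position and wire to nearest ring neighbors outward).  The
classic WS/BA models are undirected; these directed readings are this
package's documented adaptations.  A sixth generator sometimes named in
this literature is defined only in an external methods paper and is
deliberately not guessed at.

## Known limitations

- Exact Shapley is capped at 10 nodes; Monte-Carlo error scales as
  `O(n_perms^{-1/2})` (on the 8-node fixture, max error < 0.02 at 1e5
  permutations).
- The motif census is O(C(n,k)) per graph; k = 4 on ~50 nodes with
  1000 replicates is minutes-scale, not interactive.
- Orientation conventions for Co/Ci, Ro/Ri, Ceno/Ceni and the Katz α
  are documented readings where the table layout names columns without
  formulas.
- The bilateral builder mirrors one record set; genuinely asymmetric
  hemispheres require records resolved to side-specific region ids.
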