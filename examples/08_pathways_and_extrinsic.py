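"""Staged pathway search and extrinsic input/output tallies.

A stage spec is an ordered list of region sets, resolved
transhierarchically (a stage region matches its whole subtree).  The
search returns every chain with one node per stage joined by direct
arcs.  The extrinsic tally counts, per intrinsic region, projections
exchanged with regions outside the intrinsic set, split by direction,
laterality and attachment depth.
"""

from mesoconn import (
    SynthParams,
    build_connectome,
    condense,
    extrinsic_io_counts,
    generate_connectome,
    staged_paths,
)

h, records = generate_connectome(SynthParams(seed=1))
leaves = h.leaves()
c = condense(build_connectome(records, leaves, hierarchy=h))

# three-stage search across sibling subtrees of the hierarchy root
roots = h.children_of(h.root)
stages = [{roots[0]}, {roots[1] if len(roots) > 1 else roots[0]}, {leaves[-1]}]
chains = staged_paths(c, h, stages)
print(f"stage spec {[sorted(s) for s in stages]}: {len(chains)} pathways")
for ch in chains[:5]:
    hops = " -> ".join(ch.nodes)
    print(f"  {hops}   weights {ch.weights} reciprocal {ch.reciprocal}")

# treat the first 10 leaves as the intrinsic system; the rest is extrinsic
intrinsic = leaves[:10]
df = extrinsic_io_counts(records, intrinsic, h)
print("\nextrinsic tallies (direct/subtree x in/out x laterality):")
print(df.head(6))
# Dis = Dic + Dii always; S-counts aggregate over each region's subtree.
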