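"""Build a connectome from connection records and condense it.

Generates a synthetic tract-tracing dataset (49 leaf regions under an
8-level hierarchy, ~20% arc density), aggregates the records into a
weighted digraph, and condenses it to the regions with at least one
input and one output.
"""

from mesoconn import SynthParams, build_connectome, condense, generate_connectome

hierarchy, records = generate_connectome(SynthParams(seed=1))
leaves = hierarchy.leaves()
print(f"hierarchy: {len(hierarchy)} regions, depth {hierarchy.depth()}, "
      f"{len(leaves)} leaves")
print(f"records:   {len(records)} documented projections")

c = build_connectome(records, leaves, hierarchy=hierarchy)
cc = condense(c)
print(f"built:     {c.n_nodes} nodes, {c.n_arcs} arcs")
print(f"condensed: {cc.n_nodes} nodes, {cc.n_arcs} arcs")
# Every condensed region has >= 1 afferent and >= 1 efferent arc, so
# global/local parameters are not distorted by dead-end regions.
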