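"""Whole-network parameters and the small-world / scale-free diagnostics.

Prints average valency, line density, heterogeneity, path length,
clustering, small-worldness against a matched Erdős–Rényi ensemble,
the power-law delta error and directed Newman modularity.
"""

from mesoconn import (
    SynthParams,
    build_connectome,
    condense,
    generate_connectome,
    global_summary,
)

h, records = generate_connectome(SynthParams(seed=1))
c = condense(build_connectome(records, h.leaves(), hierarchy=h))
gm = global_summary(c, n_rand=100, seed=0)

print(f"N = {gm.n_nodes} regions, E = {gm.n_arcs} arcs")
print(f"average valency      {gm.avg_valency:.3f}   (mean arcs per node, 2E/N)")
print(f"line density         {gm.line_density:.3f} %  (of all ordered pairs)")
print(f"heterogeneity        {gm.heterogeneity:.3f}   (CV of valency)")
print(f"avg path length      {gm.avg_path_length:.3f}   edges, reachable pairs")
print(f"avg clustering       {gm.avg_cluster_coefficient:.3f}")
print(f"small-worldness      {gm.small_worldness:.3f}   (> 1: small-world regime)")
print(f"power-law delta err  {gm.powerlaw_delta_error:.3f}   (small: scale-free-like)")
print(f"modularity Q         {gm.modularity_Q:.3f}   (directed Newman)")
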