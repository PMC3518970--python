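"""Pairwise matrices: distance, communicability, connectivity matching.

The distance matrix shows how many edges separate each ordered region
pair; communicability weighs all walks (not just geodesics) by inverse
factorial length; the matching matrices quantify how similar two
regions' afferent/efferent sets are (1 = identical, 0 = disjoint).
"""

import numpy as np

from mesoconn import (
    SynthParams,
    build_connectome,
    communicability_matrix,
    condense,
    distance_matrix,
    generate_connectome,
    matching_matrix,
)

h, records = generate_connectome(SynthParams(seed=1))
c = condense(build_connectome(records, h.leaves(), hierarchy=h))

d = distance_matrix(c).values
off = ~np.eye(c.n_nodes, dtype=bool)
finite = np.isfinite(d) & off
print(f"distances: max {int(d[finite].max())} edges, "
      f"{100 * finite.sum() / off.sum():.1f}% of pairs reachable")

g = communicability_matrix(c).values
print(f"communicability: min {g[off].min():.4f}, max {g[off].max():.4g}")

for mode in ("in", "out", "all"):
    m = matching_matrix(c, mode).values
    print(f"matching ({mode:>3}): mean {m[off].mean():.3f}, max {m[off].max():.3f}")
# High matching pairs receive (or send) nearly the same connections and
# are candidates for functional sibling regions.
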