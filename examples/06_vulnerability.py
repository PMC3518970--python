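"""Node and arc vulnerability: who keeps the network short?

Deletes each region (and each arc) in turn and reports the percent drop
of the network's mean harmonic closeness.  Positive significance =
deletion lengthens or severs paths; the top regions are the ones whose
loss most degrades global integration.
"""

import numpy as np

from mesoconn import (
    SynthParams,
    build_connectome,
    condense,
    edge_vulnerability_matrix,
    generate_connectome,
    node_significance,
)
from mesoconn.vulnerability import mean_closeness

h, records = generate_connectome(SynthParams(seed=1))
c = condense(build_connectome(records, h.leaves(), hierarchy=h))

print(f"baseline mean closeness: {mean_closeness(c):.4f}")
sig = node_significance(c)
for r in sorted(sig, key=sig.get, reverse=True)[:5]:
    print(f"  remove {r}: {sig[r]:+.3f} % closeness lost")

m = edge_vulnerability_matrix(c)
worst = np.unravel_index(np.nanargmax(m.values), m.values.shape)
print(f"most critical arc: {m.nodes[worst[0]]} -> {m.nodes[worst[1]]} "
      f"({np.nanmax(m.values):.3f} % closeness lost)")
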