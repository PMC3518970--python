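"""Directed triad census against degree-preserving rewiring nulls.

Counts induced 3-node motifs and scores each class against 200 rewired
replicates.  In a reciprocity-enriched connectome the fully reciprocal
triad (3-13) is far more frequent than any null predicts (p = 0),
while chains and cycles are depleted.
"""

from mesoconn import (
    SynthParams,
    build_connectome,
    condense,
    generate_connectome,
    motif_participation,
    motif_significance,
)

h, records = generate_connectome(SynthParams(seed=1))
c = condense(build_connectome(records, h.leaves(), hierarchy=h))

stats = motif_significance(c, k=3, n_rand=200, swap_multiplier=10, seed=7)
print(f"{'motif':>6} {'f_real':>7} {'null mean':>10} {'null sd':>8} "
      f"{'z':>8} {'p':>5}")
for s in stats:
    print(f"{s.motif_id:>6} {s.f_real:>7} {s.rand_mean:>10.1f} "
          f"{s.rand_sd:>8.2f} {s.z:>8.2f} {s.p:>5.2f}")

part = motif_participation(c, "3-13")
top = sorted(part, key=part.get, reverse=True)[:4]
print("\nregions most often inside the fully reciprocal triad 3-13:")
for r in top:
    print(f"  {r}: {part[r]} occurrences")
# p = 0 rows are classes every rewired replicate under-produces; the
# 3-13 excess is the census signature of reciprocity-dominated wiring.
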