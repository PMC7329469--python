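"""Cluster recurring SV calls with jittered breakpoints.

The same 40 kb deletion reported by three cases with slightly different
breakpoints lands in one cluster; its centroid is the mean of the member
endpoints while the padding interval stays fixed at the founder's size
(2 kb for variants over 10 kb, 10% of length below that).
"""

from varobs import SvClusterStore, SvCoordinates, padding_interval

store = SvClusterStore()
calls = [
    ("case_A", 10_000, 50_000),
    ("case_B", 10_350, 49_800),   # caller imprecision
    ("case_C", 9_800, 50_150),
]
for case_id, start, end in calls:
    sv = SvCoordinates("DEL", "1", start, "1", end, float(end - start + 1))
    action, cluster_id = store.insert_sv(sv, case_id)
    print(f"{case_id}: {action} {cluster_id} (padding "
          f"{padding_interval(sv)} bp)")

(cluster,) = store.clusters.values()
print(f"cluster centroid: ({cluster.mean_a:.1f}, {cluster.mean_b:.1f}), "
      f"interval {cluster.interval_bp} bp, observations {cluster.obs_count}")

# a read-only query from a fourth sample, again with jitter
query = SvCoordinates("DEL", "1", 10_200, "1", 49_900, 39_701.0)
hit = store.query_sv(query, n_cases=3)
print(f"query hit: Obs={hit['obs_count']} Frq={hit['frequency']:.2f}")
# All three calls joined one cluster; the query matches it without mutating.
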