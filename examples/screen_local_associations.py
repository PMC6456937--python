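"""Screen a small simulated community for locally co-occurring pairs.

Builds a 12-factor x 120-month community with one planted correlated pair,
rank-normalizes it, and runs the all-pairs local-similarity screen with the
reference filters (theoretical p <= 0.001, q <= 0.05, association segment
spanning more than half the series).
"""

from ela import (PlantedPair, SimulationManifest, default_factors,
                 normalize_table, screen_pairs, simulate_community)

manifest = SimulationManifest(
    seed=7, n_time=120, factors=default_factors(12, 2),
    planted_pairs=[PlantedPair(x="OTU_001", y="OTU_002", strength=0.8)],
)
table, pair_truth, _ = simulate_community(manifest)
normalized = normalize_table(table)
pairs = screen_pairs(normalized)

print(f"{len(pairs)} significant pair(s) of {12 * 11 // 2} tested")
for p in pairs:
    print(f"  {p.x_id} -- {p.y_id}: LS={p.ls:+.3f} over months "
          f"[{p.interval_start}, {p.interval_end}] (p={p.p:.2e}, q={p.q:.2e})")
# The planted pair (true correlation 0.8) is the survivor; its LS score is a
# correlation-scale statistic and the interval shows where the association
# holds.  Independent factors fall far below the 0.001 p-value filter.
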