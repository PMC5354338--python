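"""Build one HA/MA twin pair and inspect its structural properties.

The human architecture (HA) carries the full projection set; the monkey
architecture (MA) is an exact copy with the four reciprocal "jumping"
projections removed.  Everything else -- every surviving link, every weight,
every word pattern -- is shared, so the pair is a within-subject contrast of
long-distance connectivity alone.
"""

import numpy as np

from perisylvian import AreaGraph, instantiate_pair

ha, ma = instantiate_pair(seed=1)

print("areas:", ha.graph.areas)
print(f"HA links: {ha.synapses.n_links:,}   MA links: {ma.synapses.n_links:,}")
print("A1 -> M1 path length:  MA =", AreaGraph.monkey().path_length("A1", "M1"),
      "  HA =", AreaGraph.human().path_length("A1", "M1"))
print("projection pairs touching PB:  MA =", AreaGraph.monkey().degree("PB"),
      "  HA =", AreaGraph.human().degree("PB"))

between = {k: v for k, v in ha.synapses.links_by_projection().items()
           if k[0] != k[1]}
print("\nrealised between-area link counts (HA):")
for (src, dst), n in sorted(between.items()):
    tag = "jumping" if (src, dst) in ha.graph.jumping_links() else "next"
    print(f"  {src:>2} -> {dst:<2}  {n:6,}  ({tag})")

pat = ha.patterns[0]
print(f"\nword pattern 0: {len(pat.a1_cells)} A1 cells + "
      f"{len(pat.m1_cells)} M1 cells "
      f"({len(pat.a1_cells) / 625:.2%} of each 25x25 area)")
print("shared with MA member:", ha.patterns == ma.patterns)

# The link counts show the HA's ~9/5 between-area surplus: the jumping
# projections have the same per-projection statistics as the next-neighbour
# ones, so removing them leaves the MA with 5 of the 9 reciprocal pairs.
print("\nHA/MA between-area link ratio:",
      round(sum(between.values())
            / sum(v for k, v in ma.synapses.links_by_projection().items()
                  if k[0] != k[1]), 3))
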