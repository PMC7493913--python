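"""Rank competing heavy metals by electronegativity.

In mixed-metal biosorption the more electronegative cation tends to bind
the algal surface groups more strongly, so a descending sort predicts
the qualitative removal-efficiency order across the mixture.
"""

from sorbopt import rank_by_electronegativity
from sorbopt.datasets import HEAVY_METALS

print("predicted removal ranking (most to least):")
for rank, metal in enumerate(rank_by_electronegativity(HEAVY_METALS), start=1):
    print(f"  {rank}. {metal.name:2s} (electronegativity {metal.electronegativity})")
print("\nnear-equal electronegativities (Cu, Co) give experimentally "
      "comparable efficiencies, so their order may swap in practice.")
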