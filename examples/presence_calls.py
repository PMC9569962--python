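"""Horizontal-coverage presence/absence calls on hand-built depth tracks.

A gene is present when strictly more than 5% of its CDS bases reach 2X
(the default rule) — so 6/100 bases is present, 5/100 is absent, and a
deleted gene with zero covered bases is unambiguously absent.
"""

import numpy as np

from armpav.models import DepthTrack, GeneModel
from armpav.pav import DEFAULT_THRESHOLDS, call_presence, gene_coverage

gene = GeneModel("demo", "chr", 0, 100, cds_intervals=((0, 100),))

for label, covered in [("deleted", 0), ("boundary 5%", 5),
                       ("boundary 6%", 6), ("retained", 100)]:
    vec = np.zeros(100, dtype=int)
    vec[:covered] = 38  # typical present-gene depth
    track = DepthTrack({"chr": vec})
    stat = call_presence(gene_coverage(gene, track, 2), DEFAULT_THRESHOLDS)
    print(f"{label:12s} horizontal={stat.horizontal_coverage:5.2f} "
          f"median={stat.median_depth:4.1f}X -> {stat.call}")

print("\nhorizontal = fraction of the 100 CDS bases with depth >= 2X; "
      "the call flips between 5% and 6% because the rule is strictly "
      "'more than 5%'.")
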