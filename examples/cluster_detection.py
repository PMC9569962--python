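"""Grouping absent genes into positional clusters.

A deleted segment shows up as consecutive absent calls along the gene
order; a translocated or diverged region may keep a few conserved genes,
so the scan tolerates up to max_gap interspersed present genes.
"""

import numpy as np

from armpav.clusters import find_absent_clusters
from armpav.models import DepthTrack, GeneModel
from armpav.pav import DEFAULT_THRESHOLDS, call_genes

# 30 genes; genes 5-11 deleted outright, genes 18-27 mostly deleted with
# two conserved genes interspersed
pattern = "PPPPPAAAAAAAPPPPPPAAAAPAAPAAAP"
vec = np.zeros(len(pattern) * 10, dtype=int)
genes = []
for i, ch in enumerate(pattern):
    if ch == "P":
        vec[i * 10:(i + 1) * 10] = 30
    genes.append(GeneModel(f"g{i:02d}", "chr", i * 10, (i + 1) * 10,
                           cds_intervals=(((i * 10), (i + 1) * 10),)))

calls = call_genes(genes, DepthTrack({"chr": vec}), DEFAULT_THRESHOLDS)
print("calls:", "".join("A" if c.call == "absent" else "P" for c in calls))

for max_gap in (0, 2):
    clusters = find_absent_clusters(calls, max_gap=max_gap, min_cluster_size=3)
    print(f"\nmax_gap={max_gap}:")
    for c in clusters:
        print(f"  {c.n_absent} absent genes "
              f"({c.n_interspersed_present} present interspersed), "
              f"span chr:{c.span_start}-{c.span_end}")

print("\nWith max_gap=0 only strict runs count; max_gap=2 merges the second "
      "region across its two conserved genes into one 9-absent-gene cluster.")
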