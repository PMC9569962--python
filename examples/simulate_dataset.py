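"""Generate a small ground-truthed flow-sorted-arm dataset.

Writes a reference FASTA (pseudomolecule + background + unplaced contigs),
a GFF3 annotation, a marker table, perfect SAM alignments and the truth
JSON into ./example_output/sim.
"""

import json

from armpav.simdata import SimConfig, write_dataset

config = SimConfig(
    seed=11,
    arm_len=300_000, offarm_len=300_000, other_seq_lens=(150_000,),
    unplaced_lens=(10_000, 10_000), n_unplaced_arm=1,
    n_genes_arm=60, deleted_blocks=((20, 7),), interspersed_template=None,
)
paths = write_dataset(config, "example_output/sim")
truth = json.loads(paths["truth"].read_text())

for name, path in paths.items():
    print(f"{name:12s} {path}")
print(f"\nsimulated reads: {truth['n_reads_total']} "
      f"({truth['n_reads_arm']} arm-origin, purity target {config.purity})")
print(f"deleted genes:   {len(truth['deleted_gene_ids'])} "
      f"(a block of 7 consecutive arm genes — these must be called absent)")
print(f"planted markers: {len(truth['marker_truth'])} "
      f"(4x 7RS in the arm by default template; here "
      f"{config.n_arm_markers}x 7RS + {config.n_off_markers}x 7RL)")
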