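"""Positional clusters of absent genes along the gene order of the arm.

Genes lost as a block (deletion, translocation or systematic mis-annotation)
show up as runs of absent calls in annotation order, possibly with a few
present genes interspersed.  A greedy left-to-right scan groups absent genes
whenever no more than ``max_gap`` consecutive present genes separate them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pav import ABSENT, GeneCoverageStat

DEFAULT_MAX_GAP = 5
DEFAULT_MIN_CLUSTER_SIZE = 5


@dataclass(frozen=True)
class AbsentCluster:
    """A run of positionally consecutive absent genes.

    ``span_start``/``span_end`` run from the start of the first member gene
    to the end of the last; interspersed present genes within the span are
    counted but not listed.
    """

    seq_id: str
    gene_ids: tuple[str, ...]
    n_interspersed_present: int
    span_start: int
    span_end: int

    @property
    def n_absent(self) -> int:
        return len(self.gene_ids)


def find_absent_clusters(
    calls: list[GeneCoverageStat],
    max_gap: int = DEFAULT_MAX_GAP,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> list[AbsentCluster]:
    """Group absent genes into clusters tolerating small present gaps.

    ``calls`` must be from a single sequence and sorted by gene start.  A
    cluster grows while at most ``max_gap`` consecutive present genes sit
    between absent members; trailing present genes are trimmed (clusters
    start and end on absent genes).  Clusters with fewer than
    ``min_cluster_size`` absent members are discarded.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    seq_ids = {c.gene.seq_id for c in calls}
    if len(seq_ids) > 1:
        raise ValueError(f"calls span multiple sequences: {sorted(seq_ids)}")
    starts = [c.gene.start for c in calls]
    if starts != sorted(starts):
        raise ValueError("calls must be sorted by gene start")

    clusters: list[AbsentCluster] = []
    members: list[GeneCoverageStat] = []  # absent genes of the open cluster
    interspersed = 0
    gap_run = 0

    def close() -> None:
        nonlocal members, interspersed
        if len(members) >= min_cluster_size:
            clusters.append(
                AbsentCluster(
                    seq_id=members[0].gene.seq_id,
                    gene_ids=tuple(m.gene.gene_id for m in members),
                    n_interspersed_present=interspersed,
                    span_start=members[0].gene.start,
                    span_end=members[-1].gene.end,
                )
            )
        members = []
        interspersed = 0

    for stat in calls:
        if stat.call == ABSENT:
            if members and gap_run > 0:
                interspersed += gap_run
            members.append(stat)
            gap_run = 0
        else:
            gap_run += 1
            if members and gap_run > max_gap:
                close()
                gap_run = 0
    close()
    return clusters


def clusters_to_bed_rows(clusters: list[AbsentCluster]) -> list[tuple]:
    return [
        (c.seq_id, c.span_start, c.span_end, f"absent_cluster_{i + 1}")
        for i, c in enumerate(clusters)
    ]


def write_clusters_tsv(clusters: list[AbsentCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster\tseq_id\tspan_start\tspan_end\tn_absent\t"
            "n_interspersed_present\tgene_ids\n"
        )
        for i, c in enumerate(clusters, 1):
            fh.write(
                f"{i}\t{c.seq_id}\t{c.span_start}\t{c.span_end}\t{c.n_absent}\t"
                f"{c.n_interspersed_present}\t{','.join(c.gene_ids)}\n"
            )
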