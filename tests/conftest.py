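"""Shared fixtures: a session-scoped default synthetic dataset and helpers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pysam
import pytest

from armpav.models import DepthTrack, GeneModel
from armpav.pipeline import RunConfig, run
from armpav.simdata import SimConfig, write_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory) -> dict:
    """The default study template, simulated once (seed 42)."""
    outdir = tmp_path_factory.mktemp("sim_default")
    paths = write_dataset(SimConfig(seed=42), outdir)
    truth = json.loads(Path(paths["truth"]).read_text())
    return {"config": SimConfig(seed=42), "paths": paths, "truth": truth}


@pytest.fixture(scope="session")
def default_report(default_dataset, tmp_path_factory):
    """Full pipeline run on the default template."""
    paths = default_dataset["paths"]
    outdir = tmp_path_factory.mktemp("run_default")
    config = RunConfig(
        reference=paths["reference"],
        annotation=paths["annotation"],
        alignments=paths["alignments"],
        markers=paths["markers"],
        outdir=outdir,
    )
    return run(config)


def make_track(**vectors) -> DepthTrack:
    return DepthTrack({k: np.asarray(v) for k, v in vectors.items()})


def make_gene(gene_id="g1", seq_id="chr", start=0, end=100,
              cds=None, **kw) -> GeneModel:
    if cds is None:
        cds = ((start, end),)
    return GeneModel(gene_id=gene_id, seq_id=seq_id, start=start, end=end,
                     cds_intervals=tuple(cds), **kw)


def write_sam(path: Path, lengths: dict[str, int], records: list[dict]) -> Path:
    """Write a SAM file from simple record dicts via pysam."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": s, "LN": n} for s, n in lengths.items()],
    }
    names = list(lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment()
            a.query_name = rec.get("name", "read")
            a.reference_id = names.index(rec["seq_id"])
            a.reference_start = rec["pos"]
            a.mapping_quality = rec.get("mapq", 60)
            a.cigarstring = rec["cigar"]
            a.flag = rec.get("flag", 0)
            qlen = sum(n for op, n in a.cigartuples or ()
                       if op in (0, 1, 4, 7, 8))
            a.query_sequence = rec.get("seq", "A" * qlen)
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            out.write(a)
    return path
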