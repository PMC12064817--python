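"""Shared fixtures: a session-scoped synthetic cohort and a tiny BAM writer."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from lncscout import synthetic_data


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """The stock micro-cohort: 5 samples, 50 kb genome, 2 plants, 2 decoys."""
    outdir = tmp_path_factory.mktemp("cohort")
    return synthetic_data.fixture_small(outdir)


def make_bam(path: Path, reads, lengths=None):
    """Write a sorted, indexed BAM from (pos, cigar, seq) or (chrom, pos, cigar, seq)."""
    lengths = lengths or {"chr1": 100_000}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for i, read in enumerate(sorted(reads, key=lambda r: r[-3])):
            if len(read) == 3:
                chrom, (pos, cigar, seq) = "chr1", read
            else:
                chrom, pos, cigar, seq = read
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.flag = 0
            a.reference_id = out.get_tid(chrom)
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = seq
            out.write(a)
    pysam.index(str(path))
    return path
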