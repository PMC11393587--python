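"""Shared fixtures: synthetic references, truth-aligned read sets and
in-memory SAM records, all generated at test time from fixed seeds."""

from __future__ import annotations

import pysam
import pytest

from lrqc import synthetic as syn

_HEADER = pysam.AlignmentHeader.from_dict(
    {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chr1", "LN": 1_000_000}],
    }
)

_OPS = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "=": 7, "X": 8}


def make_record(
    cigar: str,
    md: str | None = None,
    start: int = 0,
    seq: str | None = None,
    name: str = "r1",
    flag: int = 0,
) -> pysam.AlignedSegment:
    """Build an in-memory alignment from a CIGAR string like '4M1I3M'."""
    import re

    tuples = [
        (_OPS[op], int(n)) for n, op in re.findall(r"(\d+)([MIDNSH=X])", cigar)
    ]
    qlen = sum(n for op, n in tuples if op in (0, 1, 4, 7, 8))
    rec = pysam.AlignedSegment(_HEADER)
    rec.query_name = name
    rec.query_sequence = seq if seq is not None else "A" * qlen
    rec.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    rec.flag = flag
    rec.reference_id = 0
    rec.reference_start = start
    rec.mapping_quality = 60
    rec.cigartuples = tuples
    if md is not None:
        rec.set_tag("MD", md)
    return rec


@pytest.fixture(scope="session")
def truth_bundle(tmp_path_factory):
    """1000 simulated 1 kb reads (sub/ins/del = 0.05/0.02/0.02) over a
    50 kb reference, with FASTQ, truth BAM and truth counts."""
    root = tmp_path_factory.mktemp("truth_bundle")
    seq, _ = syn.generate_reference(50_000, gc_target=0.45, seed=101)
    ref_path = syn.write_fasta(root / "ref.fa", {"chr1": seq})
    fastq = root / "reads.fastq.gz"
    bam = root / "reads.bam"
    truth = syn.simulate_reads(
        seq,
        n_reads=1000,
        read_length=1000,
        sub_rate=0.05,
        ins_rate=0.02,
        del_rate=0.02,
        q_mean=15.0,
        q_sd=3.0,
        seed=202,
        fastq_path=fastq,
        bam_path=bam,
    )
    return {
        "reference_seq": seq,
        "reference": str(ref_path),
        "fastq": str(fastq),
        "bam": str(bam),
        "truth": truth,
        "rates": {"sub": 0.05, "ins": 0.02, "del": 0.02},
    }


@pytest.fixture(scope="session")
def uniform_coverage_genome(tmp_path_factory):
    """2 Mb reference with unimodal per-bin GC (mean 0.42) under exactly
    uniform 10x coverage, for GC-bias analyses."""
    root = tmp_path_factory.mktemp("gc_genome")
    seq, _ = syn.generate_reference(
        2_000_000, gc_target=0.42, gc_sd=0.05, seed=303
    )
    ref_path = syn.write_fasta(root / "ref.fa", {"chr1": seq})
    bam = root / "uniform.bam"
    syn.simulate_coverage(ref_path, bam, base_depth=10.0, seed=304)
    return {"reference": str(ref_path), "bam": str(bam)}
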