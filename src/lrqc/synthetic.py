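"""Synthetic fixture generator: references, reads with known injected
errors and truth alignments, coverage tracks, and bedMethyl files.

Everything every other module consumes can be generated here with known
ground truth, so the whole tool is testable without downloading data:

* references with controlled GC composition (optionally varying per
  window) and homopolymer runs planted at recorded positions;
* reads with substitutions/insertions/deletions injected at configured
  per-base rates, written as FASTQ plus a truth SAM/BAM whose CIGAR and
  MD encode exactly the injected edits (written directly, not via an
  aligner, so metric code is tested in isolation from aligner behavior);
* coverage simulations that are either deterministically uniform
  (fixed-length reads tiling each bin — the generator's definition of
  bias-free sequencing) or Poisson-like with random starts, optionally
  modulated by a configurable function of bin GC;
* modkit-dialect bedMethyl files with per-region target proportions.

All generators are fully deterministic for a given seed.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import norm

from .io_formats import Region

BASES = np.array(list("ACGT"))

TRUTH_COLUMNS = [
    "read_id", "chrom", "ref_start", "ref_end",
    "n_mat", "n_sub", "n_ins", "n_del",
]


@dataclass(frozen=True)
class HomopolymerSpec:
    """A run to plant in a generated reference: ``length`` copies of
    ``base`` starting at ``position``."""

    position: int
    base: str
    length: int


# ---------------------------------------------------------------------------
# Reference


def generate_reference(
    length: int,
    gc_target: float = 0.42,
    seed: int = 0,
    gc_sd: float = 0.0,
    gc_block: int = 1000,
    homopolymers: Sequence[HomopolymerSpec] = (),
    chrom: str = "chr1",
) -> tuple[str, list[HomopolymerSpec]]:
    """Random reference sequence with controlled GC composition.

    Bases are drawn i.i.d. with P(G)+P(C) = ``gc_target``; when
    ``gc_sd`` > 0 the GC probability is redrawn per ``gc_block`` window
    from a clipped normal, giving per-window GC variation (useful for
    GC-bias studies). Requested homopolymer runs are written over the
    sequence afterwards, with both flanking bases forced to differ from
    the run base so each planted run is maximal exactly as specified.

    Returns the sequence and the (validated) planted runs.
    """
    if not 0.0 < gc_target < 1.0:
        raise ValueError(f"gc_target must be in (0, 1), got {gc_target}")
    rng = np.random.default_rng(seed)
    if gc_sd > 0:
        n_blocks = (length + gc_block - 1) // gc_block
        block_gc = np.clip(
            rng.normal(gc_target, gc_sd, size=n_blocks), 0.05, 0.95
        )
        gc_per_base = np.repeat(block_gc, gc_block)[:length]
    else:
        gc_per_base = np.full(length, gc_target)
    u = rng.random(length)
    is_gc = u < gc_per_base
    pick = rng.integers(0, 2, size=length)
    codes = np.where(is_gc, np.where(pick == 0, 1, 2),  # C / G
                     np.where(pick == 0, 0, 3))         # A / T
    seq = np.array(list("ACGT"))[codes]

    placed: list[HomopolymerSpec] = []
    for spec in homopolymers:
        if spec.base not in "ACGT":
            raise ValueError(f"homopolymer base {spec.base!r} not in ACGT")
        if spec.position < 1 or spec.position + spec.length > length - 1:
            raise ValueError(
                f"homopolymer at {spec.position} (+{spec.length}) does not "
                f"fit inside sequence of length {length} with flanks"
            )
        seq[spec.position:spec.position + spec.length] = spec.base
        alternatives = [b for b in "ACGT" if b != spec.base]
        for flank in (spec.position - 1, spec.position + spec.length):
            if seq[flank] == spec.base:
                seq[flank] = alternatives[int(rng.integers(len(alternatives)))]
        placed.append(spec)
    return "".join(seq), placed


def write_fasta(path: str | Path, sequences: dict[str, str]) -> str:
    """Write sequences to FASTA (60-column wrap) and faidx-index it."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    pysam.faidx(path)
    return path


# ---------------------------------------------------------------------------
# Reads with truth alignments


def _phred_model(rng, n: int, q_mean: float, q_sd: float) -> np.ndarray:
    q = np.rint(rng.normal(q_mean, q_sd, size=n)).astype(int)
    return np.clip(q, 1, 60)


def analytic_mean_accuracy(q_mean: float, q_sd: float) -> float:
    """Expected estimated accuracy E[1 - 10^(-q/10)] under the
    generator's quality model (normal, rounded, clipped to [1, 60])."""
    qs = np.arange(1, 61)
    upper = np.where(qs == 60, np.inf, qs + 0.5)
    lower = np.where(qs == 1, -np.inf, qs - 0.5)
    pmf = norm.cdf(upper, q_mean, q_sd) - norm.cdf(lower, q_mean, q_sd)
    return float(1.0 - np.sum(pmf * 10.0 ** (-qs / 10.0)))


def _simulate_one_read(
    rng: np.random.Generator,
    refseq: str,
    start: int,
    ref_len: int,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
) -> tuple[int, list[tuple[str, int]], str, str, dict[str, int]] | None:
    """One read over reference interval [start, start+ref_len).

    Returns (adjusted_start, cigar ops, query sequence, MD string,
    counts) or None if the read degenerates (all bases deleted).
    """
    u = rng.random(ref_len)
    # per reference position: 0 = match, 1 = substitution, 2 = deletion
    state = np.where(u < del_rate, 2, np.where(u < del_rate + sub_rate, 1, 0))
    keep = np.flatnonzero(state != 2)
    if keep.size == 0:
        return None
    # alignments must not begin or end with a deletion
    first, last = keep[0], keep[-1]
    state = state[first:last + 1]
    start += int(first)
    ref_len = len(state)

    ins_after = rng.random(ref_len) < ins_rate

    ops: list[tuple[str, int]] = []
    query: list[str] = []
    md_parts: list[str] = []
    match_run = 0
    n_mat = n_sub = n_ins = n_del = 0

    def push(op: str, n: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    i = 0
    while i < ref_len:
        rbase = refseq[start + i]
        if state[i] == 2:
            run = [rbase]
            push("D")
            n_del += 1
            while i + 1 < ref_len and state[i + 1] == 2:
                i += 1
                run.append(refseq[start + i])
                push("D")
                n_del += 1
            md_parts.append(f"{match_run}^{''.join(run)}")
            match_run = 0
        elif state[i] == 1:
            alt = [b for b in "ACGT" if b != rbase]
            query.append(alt[int(rng.integers(3))])
            push("M")
            n_sub += 1
            md_parts.append(f"{match_run}{rbase}")
            match_run = 0
        else:
            query.append(rbase)
            push("M")
            n_mat += 1
            match_run += 1
        if ins_after[i] and i < ref_len - 1:  # never a trailing insertion
            query.append(str(BASES[int(rng.integers(4))]))
            push("I")
            n_ins += 1
        i += 1
    md_parts.append(str(match_run))
    md = "".join(md_parts)
    counts = {"n_mat": n_mat, "n_sub": n_sub, "n_ins": n_ins, "n_del": n_del}
    return start, ops, "".join(query), md, counts


def simulate_reads(
    reference: str,
    n_reads: int,
    read_length: int = 1000,
    sub_rate: float = 0.05,
    ins_rate: float = 0.02,
    del_rate: float = 0.02,
    q_mean: float = 15.0,
    q_sd: float = 3.0,
    seed: int = 0,
    chrom: str = "chr1",
    fastq_path: str | Path | None = None,
    bam_path: str | Path | None = None,
    read_prefix: str = "read",
) -> pd.DataFrame:
    """Simulate reads with injected errors and emit FASTQ + truth BAM.

    Each read covers a random ``read_length`` reference window; per
    reference base a deletion (``del_rate``) or substitution
    (``sub_rate``) is injected, and a single-base insertion follows with
    probability ``ins_rate``. The emitted CIGAR and MD encode exactly
    the injected edits; the returned truth table holds the per-read
    counts. Reads are emitted coordinate-sorted, all on the forward
    strand. Rates must be in [0, 0.2] and sum below 1.
    """
    for name, rate in (("sub", sub_rate), ("ins", ins_rate), ("del", del_rate)):
        if not 0.0 <= rate <= 0.2:
            raise ValueError(f"{name}_rate must be in [0, 0.2], got {rate}")
    if sub_rate + ins_rate + del_rate >= 1.0:
        raise ValueError("error rates must sum below 1")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if read_length > len(reference):
        raise ValueError("read_length exceeds reference length")

    rng = np.random.default_rng(seed)
    starts = np.sort(
        rng.integers(0, len(reference) - read_length + 1, size=n_reads)
    )

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": chrom, "LN": len(reference)}],
        }
    )
    op_code = {"M": 0, "I": 1, "D": 2}

    rows = []
    fq = None
    if fastq_path is not None:
        fastq_path = os.fspath(fastq_path)
        opener = gzip.open if fastq_path.endswith(".gz") else open
        fq = opener(fastq_path, "wt")
    bam = None
    if bam_path is not None:
        bam = pysam.AlignmentFile(os.fspath(bam_path), "wb", header=header)
    try:
        for i, s0 in enumerate(starts):
            sim = _simulate_one_read(
                rng, reference, int(s0), read_length,
                sub_rate, ins_rate, del_rate,
            )
            if sim is None:
                continue
            start, ops, query, md, counts = sim
            quals = _phred_model(rng, len(query), q_mean, q_sd)
            read_id = f"{read_prefix}_{i:05d}"
            ref_end = start + sum(n for op, n in ops if op in "MD")
            rows.append(
                {
                    "read_id": read_id, "chrom": chrom,
                    "ref_start": start, "ref_end": ref_end, **counts,
                }
            )
            if fq is not None:
                qstr = "".join(chr(q + 33) for q in quals)
                fq.write(f"@{read_id}\n{query}\n+\n{qstr}\n")
            if bam is not None:
                rec = pysam.AlignedSegment(header)
                rec.query_name = read_id
                rec.query_sequence = query
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals)
                )
                rec.flag = 0
                rec.reference_id = 0
                rec.reference_start = start
                rec.mapping_quality = 60
                rec.cigartuples = [(op_code[op], n) for op, n in ops]
                rec.set_tag("MD", md)
                rec.set_tag(
                    "NM",
                    counts["n_sub"] + counts["n_ins"] + counts["n_del"],
                )
                bam.write(rec)
    finally:
        if fq is not None:
            fq.close()
        if bam is not None:
            bam.close()
    if bam_path is not None:
        pysam.index(os.fspath(bam_path))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# Coverage simulation (for GC-bias studies)


def simulate_coverage(
    reference_path: str | Path,
    bam_path: str | Path,
    base_depth: float = 10.0,
    bin_size: int = 1000,
    bias: Callable[[float], float] | None = None,
    mode: str = "uniform",
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a sorted, indexed BAM with controlled per-bin coverage.

    In ``uniform`` mode each complete ``bin_size`` bin receives exactly
    ``round(base_depth * bias(gc))`` error-free reads spanning the whole
    bin, so per-bin depth is exact and bias-free data is perfectly flat.
    In ``poisson`` mode read starts are drawn uniformly at random
    (``bias`` must be None), giving shot-noise coverage. Returns the
    per-bin truth table (gc_fraction, target_depth).
    """
    if mode not in ("uniform", "poisson"):
        raise ValueError(f"mode must be uniform or poisson, got {mode}")
    if mode == "poisson" and bias is not None:
        raise ValueError("bias modulation requires uniform mode")
    rng = np.random.default_rng(seed)
    fasta = pysam.FastaFile(os.fspath(reference_path))
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": fasta.get_reference_length(c)}
                for c in fasta.references
            ],
        }
    )
    bam_path = os.fspath(bam_path)
    rows = []
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for tid, chrom in enumerate(fasta.references):
            clen = fasta.get_reference_length(chrom)
            if mode == "poisson":
                n_reads = int(round(base_depth * clen / bin_size))
                starts = np.sort(
                    rng.integers(0, max(clen - bin_size, 0) + 1, size=n_reads)
                )
                for j, start in enumerate(starts):
                    seq = fasta.fetch(chrom, int(start), int(start) + bin_size)
                    _write_simple_read(
                        bam, header, f"cov_{chrom}_{j:06d}", tid, int(start), seq
                    )
                continue
            n_bins = clen // bin_size
            for b in range(n_bins):
                start = b * bin_size
                seq = fasta.fetch(chrom, start, start + bin_size).upper()
                acgt = sum(seq.count(x) for x in "ACGT")
                gc = (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0
                mult = bias(gc) if bias is not None else 1.0
                n = int(round(base_depth * mult))
                for j in range(n):
                    _write_simple_read(
                        bam, header, f"cov_{chrom}_{b:05d}_{j:03d}",
                        tid, start, seq,
                    )
                rows.append(
                    {
                        "chrom": chrom, "start": start,
                        "end": start + bin_size, "gc_fraction": gc,
                        "target_depth": float(n),
                    }
                )
    pysam.index(bam_path)
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gc_fraction", "target_depth"],
    )


def _write_simple_read(bam, header, name, tid, start, seq) -> None:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("?" * len(seq))
    rec.flag = 0
    rec.reference_id = tid
    rec.reference_start = start
    rec.mapping_quality = 60
    rec.cigartuples = [(0, len(seq))]
    rec.set_tag("MD", str(len(seq)))
    rec.set_tag("NM", 0)
    bam.write(rec)


# ---------------------------------------------------------------------------
# bedMethyl


def simulate_bedmethyl(
    region_targets: Sequence[tuple[Region, float]],
    sites_per_region: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    path: str | Path = "sites.bedmethyl",
    code: str = "m",
    coverage: int = 20,
) -> pd.DataFrame:
    """Write a modkit-dialect bedMethyl file with per-region target
    methylation proportions.

    Sites are evenly spaced within each region; each site's proportion
    is the region target plus clipped Gaussian noise (``noise_sd`` = 0
    gives the target exactly). Returns the truth table with the written
    (post-rounding) per-region empirical means.
    """
    rng = np.random.default_rng(seed)
    path = os.fspath(path)
    rows = []
    with open(path, "w") as fh:
        for region, target in region_targets:
            if not 0.0 <= target <= 1.0:
                raise ValueError(f"target proportion {target} outside [0, 1]")
            span = region.end - region.start
            n = min(sites_per_region, span)
            offsets = np.unique(
                (np.arange(n) * span // max(n, 1)).astype(int)
            )
            written = []
            for off in offsets:
                p = target
                if noise_sd > 0:
                    p = float(np.clip(p + rng.normal(0, noise_sd), 0.0, 1.0))
                percent = float(f"{p * 100.0:.4f}")
                start = region.start + int(off)
                n_mod = int(round(percent / 100.0 * coverage))
                tail = (
                    f"{coverage} {percent:.4f} {n_mod} {coverage - n_mod} "
                    "0 0 0 0 0"
                )
                fh.write(
                    f"{region.chrom}\t{start}\t{start + 1}\t{code}\t"
                    f"{int(round(percent))}\t+\t{start}\t{start + 1}\t"
                    f"255,0,0\t{tail}\n"
                )
                written.append(percent / 100.0)
            rows.append(
                {
                    "chrom": region.chrom, "start": region.start,
                    "end": region.end, "label": region.label,
                    "target_proportion": target,
                    "n_sites": len(written),
                    "empirical_mean": float(np.mean(written)) if written else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Demo bundle


def demo_bundle(outdir: str | Path, seed: int = 0) -> dict[str, str]:
    """Generate a complete self-contained demo data set: a reference,
    two read samples (FASTQ.gz + truth BAM) with different error and
    quality profiles, two bedMethyl files with region-dependent
    methylation, a region BED, a sample sheet and truth tables.

    Returns a dict of the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    hp = [
        HomopolymerSpec(5_000, "A", 8),
        HomopolymerSpec(20_000, "C", 6),
        HomopolymerSpec(60_000, "G", 10),
        HomopolymerSpec(110_000, "T", 7),
    ]
    ref_seq, _ = generate_reference(
        200_000, gc_target=0.45, seed=int(rng.integers(2**31)),
        homopolymers=hp,
    )
    ref_path = write_fasta(outdir / "reference.fa", {"chr1": ref_seq})

    paths = {"reference": ref_path}
    sheet_lines = []
    profiles = {
        "sampleA": dict(sub_rate=0.05, ins_rate=0.02, del_rate=0.02,
                        q_mean=13.0, q_sd=3.0),
        "sampleB": dict(sub_rate=0.02, ins_rate=0.01, del_rate=0.01,
                        q_mean=20.0, q_sd=3.0),
    }
    for sample_id, prof in profiles.items():
        fq = outdir / f"{sample_id}.fastq.gz"
        bam = outdir / f"{sample_id}.bam"
        truth = simulate_reads(
            ref_seq, n_reads=300, read_length=1000,
            seed=int(rng.integers(2**31)),
            fastq_path=fq, bam_path=bam, read_prefix=sample_id, **prof,
        )
        truth_path = outdir / f"{sample_id}.truth.tsv"
        truth.to_csv(truth_path, sep="\t", index=False)
        paths[f"{sample_id}_fastq"] = str(fq)
        paths[f"{sample_id}_bam"] = str(bam)
        paths[f"{sample_id}_truth"] = str(truth_path)
        sheet_lines.append(f"{sample_id}\tONT\t{fq.name}")

    sheet = outdir / "sample_sheet.tsv"
    sheet.write_text("\n".join(sheet_lines) + "\n")
    paths["sample_sheet"] = str(sheet)

    regions = [
        Region("chr1", i * 20_000, (i + 1) * 20_000, f"bin{i:02d}")
        for i in range(10)
    ]
    bed = outdir / "regions.bed"
    with open(bed, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
    paths["regions"] = str(bed)

    for sample_id, base in (("sampleA", 0.15), ("sampleB", 0.75)):
        targets = [
            (r, float(np.clip(base + 0.05 * (i % 3), 0, 1)))
            for i, r in enumerate(regions)
        ]
        bm = outdir / f"{sample_id}.bedmethyl"
        truth = simulate_bedmethyl(
            targets, sites_per_region=40, noise_sd=0.05,
            seed=int(rng.integers(2**31)), path=bm,
        )
        truth.to_csv(outdir / f"{sample_id}.bedmethyl.truth.tsv",
                     sep="\t", index=False)
        paths[f"{sample_id}_bedmethyl"] = str(bm)
    return paths
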