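"""Readers and writers for the external formats the tool touches.

Every reader normalizes its input into the small domain types below
(:class:`ReadRecord`, :class:`SampleSpec`, :class:`MethylSite`,
:class:`Region`) so downstream modules never see a raw file format.
All genomic intervals are 0-based, half-open (BED convention).
Readers reject records that violate a type invariant with an error that
names the offending record; they never silently truncate.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

PLATFORMS = ("ONT", "ONT_RNA", "Pacbio")
#: Minimap2 presets used when reads must be aligned before "observe"/"gcbias".
PLATFORM_PRESETS = {
    "ONT": ["-ax", "map-ont"],
    "Pacbio": ["-ax", "map-pb"],
    "ONT_RNA": ["-ax", "splice", "-uf", "-k14"],
}

METHYL_CODES = ("m", "h")


class FormatError(ValueError):
    """Malformed input file content."""


@dataclass
class ReadRecord:
    """One sequencing read: id, bases, per-base Phred scores."""

    read_id: str
    sequence: str
    quals: list[int]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise FormatError("read with empty identifier")
        if len(self.quals) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if any(q < 0 for q in self.quals):
            raise FormatError(f"read {self.read_id!r}: negative Phred score")


@dataclass(frozen=True)
class SampleSpec:
    """One sample-sheet row: sample id, platform, data path, inferred format."""

    sample_id: str
    platform: str
    path: str
    format: str  # fastq | fastq_gz | unaligned_bam | aligned_bam

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown platform "
                f"{self.platform!r}; allowed: {', '.join(PLATFORMS)}"
            )


@dataclass(frozen=True)
class MethylSite:
    """A single CpG-level modification call (code "m" = 5mC, "h" = 5hmC)."""

    chrom: str
    start: int
    end: int
    code: str
    proportion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise FormatError(
                f"site {self.chrom}:{self.start}: proportion "
                f"{self.proportion} outside [0, 1]"
            )


@dataclass(frozen=True)
class Region:
    """A genomic interval [start, end) with an optional label."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"region {self.chrom}:{self.start}-{self.end}: start >= end"
            )


# ---------------------------------------------------------------------------
# Read input


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ file, gzip-compressed or not.

    Compression is auto-detected (htslib). Phred+33 is the only quality
    encoding accepted. A record whose quality string length differs from
    its sequence length raises :class:`FormatError` naming the record.
    """
    path = os.fspath(path)
    with pysam.FastxFile(path) as fh:
        for idx, entry in enumerate(fh):
            if entry.quality is None:
                raise FormatError(
                    f"{path}: record {idx} ({entry.name!r}) has no quality line"
                )
            if len(entry.quality) != len(entry.sequence or ""):
                raise FormatError(
                    f"{path}: record {idx} ({entry.name!r}) quality/sequence "
                    "length mismatch"
                )
            yield ReadRecord(
                read_id=entry.name,
                sequence=entry.sequence or "",
                quals=[ord(c) - 33 for c in entry.quality],
            )


def read_unaligned_reads(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a SAM/BAM file, ignoring any alignment content.

    Secondary (0x100) and supplementary (0x800) records are skipped so a
    read is never emitted twice. A record without base qualities raises.
    """
    path = os.fspath(path)
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        # until_eof also covers SAM text without any @SQ header lines
        for rec in fh.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_qualities is None:
                raise FormatError(
                    f"{path}: read {rec.query_name!r} has no base qualities"
                )
            yield ReadRecord(
                read_id=rec.query_name,
                sequence=rec.query_sequence or "",
                quals=list(rec.query_qualities),
            )


def read_reads(spec: SampleSpec) -> Iterator[ReadRecord]:
    """Dispatch on a sample's format to the matching read stream."""
    if spec.format in ("fastq", "fastq_gz"):
        return read_fastq(spec.path)
    return read_unaligned_reads(spec.path)


# ---------------------------------------------------------------------------
# bedMethyl

def _open_text(path: str | Path):
    path = os.fspath(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bedmethyl(
    path: str | Path, code_filter: str = "both"
) -> Iterator[MethylSite]:
    """Stream modification sites from a modkit-dialect bedMethyl file.

    The dialect has 9 tab-separated BED fields (chrom, start, end, code,
    score, strand, thickStart, thickEnd, color) followed by 9 further
    fields (valid coverage, percent modified, N_mod, N_canonical,
    N_other_mod, N_delete, N_fail, N_diff, N_nocall) that modkit emits
    space-separated in a single trailing tab block; fully tab-separated
    18-column lines are accepted too. Only chrom/start/end/code/percent
    are retained; the percent (0-100) is converted to a [0, 1] proportion.

    ``code_filter`` is ``"m"`` (5mC), ``"h"`` (5hmC) or ``"both"``.
    """
    if code_filter not in ("m", "h", "both"):
        raise ValueError(f"code_filter must be m, h or both, got {code_filter!r}")
    path = os.fspath(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 10:
                fields = fields[:9] + fields[9].split()
            if len(fields) != 18:
                raise FormatError(
                    f"{path}:{lineno}: expected 18 bedMethyl columns, "
                    f"got {len(fields)}"
                )
            code = fields[3]
            if code not in METHYL_CODES:
                continue
            if code_filter != "both" and code != code_filter:
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
                percent = float(fields[10])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not 0.0 <= percent <= 100.0:
                raise FormatError(
                    f"{path}:{lineno}: percent modified {percent} "
                    "outside [0, 100]"
                )
            yield MethylSite(
                chrom=fields[0], start=start, end=end, code=code,
                proportion=percent / 100.0,
            )


# ---------------------------------------------------------------------------
# Sample sheet


def _sam_has_alignments(path: str) -> bool:
    """True if a SAM/BAM file carries reference sequences in its header."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        return fh.header.nreferences > 0


def infer_format(path: str) -> str:
    lower = path.lower()
    if lower.endswith((".fastq.gz", ".fq.gz")):
        return "fastq_gz"
    if lower.endswith((".fastq", ".fq")):
        return "fastq"
    if lower.endswith((".bam", ".sam")):
        return "aligned_bam" if _sam_has_alignments(path) else "unaligned_bam"
    if lower.endswith((".bed", ".bedmethyl", ".bed.gz", ".bedmethyl.gz")):
        return "bedmethyl"
    raise FormatError(f"cannot infer read format from extension of {path!r}")


def read_sample_sheet(path: str | Path) -> list[SampleSpec]:
    """Parse the whitespace-delimited sample sheet.

    Three columns, no header: sample id, platform (ONT / ONT_RNA /
    Pacbio), data path. Paths are resolved relative to the sheet's
    directory and must exist. Duplicate sample ids are an error.
    """
    path = os.fspath(path)
    base = os.path.dirname(os.path.abspath(path))
    specs: list[SampleSpec] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns "
                    "(sample_id platform path)"
                )
            sample_id, platform, data_path = fields
            if sample_id in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate sample id {sample_id!r}"
                )
            seen.add(sample_id)
            if not os.path.isabs(data_path):
                data_path = os.path.join(base, data_path)
            if not os.path.exists(data_path):
                raise FormatError(
                    f"{path}:{lineno}: sample {sample_id!r} data file "
                    f"{data_path!r} does not exist"
                )
            specs.append(
                SampleSpec(sample_id, platform, data_path, infer_format(data_path))
            )
    return specs


# ---------------------------------------------------------------------------
# Regions (BED3 + optional label)


def read_region_bed(path: str | Path) -> list[Region]:
    """Read a BED3(+label) region table."""
    path = os.fspath(path)
    regions: list[Region] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            label = fields[3] if len(fields) > 3 else None
            try:
                regions.append(Region(fields[0], start, end, label))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return regions


# ---------------------------------------------------------------------------
# TSV output


def write_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    schema: Sequence[str],
) -> None:
    """Write rows as a TSV with a fixed column order and header row.

    Rows may be any mappings; a row missing a schema field is an error.
    An empty row list yields a header-only file. ``None`` values are
    rendered as ``NA`` and read back as missing.
    """
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("\t".join(schema) + "\n")
        for i, row in enumerate(rows):
            values = []
            for col in schema:
                if col not in row:
                    raise KeyError(f"row {i} missing field {col!r}")
                v = row[col]
                values.append("NA" if v is None else str(v))
            fh.write("\t".join(values) + "\n")
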