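"""Alignment-derived observed accuracy, error decomposition, and
homopolymer-identification scoring.

For each primary alignment the bases are partitioned into matches,
substitutions, insertions and deletions (soft/hard clips excluded,
reference skips from spliced alignments ignored):

    N_total = N_mat + N_sub + N_ins + N_del
    observed accuracy       = N_mat / N_total
    observed identification = N_mat / (N_mat + N_sub)
    ins/del/sub proportion  = N_ins/N_total, N_del/N_total, N_sub/N_total

The M operator does not distinguish matches from substitutions, so the
split uses the MD tag (or =/X operators, or the reference sequence when
neither is present).

A reference homopolymer run is scored "correctly identified" by a read
iff the alignment reproduces it exactly: every base of the run matched
(no substitution) and no insertion or deletion strictly inside the run.
Indels at the run boundary belong to the flanks and do not penalize.
Alignments that do not span the run plus one flanking base on each side
are excluded from scoring (counted as unspanned).
"""

from __future__ import annotations

import os
import re
import shutil
import subprocess
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from itertools import groupby
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .io_formats import PLATFORM_PRESETS

# CIGAR op codes
_M, _I, _D, _N, _S, _H, _P, _EQ, _X = range(9)
_REF_CONSUMING = {_M, _D, _N, _EQ, _X}

OBSERVE_COLUMNS = [
    "read_id",
    "sample_id",
    "chrom",
    "ref_start",
    "ref_end",
    "n_mat",
    "n_sub",
    "n_ins",
    "n_del",
    "n_total",
    "observed_accuracy",
    "observed_identification",
    "ins_prop",
    "del_prop",
    "sub_prop",
]

HOMOPOLYMER_SUMMARY_COLUMNS = [
    "sample_id", "base", "n_events", "n_correct", "accuracy",
]


@dataclass(frozen=True)
class AlignmentFeatureCounts:
    """Base-level alignment composition of one read (Eq. symbols
    N_mat/N_sub/N_ins/N_del; clipped bases are none of these)."""

    read_id: str
    n_mat: int
    n_sub: int
    n_ins: int
    n_del: int

    @property
    def n_total(self) -> int:
        return self.n_mat + self.n_sub + self.n_ins + self.n_del


@dataclass(frozen=True)
class ObservedMetrics:
    observed_accuracy: float
    observed_identification: float | None
    ins_prop: float
    del_prop: float
    sub_prop: float


@dataclass(frozen=True)
class HomopolymerEvent:
    """A maximal single-base run on the reference, optionally scored."""

    chrom: str
    start: int
    end: int
    base: str
    scored: bool | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceProfile:
    """Per-reference-position account of one alignment.

    ``matched`` / ``substituted`` / ``deleted`` are sets of reference
    positions; ``insertions`` maps a reference position ``p`` to the
    number of read bases inserted between ``p-1`` and ``p``.
    """

    reference_start: int
    reference_end: int
    matched: set[int]
    substituted: set[int]
    deleted: set[int]
    insertions: dict[int, int]

    @property
    def n_ins(self) -> int:
        return sum(self.insertions.values())


_MD_TOKEN = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")


def _md_mismatch_offsets(md: str) -> tuple[list[int], int]:
    """Offsets (within the aligned, non-deleted reference bases covered
    by M/=/X ops) of MD-declared mismatches, and the total aligned-base
    count the MD string accounts for."""
    offsets: list[int] = []
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        num, deletion, mismatch = m.groups()
        if num is not None:
            pos += int(num)
        elif deletion is not None:
            pass  # deleted reference bases: tracked from CIGAR, not MD
        else:
            offsets.append(pos)
            pos += 1
    return offsets, pos


def alignment_reference_profile(
    rec: pysam.AlignedSegment,
    reference: pysam.FastaFile | None = None,
) -> ReferenceProfile:
    """Classify every aligned reference position of a primary alignment.

    The match/substitution split comes from =/X operators when present,
    else from the MD tag, else by comparing the read to ``reference``.
    Raises ``ValueError`` if none of the three is available.
    """
    if rec.is_unmapped:
        raise ValueError(f"read {rec.query_name!r} is unmapped")
    cig = rec.cigartuples
    if not cig:
        raise ValueError(f"read {rec.query_name!r} has no CIGAR")

    has_eqx = any(op in (_EQ, _X) for op, _ in cig)
    md = rec.get_tag("MD") if rec.has_tag("MD") else None

    mismatch_offsets: set[int] = set()
    if not has_eqx:
        if md is not None:
            offsets, _ = _md_mismatch_offsets(str(md))
            mismatch_offsets = set(offsets)
        elif reference is None:
            raise ValueError(
                f"read {rec.query_name!r}: no MD tag, no =/X operators and "
                "no reference sequence supplied; cannot split matches from "
                "substitutions"
            )

    ref_seq = None
    if not has_eqx and md is None and reference is not None:
        ref_seq = reference.fetch(
            rec.reference_name, rec.reference_start, rec.reference_end
        ).upper()

    matched: set[int] = set()
    substituted: set[int] = set()
    deleted: set[int] = set()
    insertions: dict[int, int] = {}

    rpos = rec.reference_start
    qpos = 0
    aligned_offset = 0  # index among M/=/X reference bases, for MD offsets
    query = rec.query_sequence
    for op, length in cig:
        if op in (_M, _EQ, _X):
            for k in range(length):
                p = rpos + k
                if op == _EQ:
                    matched.add(p)
                elif op == _X:
                    substituted.add(p)
                elif ref_seq is not None:
                    qbase = query[qpos + k].upper() if query else "N"
                    rbase = ref_seq[p - rec.reference_start]
                    (matched if qbase == rbase else substituted).add(p)
                elif aligned_offset + k in mismatch_offsets:
                    substituted.add(p)
                else:
                    matched.add(p)
            rpos += length
            qpos += length
            aligned_offset += length
        elif op == _I:
            insertions[rpos] = insertions.get(rpos, 0) + length
            qpos += length
        elif op == _D:
            deleted.update(range(rpos, rpos + length))
            rpos += length
        elif op == _N:
            rpos += length  # spliced intron: not an error operation
        elif op == _S:
            qpos += length
        # H, P consume nothing we count

    return ReferenceProfile(
        reference_start=rec.reference_start,
        reference_end=rpos,
        matched=matched,
        substituted=substituted,
        deleted=deleted,
        insertions=insertions,
    )


def extract_alignment_features(
    rec: pysam.AlignedSegment,
    reference: pysam.FastaFile | None = None,
) -> AlignmentFeatureCounts:
    """Count matched / substituted / inserted / deleted bases of one
    aligned read (clips excluded)."""
    prof = alignment_reference_profile(rec, reference)
    return AlignmentFeatureCounts(
        read_id=rec.query_name,
        n_mat=len(prof.matched),
        n_sub=len(prof.substituted),
        n_ins=prof.n_ins,
        n_del=len(prof.deleted),
    )


def observed_metrics(c: AlignmentFeatureCounts) -> ObservedMetrics:
    """Observed accuracy, identification and error proportions from the
    base counts. Identification is ``None`` (missing) when the read has
    no matched or substituted base at all."""
    total = c.n_total
    if total == 0:
        raise ValueError(f"read {c.read_id!r}: zero aligned bases")
    ident_denom = c.n_mat + c.n_sub
    return ObservedMetrics(
        observed_accuracy=c.n_mat / total,
        observed_identification=(c.n_mat / ident_denom) if ident_denom else None,
        ins_prop=c.n_ins / total,
        del_prop=c.n_del / total,
        sub_prop=c.n_sub / total,
    )


# ---------------------------------------------------------------------------
# Homopolymers


def find_homopolymers_in_sequence(
    sequence: str, min_len: int = 4, chrom: str = ""
) -> list[HomopolymerEvent]:
    """All maximal single-base runs of length >= ``min_len`` in a
    sequence, in coordinate order. Runs of N (or any non-ACGT
    character) are excluded; U is treated as T."""
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    events: list[HomopolymerEvent] = []
    pos = 0
    for base, group in groupby(sequence.upper().replace("U", "T")):
        length = sum(1 for _ in group)
        if length >= min_len and base in "ACGT":
            events.append(HomopolymerEvent(chrom, pos, pos + length, base))
        pos += length
    return events


def find_reference_homopolymers(
    reference: str | Path | pysam.FastaFile, min_len: int = 4
) -> list[HomopolymerEvent]:
    """Scan every chromosome of a FASTA reference for homopolymer runs."""
    fasta = (
        reference
        if isinstance(reference, pysam.FastaFile)
        else pysam.FastaFile(os.fspath(reference))
    )
    events: list[HomopolymerEvent] = []
    for chrom in fasta.references:
        seq = fasta.fetch(chrom)
        events.extend(find_homopolymers_in_sequence(seq, min_len, chrom))
    return events


def score_homopolymer_event(
    event: HomopolymerEvent, profile: ReferenceProfile
) -> bool | None:
    """Score one homopolymer run against one alignment.

    Returns ``True``/``False`` for correct/incorrect identification, or
    ``None`` when the alignment does not span the run plus one flanking
    base on each side (the event is then excluded, not scored).
    """
    if (
        profile.reference_start > event.start - 1
        or profile.reference_end < event.end + 1
    ):
        return None
    run = range(event.start, event.end)
    if any(p in profile.substituted or p in profile.deleted for p in run):
        return False
    if not all(p in profile.matched for p in run):
        return False  # e.g. run interrupted by an unaligned gap
    # insertion between p-1 and p is strictly inside the run iff both
    # neighbours are run positions
    if any(
        event.start + 1 <= p <= event.end - 1 for p in profile.insertions
    ):
        return False
    return True


def summarize_homopolymers(
    events: Iterable[HomopolymerEvent], sample_id: str = ""
) -> pd.DataFrame:
    """Per-base-type identification accuracy over scored events.

    A base type with no scored event gets a missing accuracy (NaN),
    never zero.
    """
    counts = {b: [0, 0] for b in "ACGT"}  # base -> [n_events, n_correct]
    for ev in events:
        if ev.scored is None:
            continue
        counts[ev.base][0] += 1
        counts[ev.base][1] += int(ev.scored)
    rows = []
    for base in "ACGT":
        n, correct = counts[base]
        rows.append(
            {
                "sample_id": sample_id,
                "base": base,
                "n_events": n,
                "n_correct": correct,
                "accuracy": (correct / n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=HOMOPOLYMER_SUMMARY_COLUMNS)


# ---------------------------------------------------------------------------
# Whole-file orchestration


def observe_alignments(
    alignment_path: str | Path,
    reference_path: str | Path | None = None,
    sample_id: str = "",
    min_homopolymer_len: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full observed-accuracy analysis over an aligned SAM/BAM.

    Returns the per-read metrics table, the per-base homopolymer summary
    and a stats dict (reads scored / unmapped skipped / homopolymer
    events scored and unspanned).
    """
    alignment_path = os.fspath(alignment_path)
    fasta = (
        pysam.FastaFile(os.fspath(reference_path)) if reference_path else None
    )

    hp_by_chrom: dict[str, list[HomopolymerEvent]] = {}
    hp_starts: dict[str, list[int]] = {}
    if fasta is not None:
        for ev in find_reference_homopolymers(fasta, min_homopolymer_len):
            hp_by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in hp_by_chrom.items():
            evs.sort(key=lambda e: e.start)
            hp_starts[chrom] = [e.start for e in evs]

    rows = []
    scored_events: list[HomopolymerEvent] = []
    stats = {"reads_scored": 0, "reads_skipped_unmapped": 0,
             "reads_skipped_secondary": 0, "hp_scored": 0, "hp_unspanned": 0}

    with pysam.AlignmentFile(alignment_path) as bam:
        for rec in bam:
            if rec.is_secondary or rec.is_supplementary:
                stats["reads_skipped_secondary"] += 1
                continue
            if rec.is_unmapped:
                stats["reads_skipped_unmapped"] += 1
                continue
            prof = alignment_reference_profile(rec, fasta)
            counts = AlignmentFeatureCounts(
                read_id=rec.query_name,
                n_mat=len(prof.matched),
                n_sub=len(prof.substituted),
                n_ins=prof.n_ins,
                n_del=len(prof.deleted),
            )
            m = observed_metrics(counts)
            rows.append(
                {
                    "read_id": rec.query_name,
                    "sample_id": sample_id,
                    "chrom": rec.reference_name,
                    "ref_start": rec.reference_start,
                    "ref_end": prof.reference_end,
                    "n_mat": counts.n_mat,
                    "n_sub": counts.n_sub,
                    "n_ins": counts.n_ins,
                    "n_del": counts.n_del,
                    "n_total": counts.n_total,
                    "observed_accuracy": m.observed_accuracy,
                    "observed_identification": m.observed_identification,
                    "ins_prop": m.ins_prop,
                    "del_prop": m.del_prop,
                    "sub_prop": m.sub_prop,
                }
            )
            stats["reads_scored"] += 1

            chrom = rec.reference_name
            if chrom in hp_by_chrom:
                evs, starts = hp_by_chrom[chrom], hp_starts[chrom]
                lo = bisect_left(starts, prof.reference_start)
                hi = bisect_right(starts, prof.reference_end)
                for ev in evs[lo:hi]:
                    verdict = score_homopolymer_event(ev, prof)
                    if verdict is None:
                        stats["hp_unspanned"] += 1
                    else:
                        stats["hp_scored"] += 1
                        scored_events.append(replace(ev, scored=verdict))

    per_read = pd.DataFrame(rows, columns=OBSERVE_COLUMNS)
    hp_summary = summarize_homopolymers(scored_events, sample_id)
    return per_read, hp_summary, stats


def align_with_minimap2(
    reads_path: str | Path,
    reference_path: str | Path,
    platform: str,
    out_bam: str | Path,
    threads: int = 1,
) -> str:
    """Align reads with minimap2 (platform-specific preset, MD tags on,
    secondary alignments suppressed), then coordinate-sort and index.

    Returns the sorted BAM path. Requires ``minimap2`` and ``samtools``
    on PATH.
    """
    if platform not in PLATFORM_PRESETS:
        raise ValueError(f"unknown platform {platform!r}")
    for tool in ("minimap2", "samtools"):
        if shutil.which(tool) is None:
            raise RuntimeError(f"{tool} not found on PATH")
    out_bam = os.fspath(out_bam)
    preset = PLATFORM_PRESETS[platform]
    cmd = (
        ["minimap2"] + preset
        + ["--MD", "--secondary=no", "-t", str(threads),
           os.fspath(reference_path), os.fspath(reads_path)]
    )
    aln = subprocess.run(cmd, capture_output=True, check=True)
    sort = subprocess.run(
        ["samtools", "sort", "-@", str(threads), "-O", "BAM", "-o", out_bam],
        input=aln.stdout, capture_output=True, check=True,
    )
    subprocess.run(["samtools", "index", out_bam], check=True,
                   capture_output=True)
    return out_bam
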