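"""GC-content sequencing-bias profiling.

The reference is tiled into fixed-width bins (default 1 kb). For each
bin the GC fraction and the mean per-base sequencing depth are computed,
the bin is assigned to an integer GC-percent category (0-100), and depth
is normalized within an automatically selected GC window: the narrowest
contiguous category window containing at least 90% of the scored bins
(most genomes occupy a small part of the 0-100% spectrum, and bins at
extreme GC are too few for a stable depth estimate). Normalized depth is
mean depth divided by the mean depth of the in-window bins, so a
bias-free library has a flat profile at 1.0.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

BIN_COLUMNS = [
    "chrom", "start", "end", "gc_fraction", "gc_category",
    "mean_depth", "normalized_depth",
]

PROFILE_COLUMNS = ["gc_category", "n_bins", "mean_normalized_depth"]


@dataclass(frozen=True)
class GcScale:
    """Inclusive GC-percent window used for depth normalization."""

    lo: int
    hi: int
    bin_coverage: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo <= self.hi <= 100:
            raise ValueError(f"invalid GC scale [{self.lo}, {self.hi}]")


def make_bins(
    reference: str | Path | pysam.FastaFile, bin_size: int = 1000
) -> pd.DataFrame:
    """Tile every chromosome into non-overlapping ``bin_size`` windows.

    Trailing partial bins are dropped (unequal lengths would distort the
    GC/depth comparison), as are bins without a single unambiguous base.
    GC is computed with N-exclusion. A chromosome shorter than one bin
    contributes nothing (with a warning).
    """
    if bin_size < 100:
        raise ValueError(f"bin_size must be >= 100, got {bin_size}")
    fasta = (
        reference
        if isinstance(reference, pysam.FastaFile)
        else pysam.FastaFile(os.fspath(reference))
    )
    if not fasta.references:
        raise ValueError("reference contains no sequences")
    rows = []
    for chrom in fasta.references:
        length = fasta.get_reference_length(chrom)
        n_bins = length // bin_size
        if n_bins == 0:
            warnings.warn(
                f"chromosome {chrom!r} shorter than one bin "
                f"({length} < {bin_size}); skipped"
            )
            continue
        seq = fasta.fetch(chrom, 0, n_bins * bin_size).upper()
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        arr = arr.reshape(n_bins, bin_size)
        gc = ((arr == ord("G")) | (arr == ord("C"))).sum(axis=1)
        at = ((arr == ord("A")) | (arr == ord("T")) | (arr == ord("U"))).sum(
            axis=1
        )
        denom = gc + at
        for i in range(n_bins):
            if denom[i] == 0:
                continue  # all-N bin
            frac = gc[i] / denom[i]
            rows.append(
                {
                    "chrom": chrom,
                    "start": i * bin_size,
                    "end": (i + 1) * bin_size,
                    "gc_fraction": frac,
                    "gc_category": int(round(100.0 * frac)),
                    "mean_depth": np.nan,
                    "normalized_depth": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def _keep_read(rec: pysam.AlignedSegment) -> bool:
    return not (
        rec.is_unmapped
        or rec.is_secondary
        or rec.is_supplementary
        or rec.is_duplicate
        or rec.is_qcfail
    )


def bin_depth(bins: pd.DataFrame, alignment_path: str | Path) -> pd.DataFrame:
    """Mean per-base depth per bin from primary alignments.

    Requires a coordinate-sorted, indexable BAM (the index is built on
    the fly if absent); an unsorted file raises with instructions.
    """
    alignment_path = os.fspath(alignment_path)
    with pysam.AlignmentFile(alignment_path) as bam:
        so = bam.header.get("HD", {}).get("SO", "unknown")
        if so != "coordinate":
            raise ValueError(
                f"{alignment_path}: not coordinate-sorted (SO: {so}); "
                "sort with 'samtools sort' first"
            )
        if not bam.has_index():
            pysam.index(alignment_path)
    bins = bins.copy()
    depths = np.zeros(len(bins), dtype=float)
    with pysam.AlignmentFile(alignment_path) as bam:
        for chrom, group in bins.groupby("chrom", sort=False):
            if chrom not in bam.references:
                continue
            clen = bam.get_reference_length(chrom)
            cov = np.zeros(clen, dtype=np.int64)
            acgt = bam.count_coverage(
                chrom, 0, clen, quality_threshold=0, read_callback=_keep_read
            )
            cov = np.sum(np.asarray(acgt), axis=0)
            for idx, row in zip(group.index, group.itertuples()):
                depths[bins.index.get_loc(idx)] = cov[
                    row.start:row.end
                ].mean()
    bins["mean_depth"] = depths
    return bins


def select_scale(
    bins: pd.DataFrame, required_coverage: float = 0.90
) -> GcScale:
    """Narrowest contiguous GC-percent window holding at least
    ``required_coverage`` of the scored bins.

    Ties between equally narrow windows are broken by the window whose
    center is nearest the modal GC category, then by the lower bound.
    """
    if bins.empty:
        raise ValueError("no scored bins")
    cats = bins["gc_category"].to_numpy()
    counts = np.bincount(cats, minlength=101)
    total = counts.sum()
    mode = int(np.argmax(counts))
    cum = np.concatenate([[0], np.cumsum(counts)])

    best: tuple | None = None
    for width in range(101):
        for lo in range(0, 101 - width):
            hi = lo + width
            inside = cum[hi + 1] - cum[lo]
            if inside / total >= required_coverage:
                key = (abs((lo + hi) / 2.0 - mode), lo)
                if best is None or key < best[0]:
                    best = (key, lo, hi, inside / total)
        if best is not None:
            break
    assert best is not None  # width 100 always covers everything
    _, lo, hi, coverage = best
    return GcScale(lo=lo, hi=hi, bin_coverage=float(coverage))


def normalize_depth(
    bins: pd.DataFrame, scale: GcScale
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize bin depths by the mean depth of in-scale bins.

    Returns the bin table with ``normalized_depth`` filled for every bin,
    and the per-GC-category profile (bin count and mean normalized depth
    for each category with at least one bin).
    """
    if bins.empty:
        raise ValueError("no scored bins")
    bins = bins.copy()
    in_scale = bins["gc_category"].between(scale.lo, scale.hi)
    if not in_scale.any():
        raise ValueError(
            f"no bins inside GC scale [{scale.lo}, {scale.hi}]"
        )
    mean_in_scale = bins.loc[in_scale, "mean_depth"].mean()
    if not mean_in_scale > 0:
        raise ValueError("zero mean depth inside the normalization scale")
    bins["normalized_depth"] = bins["mean_depth"] / mean_in_scale
    profile = (
        bins.groupby("gc_category")["normalized_depth"]
        .agg(n_bins="size", mean_normalized_depth="mean")
        .reset_index()
    )
    return bins, profile[PROFILE_COLUMNS]


def renormalize(
    bins: pd.DataFrame, lo: int, hi: int
) -> tuple[pd.DataFrame, pd.DataFrame, GcScale]:
    """Re-run normalization with a user-supplied GC window.

    The returned :class:`GcScale` reports what fraction of the scored
    bins the user's window actually covers. A window containing no bin
    is an error.
    """
    inside = bins["gc_category"].between(lo, hi).sum()
    scale = GcScale(lo=lo, hi=hi, bin_coverage=float(inside / len(bins)))
    if inside == 0:
        raise ValueError(f"user GC scale [{lo}, {hi}] contains no bins")
    out_bins, profile = normalize_depth(bins, scale)
    return out_bins, profile, scale


def gcbias_analysis(
    reference_path: str | Path,
    alignment_path: str | Path,
    bin_size: int = 1000,
    required_coverage: float = 0.90,
    user_scale: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GcScale]:
    """Full GC-bias pipeline: bin, measure depth, select scale (unless a
    manual one is given), normalize. Returns (bins, profile, scale)."""
    bins = make_bins(reference_path, bin_size)
    if bins.empty:
        raise ValueError("no scored bins in reference")
    bins = bin_depth(bins, alignment_path)
    if user_scale is not None:
        bins, profile, scale = renormalize(bins, *user_scale)
    else:
        scale = select_scale(bins, required_coverage)
        bins, profile = normalize_depth(bins, scale)
    return bins, profile, scale
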