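"""Aggregation of site-level methylation proportions over genomic regions.

Sites (CpG-level modification proportions from a bedMethyl file) are
assigned to user-supplied target regions by half-open interval overlap
of the site start, and each region is summarized by the unweighted
arithmetic mean of its site proportions — coverage information has
already been discarded upstream, so every site counts equally. Regions
without any site report a missing value, never zero. Fixed-width tiling
of the genome (e.g. 1 Mb bins) is a supported region source.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import MethylSite, Region

REGION_SUMMARY_COLUMNS = [
    "chrom", "start", "end", "label", "sample_id", "n_sites",
    "mean_proportion",
]


def assign_sites_to_regions(
    sites: Iterable[MethylSite],
    regions: Sequence[Region],
    allow_overlap: bool = False,
) -> tuple[dict[int, list[MethylSite]], int]:
    """Map each site to the region(s) containing its start coordinate.

    A site lands in region ``r`` iff ``r.start <= site.start < r.end``
    on the same chromosome. Returns ``(assignment, n_orphans)`` where
    ``assignment`` maps region index -> sites and ``n_orphans`` counts
    sites matching no region. Overlapping regions are rejected unless
    ``allow_overlap`` is set, in which case a site may count in several
    regions.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, region in enumerate(regions):
        tree = trees.setdefault(region.chrom, IntervalTree())
        if not allow_overlap and tree.overlaps(region.start, region.end):
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} overlaps "
                "another region; pass allow_overlap=True to permit this"
            )
        tree.addi(region.start, region.end, idx)

    assignment: dict[int, list[MethylSite]] = {i: [] for i in range(len(regions))}
    orphans = 0
    for site in sites:
        tree = trees.get(site.chrom)
        hits = tree[site.start] if tree is not None else ()
        if not hits:
            orphans += 1
            continue
        for iv in hits:
            assignment[iv.data].append(site)
    return assignment, orphans


def regional_summary(
    assignment: Mapping[int, list[MethylSite]],
    regions: Sequence[Region],
    sample_id: str = "",
) -> pd.DataFrame:
    """Unweighted mean site proportion per region, one row per region in
    input order; empty regions get NaN."""
    rows = []
    for idx, region in enumerate(regions):
        sites = assignment.get(idx, [])
        props = [s.proportion for s in sites]
        if not props:
            mean = np.nan
        elif min(props) == max(props):
            # constant-proportion regions average to that value exactly,
            # not to within a summation ulp
            mean = props[0]
        else:
            mean = float(np.mean(props))
        rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "label": region.label,
                "sample_id": sample_id,
                "n_sites": len(sites),
                "mean_proportion": mean,
            }
        )
    return pd.DataFrame(rows, columns=REGION_SUMMARY_COLUMNS)


def tile_regions(
    chrom_lengths: Mapping[str, int], bin_size: int
) -> list[Region]:
    """Fixed-width tiling of each chromosome; the trailing partial
    region is kept (methylation means are length-insensitive)."""
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    regions: list[Region] = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + bin_size, length)
            regions.append(Region(chrom, start, end, f"{chrom}:{start}-{end}"))
            start = end
    return regions


def modbin_analysis(
    sites: Iterable[MethylSite],
    regions: Sequence[Region],
    sample_id: str = "",
    allow_overlap: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Assign and summarize in one call; returns (summary, n_orphans)."""
    assignment, orphans = assign_sites_to_regions(
        sites, regions, allow_overlap
    )
    return regional_summary(assignment, regions, sample_id), orphans


def join_samples(summaries: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Wide comparison table: one row per region, one mean-proportion
    column per sample (for cross-sample plotting)."""
    if not summaries:
        return pd.DataFrame()
    wide = None
    for summary in summaries:
        sid = summary["sample_id"].iloc[0] if len(summary) else "sample"
        part = summary[["chrom", "start", "end", "label", "mean_proportion"]]
        part = part.rename(columns={"mean_proportion": f"mean_proportion_{sid}"})
        wide = part if wide is None else wide.merge(
            part, on=["chrom", "start", "end", "label"], how="outer"
        )
    return wide
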