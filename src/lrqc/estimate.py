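"""Per-read estimated quality metrics from base qualities alone.

The estimated read accuracy is computed without any alignment: each base
quality ``q_i`` (Phred scale) is converted to an error probability
``10^(-q_i/10)``, the per-base probabilities are averaged over the read,
and the accuracy is one minus that mean error probability:

    estimated accuracy = 1 - (1/N) * sum_i 10^(-q_i / 10)

The per-read Q score reported alongside is recomputed from the mean
error probability, ``-10*log10(mean p)``, so the accuracy and Q columns
are always mutually consistent (the arithmetic mean of q_i would not be).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import ReadRecord, SampleSpec

#: Columns of the per-read estimate table, in output order.
ESTIMATE_COLUMNS = [
    "read_id",
    "sample_id",
    "length",
    "gc_content",
    "mean_error_prob",
    "estimated_accuracy",
    "estimated_error",
    "read_q",
]


@dataclass(frozen=True)
class ReadQualityEstimate:
    read_id: str
    sample_id: str
    length: int
    gc_content: float | None
    mean_error_prob: float
    estimated_accuracy: float
    read_q: float

    @property
    def estimated_error(self) -> float:
        return 1.0 - self.estimated_accuracy


def phred_to_error_prob(q: float) -> float:
    """Error probability of a basecall with Phred score ``q`` (>= 0)."""
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def mean_error_prob(quals: Iterable[int]) -> float:
    q = np.asarray(list(quals), dtype=float)
    if q.size == 0:
        raise ValueError("read has no bases; accuracy undefined")
    if (q < 0).any():
        raise ValueError("negative Phred score")
    # constant-quality reads (e.g. uniform-Q HiFi records): the mean is
    # the per-base value itself; computing it directly keeps the
    # constant-q closed form exact instead of within a rounding ulp
    if q[0] == q.max() == q.min():
        return float(10.0 ** (-q[0] / 10.0))
    return float(np.mean(10.0 ** (-q / 10.0)))


def estimated_read_accuracy(quals: Iterable[int]) -> float:
    """Alignment-free read accuracy: 1 minus the mean per-base error
    probability. Undefined (an error) for an empty read."""
    return 1.0 - mean_error_prob(quals)


_GC = frozenset("GCgc")
_AT = frozenset("ATUatu")  # U (direct RNA) counts with T


def read_gc_content(sequence: str) -> float | None:
    """GC fraction of a read; N (and other ambiguity codes) excluded from
    numerator and denominator. ``None`` when no unambiguous base exists."""
    if not sequence:
        raise ValueError("empty sequence")
    gc = sum(1 for b in sequence if b in _GC)
    at = sum(1 for b in sequence if b in _AT)
    denom = gc + at
    if denom == 0:
        return None
    return gc / denom


def estimate_read(read: ReadRecord, sample_id: str = "") -> ReadQualityEstimate:
    p = mean_error_prob(read.quals)
    return ReadQualityEstimate(
        read_id=read.read_id,
        sample_id=sample_id,
        length=len(read.sequence),
        gc_content=read_gc_content(read.sequence),
        mean_error_prob=p,
        estimated_accuracy=1.0 - p,
        read_q=-10.0 * math.log10(p),
    )


def summarize_estimates(
    reads: Iterable[ReadRecord], sample: SampleSpec | str
) -> pd.DataFrame:
    """Per-read estimate table for one sample (one row per read, input
    order preserved). See :func:`sample_summary` for the roll-up."""
    sample_id = sample if isinstance(sample, str) else sample.sample_id
    rows = []
    for read in reads:
        est = estimate_read(read, sample_id)
        rows.append(
            {
                "read_id": est.read_id,
                "sample_id": est.sample_id,
                "length": est.length,
                "gc_content": est.gc_content,
                "mean_error_prob": est.mean_error_prob,
                "estimated_accuracy": est.estimated_accuracy,
                "estimated_error": est.estimated_error,
                "read_q": est.read_q,
            }
        )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def sample_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and median of each numeric estimate column, one row per
    statistic; empty (but well-formed) for an empty per-read table."""
    numeric = [c for c in ESTIMATE_COLUMNS if c not in ("read_id", "sample_id")]
    out_cols = ["sample_id", "statistic", "n_reads"] + numeric
    if table.empty:
        return pd.DataFrame(columns=out_cols)
    rows = []
    for sample_id, group in table.groupby("sample_id", sort=True):
        vals = group[numeric].astype(float)
        for stat, fn in (("mean", np.nanmean), ("median", np.nanmedian)):
            row = {"sample_id": sample_id, "statistic": stat,
                   "n_reads": len(group)}
            for col in numeric:
                row[col] = float(fn(vals[col].to_numpy()))
            rows.append(row)
    return pd.DataFrame(rows, columns=out_cols)
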