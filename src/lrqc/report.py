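"""Figures and the self-contained HTML summary report.

All figures are drawn with matplotlib/seaborn on the Agg backend and
embedded into a single HTML file as base64 PNGs, so the report renders
with zero network access. Rendering uses stdlib string templating.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from string import Template

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

sns.set_theme(style="whitegrid")

_PAGE = Template(
    """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>$title</title>
<style>
body { font-family: sans-serif; margin: 2em auto; max-width: 1100px;
       color: #222; }
h1 { border-bottom: 2px solid #4a7; padding-bottom: 0.2em; }
h2 { color: #264; margin-top: 2em; }
table { border-collapse: collapse; margin: 1em 0; font-size: 0.9em; }
th, td { border: 1px solid #bbb; padding: 0.3em 0.7em; text-align: right; }
th { background: #eef5ee; }
img { max-width: 100%; margin: 0.5em 0; }
.note { color: #666; font-size: 0.85em; }
</style>
</head>
<body>
<h1>$title</h1>
<p class="note">$subtitle</p>
$sections
</body>
</html>
"""
)

_SECTION = Template("<h2>$heading</h2>\n$body\n")


@dataclass
class ReportSection:
    heading: str
    tables: list[pd.DataFrame] = field(default_factory=list)
    figures: list[plt.Figure] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _fig_to_img(fig: plt.Figure) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode("ascii")
    return f'<img src="data:image/png;base64,{data}">'


def render_report(
    sections: list[ReportSection],
    title: str = "Long-read QC comparison report",
    subtitle: str = "",
) -> str:
    """Render completed stage outputs into one self-contained HTML page."""
    if not sections:
        raise ValueError("no completed stages to report")
    html_sections = []
    for sec in sections:
        parts = []
        for note in sec.notes:
            parts.append(f'<p class="note">{note}</p>')
        for table in sec.tables:
            parts.append(
                table.to_html(index=False, float_format=lambda v: f"{v:.4g}",
                              na_rep="NA", border=0)
            )
        for fig in sec.figures:
            parts.append(_fig_to_img(fig))
        html_sections.append(
            _SECTION.substitute(heading=sec.heading, body="\n".join(parts))
        )
    return _PAGE.substitute(
        title=title, subtitle=subtitle, sections="\n".join(html_sections)
    )


# ---------------------------------------------------------------------------
# Stage figures


def plot_estimate(per_read: pd.DataFrame) -> list[plt.Figure]:
    """Accuracy density, length density (log10 axis) and GC boxplot,
    one curve/box per sample."""
    figs = []
    fig, ax = plt.subplots(figsize=(6, 3.5))
    sns.kdeplot(
        data=per_read.assign(
            estimated_accuracy_pct=per_read["estimated_accuracy"] * 100
        ),
        x="estimated_accuracy_pct", hue="sample_id", common_norm=False, ax=ax,
    )
    ax.set_xlabel("Estimated read accuracy (%)")
    figs.append(fig)

    fig, ax = plt.subplots(figsize=(6, 3.5))
    sns.kdeplot(
        data=per_read, x="length", hue="sample_id", log_scale=True,
        common_norm=False, ax=ax,
    )
    ax.set_xlabel("Read length (bases)")
    figs.append(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    sns.boxplot(
        data=per_read.assign(gc_pct=per_read["gc_content"] * 100),
        x="sample_id", y="gc_pct", ax=ax,
    )
    ax.set_ylabel("Read GC content (%)")
    figs.append(fig)
    return figs


def plot_observe(per_read: pd.DataFrame, hp_summary: pd.DataFrame
                 ) -> list[plt.Figure]:
    figs = []
    fig, ax = plt.subplots(figsize=(6, 3.5))
    sns.kdeplot(
        data=per_read.assign(acc_pct=per_read["observed_accuracy"] * 100),
        x="acc_pct", hue="sample_id", common_norm=False, ax=ax,
    )
    ax.set_xlabel("Observed read accuracy (%)")
    figs.append(fig)

    melted = per_read.melt(
        id_vars=["sample_id"],
        value_vars=["ins_prop", "del_prop", "sub_prop"],
        var_name="error_type", value_name="proportion",
    )
    fig, ax = plt.subplots(figsize=(6, 3.5))
    sns.boxplot(
        data=melted, x="error_type", y="proportion", hue="sample_id", ax=ax,
    )
    ax.set_ylabel("Proportion of aligned bases")
    figs.append(fig)

    if not hp_summary.empty and hp_summary["n_events"].sum() > 0:
        fig, ax = plt.subplots(figsize=(5.5, 3.5))
        sns.barplot(
            data=hp_summary, x="base", y="accuracy", hue="sample_id", ax=ax,
        )
        ax.set_ylabel("Homopolymer identification accuracy")
        ax.set_ylim(0, 1.05)
        figs.append(fig)
    return figs


def plot_gcbias(bins: pd.DataFrame, profile: pd.DataFrame,
                sample_id: str = "") -> list[plt.Figure]:
    figs = []
    fig, ax = plt.subplots(figsize=(6, 3.5))
    counts = bins.groupby("gc_category").size()
    ax.bar(counts.index, counts.values, width=1.0, color="#4a7")
    ax.set_xlabel("Bin GC content (%)")
    ax.set_ylabel("Number of bins")
    if sample_id:
        ax.set_title(sample_id)
    figs.append(fig)

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(profile["gc_category"], profile["mean_normalized_depth"],
            marker="o", ms=3, color="#264")
    ax.axhline(1.0, ls="--", color="#999", lw=1)
    ax.set_xlabel("Bin GC content (%)")
    ax.set_ylabel("Mean normalized depth")
    if sample_id:
        ax.set_title(sample_id)
    figs.append(fig)
    return figs


def plot_modbin(summaries: pd.DataFrame) -> list[plt.Figure]:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    sns.violinplot(
        data=summaries, x="sample_id", y="mean_proportion", cut=0, ax=ax,
    )
    ax.set_ylabel("Regional methylation proportion")
    return [fig]
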