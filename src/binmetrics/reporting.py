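"""Comparative outputs: flat tables, rankings, heat maps, plots, HTML.

All numeric tables are written as TSV with ``#``-prefixed header
comments, 6 significant digits, and deterministic ordering, so reruns
on identical input produce byte-identical files.  Images and the HTML
summary page are conveniences layered on top of those tables; the data
series behind every plot panel is itself written as TSV so that the
rendering is verifiable numerically.
"""

from __future__ import annotations

import base64
import logging
import os
from dataclasses import dataclass
from html import escape
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contingency import BinGenomeMapping, ContingencyTable
from .metrics import (
    RANK_COMPLETENESS,
    RANK_PURITY,
    RANK_SUM,
    AssessmentSummary,
    BinMetrics,
    rank_binnings,
)

logger = logging.getLogger(__name__)

UNASSIGNED_ROW = "unassigned"


def _fmt(value: float) -> str:
    """Render a number with 6 significant digits (ints unchanged)."""
    if isinstance(value, (int, np.integer)) and not isinstance(value, bool):
        return str(int(value))
    return f"{value:.6g}"


@dataclass
class HeatmapMatrix:
    """Bin x genome base-pair matrix ordered for visual diagonality.

    Rows are predicted bins sorted by true positives descending, plus a
    terminal ``unassigned`` row; columns are genomes ordered to follow
    the mapped genome of each sorted bin.  Row sums (excluding the last
    row) equal bin sizes; column sums over all rows equal genome sizes.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


def heatmap_matrix(
    ct: ContingencyTable, mapping: BinGenomeMapping
) -> HeatmapMatrix:
    """Order the contingency table so true positives hug the diagonal.

    Bins are sorted by TP descending (ties: larger bin first, then
    label); genomes follow the mapped genome of each sorted bin, first
    occurrence winning, with genomes mapped by no bin appended in
    descending size (ties by id).  The final row holds the unassigned
    base pairs of every genome.
    """
    bins = sorted(
        ct.bin_totals_bp,
        key=lambda x: (-mapping.tp_bp[x], -ct.bin_totals_bp[x], x),
    )
    cols: list[str] = []
    for x in bins:
        g = mapping.mapped_genome[x]
        if g not in cols:
            cols.append(g)
    rest = sorted(
        (g for g in ct.genome_sizes if g not in cols),
        key=lambda g: (-ct.genome_sizes[g], g),
    )
    cols.extend(rest)
    values = np.zeros((len(bins) + 1, len(cols)), dtype=np.int64)
    col_index = {g: j for j, g in enumerate(cols)}
    for i, x in enumerate(bins):
        for (bx, y), bp in ct.cells_bp.items():
            if bx == x:
                values[i, col_index[y]] = bp
    for y, bp in ct.unassigned_per_genome_bp.items():
        values[len(bins), col_index[y]] = bp
    return HeatmapMatrix(
        row_ids=bins + [UNASSIGNED_ROW], col_ids=cols, values=values
    )


SUMMARY_COLUMNS = [
    "label",
    "avg_purity",
    "avg_contamination",
    "truncated_avg_purity",
    "alpha",
    "avg_completeness",
    "avg_purity_bp",
    "avg_completeness_bp",
    "accuracy",
    "ari_bp",
    "ari_seq",
    "pct_assigned_bp",
    "n_bins",
    "n_bins_after_truncation",
    "n_genomes",
    "std_error_purity",
    "std_error_completeness",
]


def _write_tsv(path: Path, header_comment: str, lines: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# {header_comment}\n")
        for line in lines:
            fh.write(line + "\n")


def write_flat_reports(
    summaries: Sequence[AssessmentSummary],
    outdir: str | os.PathLike,
    per_bin: dict[str, Sequence[BinMetrics]] | None = None,
) -> list[Path]:
    """Write the metric tables as deterministic TSV flat files.

    Emits ``summary.tsv`` (one row per binning), ``recovery.tsv`` (the
    genome-recovery table: rows binner x contamination bound, columns
    completeness bounds), ``rankings.tsv`` (all three ranking criteria)
    and, when per-bin records are given, ``bins/<label>.tsv``.
    """
    if not summaries:
        raise ValueError("write_flat_reports requires at least one summary")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = [
        "\t".join(_fmt(s.as_dict()[c]) if c != "label" else s.label
                  for c in SUMMARY_COLUMNS)
        for s in summaries
    ]
    path = outdir / "summary.tsv"
    _write_tsv(path, "per-binning assessment metrics",
               ["\t".join(SUMMARY_COLUMNS)] + rows)
    written.append(path)

    # recovery table: binner x contamination bound rows, completeness cols
    r_bounds = sorted({r for s in summaries for (_c, r) in s.recovery_counts})
    c_bounds = sorted({c for s in summaries for (c, _r) in s.recovery_counts})
    header = ["label", "contamination"] + [f">{_fmt(r)}" for r in r_bounds]
    rec_lines = ["\t".join(header)]
    for s in summaries:
        for c in c_bounds:
            cells = [str(s.recovery_counts.get((c, r), 0)) for r in r_bounds]
            rec_lines.append("\t".join([s.label, f"<{_fmt(c)}"] + cells))
    path = outdir / "recovery.tsv"
    _write_tsv(path, "genomes recovered under contamination/completeness bounds",
               rec_lines)
    written.append(path)

    rank_lines = ["\t".join(["criterion", "rank", "label", "score"])]
    for criterion in (RANK_PURITY, RANK_COMPLETENESS, RANK_SUM):
        ranked = rank_binnings(summaries, criterion)
        for i, s in enumerate(ranked, start=1):
            score = {
                RANK_PURITY: s.truncated_avg_purity,
                RANK_COMPLETENESS: s.avg_completeness,
                RANK_SUM: s.truncated_avg_purity + s.avg_completeness,
            }[criterion]
            rank_lines.append(
                "\t".join([criterion, str(i), s.label, _fmt(score)])
            )
    path = outdir / "rankings.tsv"
    _write_tsv(path, "binnings ranked by each criterion", rank_lines)
    written.append(path)

    if per_bin:
        bin_dir = outdir / "bins"
        bin_dir.mkdir(exist_ok=True)
        for label in sorted(per_bin):
            lines = ["\t".join(
                ["bin_id", "mapped_genome", "size_bp", "purity",
                 "completeness", "contamination"])]
            for b in sorted(per_bin[label], key=lambda b: b.bin_id):
                lines.append("\t".join([
                    b.bin_id, b.mapped_genome, str(b.size_bp),
                    _fmt(b.purity), _fmt(b.completeness),
                    _fmt(b.contamination),
                ]))
            path = bin_dir / f"{label}.tsv"
            _write_tsv(path, f"per-bin metrics for {label}", lines)
            written.append(path)
    return written


def write_heatmap_tsv(
    hm: HeatmapMatrix, path: str | os.PathLike
) -> None:
    lines = ["\t".join(["bin"] + hm.col_ids)]
    for i, row_id in enumerate(hm.row_ids):
        lines.append(
            "\t".join([row_id] + [str(int(v)) for v in hm.values[i]])
        )
    _write_tsv(Path(path), "bin x genome base-pair assignment matrix", lines)


def write_plot_data(
    summaries: Sequence[AssessmentSummary],
    per_bin: dict[str, Sequence[BinMetrics]],
    outdir: str | os.PathLike,
) -> list[Path]:
    """Write the data series behind each plot panel as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    lines = ["\t".join(["label", "truncated_avg_purity", "std_error_purity",
                        "avg_completeness", "std_error_completeness"])]
    for s in summaries:
        lines.append("\t".join([
            s.label, _fmt(s.truncated_avg_purity), _fmt(s.std_error_purity),
            _fmt(s.avg_completeness), _fmt(s.std_error_completeness)]))
    p = outdir / "purity_vs_completeness.tsv"
    _write_tsv(p, "avg purity per bin vs avg completeness per genome", lines)
    written.append(p)

    lines = ["\t".join(["label", "avg_purity_bp", "avg_completeness_bp"])]
    for s in summaries:
        lines.append("\t".join(
            [s.label, _fmt(s.avg_purity_bp), _fmt(s.avg_completeness_bp)]))
    p = outdir / "purity_vs_completeness_bp.tsv"
    _write_tsv(p, "per-base-pair purity vs completeness", lines)
    written.append(p)

    lines = ["\t".join(["label", "ari_bp", "pct_assigned_bp"])]
    for s in summaries:
        lines.append("\t".join(
            [s.label, _fmt(s.ari_bp), _fmt(s.pct_assigned_bp)]))
    p = outdir / "ari_vs_assigned.tsv"
    _write_tsv(p, "adjusted Rand index vs fraction of assigned base pairs", lines)
    written.append(p)

    lines = ["\t".join(["label", "bin_id", "purity", "completeness"])]
    for label in sorted(per_bin):
        for b in sorted(per_bin[label], key=lambda b: b.bin_id):
            lines.append("\t".join(
                [label, b.bin_id, _fmt(b.purity), _fmt(b.completeness)]))
    p = outdir / "per_bin_distributions.tsv"
    _write_tsv(p, "per-bin purity and completeness (box-plot series)", lines)
    written.append(p)
    return written


def _render_images(
    summaries: Sequence[AssessmentSummary],
    per_bin: dict[str, Sequence[BinMetrics]],
    heatmaps: dict[str, HeatmapMatrix],
    outdir: Path,
) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []

    def scatter(fname, xs, ys, xerr, yerr, labels, xlabel, ylabel):
        fig, ax = plt.subplots(figsize=(5, 4))
        for x, y, ex, ey, lab in zip(xs, ys, xerr, yerr, labels):
            ax.errorbar(x, y, xerr=ex, yerr=ey, fmt="o", capsize=3, label=lab)
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        ax.set_xlim(-0.05, 1.05)
        ax.set_ylim(-0.05, 1.05)
        ax.legend(fontsize=7, loc="best")
        fig.tight_layout()
        path = outdir / fname
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    labels = [s.label for s in summaries]
    scatter("purity_vs_completeness.png",
            [s.truncated_avg_purity for s in summaries],
            [s.avg_completeness for s in summaries],
            [s.std_error_purity for s in summaries],
            [s.std_error_completeness for s in summaries],
            labels, "average purity per bin", "average completeness per genome")
    scatter("purity_vs_completeness_bp.png",
            [s.avg_purity_bp for s in summaries],
            [s.avg_completeness_bp for s in summaries],
            [0] * len(summaries), [0] * len(summaries),
            labels, "average purity per bp", "average completeness per bp")
    scatter("ari_vs_assigned.png",
            [s.ari_bp for s in summaries],
            [s.pct_assigned_bp for s in summaries],
            [0] * len(summaries), [0] * len(summaries),
            labels, "adjusted Rand index (bp)", "fraction of bp assigned")

    for field_name, fname, title in (
        ("purity", "purity_boxplot.png", "purity per bin"),
        ("completeness", "completeness_boxplot.png", "completeness per bin"),
    ):
        fig, ax = plt.subplots(figsize=(5, 4))
        data = [
            [getattr(b, field_name) for b in per_bin[lab]]
            for lab in sorted(per_bin)
        ]
        ax.boxplot(data, tick_labels=sorted(per_bin))
        ax.set_ylabel(title)
        ax.set_ylim(-0.05, 1.05)
        ax.tick_params(axis="x", labelrotation=45)
        fig.tight_layout()
        path = outdir / fname
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    for label in sorted(heatmaps):
        hm = heatmaps[label]
        fig, ax = plt.subplots(figsize=(5, 4))
        with np.errstate(divide="ignore"):
            shown = np.log10(hm.values.astype(float) + 1.0)
        im = ax.imshow(shown, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(hm.col_ids)), hm.col_ids, rotation=90, fontsize=6)
        ax.set_yticks(range(len(hm.row_ids)), hm.row_ids, fontsize=6)
        ax.set_title(f"{label}: bp per (bin, genome), log10 scale", fontsize=8)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        path = outdir / f"heatmap_{label}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written


def render_summary(
    summaries: Sequence[AssessmentSummary],
    per_bin: dict[str, Sequence[BinMetrics]],
    heatmaps: dict[str, HeatmapMatrix],
    outdir: str | os.PathLike,
) -> Path:
    """Write plot data, images, heat-map TSVs and the HTML summary page.

    If the plotting backend fails the images are skipped with a warning
    and the numeric outputs are still written.
    """
    if not summaries:
        raise ValueError("render_summary requires at least one summary")
    outdir = Path(outdir)
    plots_dir = outdir / "plots"
    plots_dir.mkdir(parents=True, exist_ok=True)
    heat_dir = outdir / "heatmaps"
    heat_dir.mkdir(parents=True, exist_ok=True)

    write_plot_data(summaries, per_bin, plots_dir)
    for label in sorted(heatmaps):
        write_heatmap_tsv(heatmaps[label], heat_dir / f"{label}.tsv")

    images: list[Path] = []
    try:
        images = _render_images(summaries, per_bin, heatmaps, plots_dir)
    except Exception as exc:  # pragma: no cover - backend-dependent
        logger.warning("plot rendering unavailable (%s); data TSVs written", exc)

    html_path = outdir / "index.html"
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Binning assessment</title>",
        "<style>body{font-family:sans-serif;margin:2em}"
        "table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:4px 8px;font-size:13px}</style>",
        "</head><body><h1>Genome binning assessment</h1>",
        "<h2>Summary metrics</h2><table><tr>",
    ]
    parts += [f"<th>{escape(c)}</th>" for c in SUMMARY_COLUMNS]
    parts.append("</tr>")
    for s in summaries:
        d = s.as_dict()
        parts.append("<tr>" + "".join(
            f"<td>{escape(str(d[c]) if c == 'label' else _fmt(d[c]))}</td>"
            for c in SUMMARY_COLUMNS) + "</tr>")
    parts.append("</table>")
    parts.append("<h2>Genome recovery</h2><table><tr><th>label</th>"
                 "<th>contamination</th>")
    r_bounds = sorted({r for s in summaries for (_c, r) in s.recovery_counts})
    c_bounds = sorted({c for s in summaries for (c, _r) in s.recovery_counts})
    parts += [f"<th>&gt;{_fmt(r)}</th>" for r in r_bounds]
    parts.append("</tr>")
    for s in summaries:
        for c in c_bounds:
            cells = "".join(
                f"<td>{s.recovery_counts.get((c, r), 0)}</td>"
                for r in r_bounds)
            parts.append(
                f"<tr><td>{escape(s.label)}</td><td>&lt;{_fmt(c)}</td>"
                f"{cells}</tr>")
    parts.append("</table>")
    if images:
        parts.append("<h2>Plots</h2>")
        for img in images:
            data = base64.b64encode(img.read_bytes()).decode("ascii")
            parts.append(
                f"<div><img src='data:image/png;base64,{data}' "
                f"alt='{escape(img.stem)}' style='max-width:640px'></div>")
    parts.append("</body></html>")
    html_path.write_text("".join(parts), encoding="utf-8")
    return html_path
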