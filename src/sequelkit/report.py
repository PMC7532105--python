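"""QC report rendering: the plot catalog A-J, suite selection, sidecars.

Plot codes:

==== =======================================  ==========
code content                                  granularity
==== =======================================  ==========
A    N50 barplot                              all cells
B    L50 barplot                              all cells
C    total-bases barplot                      all cells
D    read-length histograms (one per group)   per cell
E    subreads-per-subedCLR frequency plot     per cell
F    adapters-per-CLR frequency plot          per cell
G    subread-length boxplot (+ N50 diamonds)  all cells
H    subedCLR-length boxplot (+ N50 diamonds) all cells
I    ZOR barplot                              all cells
J    PSR barplot                              all cells
==== =======================================  ==========

Every figure writes a tab-delimited sidecar of exactly the numbers it plots,
so tests and downstream custom plotting can consume data without touching
PDFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from sequelkit.errors import ConfigError
from sequelkit.groups import ReadGroupSet
from sequelkit.stats import QcSummary

SUITES = ("basic", "intermediate", "full")

_PLOT_SETS = {
    (True, "full"): "ABCDEFGHIJ",
    (True, "intermediate"): "ACGHIJ",
    (True, "basic"): "AC",
    (False, "full"): "ABCDGIJ",
    (False, "intermediate"): "ACGIJ",
    (False, "basic"): "AC",
}

#: plots rendered once per SMRTcell rather than once per run
PER_CELL_PLOTS = frozenset("DEF")

_BAR_STATS = {"A": ("n50", "N50"), "B": ("l50", "L50"), "C": ("total_bases", "total bases")}


@dataclass
class PlotSuiteConfig:
    suite: str = "intermediate"
    with_scraps: bool = True
    output_dir: Path = Path(".")
    keep_intermediates: bool = False

    def __post_init__(self) -> None:
        if self.suite not in SUITES:
            raise ConfigError(f"unknown plot suite {self.suite!r}; choose from {SUITES}")
        self.output_dir = Path(self.output_dir)


def resolve_plot_set(config: PlotSuiteConfig) -> set[str]:
    """The plot codes implied by suite choice and scraps availability."""
    return set(_PLOT_SETS[(config.with_scraps, config.suite)])


def _write_sidecar(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("NA" if v is None else str(v) for v in row) + "\n")


def _barplot(code: str, summaries: Sequence[QcSummary], out_dir: Path) -> Path:
    attr, label = _BAR_STATS[code]
    rows = []
    for s in summaries:
        for group, gs in s.group_stats.items():
            rows.append((s.cell_id, group, getattr(gs, attr)))
    groups = list(dict.fromkeys(g for _, g, _ in rows))
    cells = [s.cell_id for s in summaries]
    fig, ax = plt.subplots(figsize=(max(4, 1.5 * len(cells)), 4))
    width = 0.8 / max(1, len(groups))
    x = np.arange(len(cells))
    for gi, group in enumerate(groups):
        heights = [
            next((v for c, g, v in rows if c == cell and g == group), None) or 0
            for cell in cells
        ]
        ax.bar(x + gi * width, heights, width=width, label=group)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(cells, rotation=30, ha="right", fontsize=7)
    ax.set_ylabel(label)
    ax.legend(fontsize=7)
    fig.tight_layout()
    stem = f"{code}_{label.replace(' ', '_').lower()}_barplot"
    pdf = out_dir / f"{stem}.pdf"
    fig.savefig(pdf)
    plt.close(fig)
    _write_sidecar(out_dir / f"{stem}.tsv", ["cell", "group", attr], rows)
    return pdf


def _ratio_plot(code: str, summaries: Sequence[QcSummary], out_dir: Path) -> Path:
    attr = "zor" if code == "I" else "psr"
    rows = [(s.cell_id, getattr(s, attr)) for s in summaries]
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(rows)), 4))
    ax.bar([c for c, _ in rows], [v if v is not None else 0 for _, v in rows], color="steelblue")
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=0.8)
    ax.set_ylabel(attr.upper())
    ax.tick_params(axis="x", rotation=30, labelsize=7)
    fig.tight_layout()
    stem = f"{code}_{attr}_plot"
    pdf = out_dir / f"{stem}.pdf"
    fig.savefig(pdf)
    plt.close(fig)
    _write_sidecar(out_dir / f"{stem}.tsv", ["cell", attr], rows)
    return pdf


def _boxplot(
    code: str,
    summaries: Sequence[QcSummary],
    group_sets: Mapping[str, ReadGroupSet],
    out_dir: Path,
) -> Path:
    group = "subreads" if code == "G" else "subed_clrs"
    label = "subread lengths" if code == "G" else "subedCLR lengths"
    cells, data, n50s = [], [], []
    for s in summaries:
        lengths = getattr(group_sets[s.cell_id], group)
        if lengths is None:
            lengths = []
        cells.append(s.cell_id)
        data.append(lengths)
        gs = s.group_stats.get(group)
        n50s.append(gs.n50 if gs is not None else None)
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(cells)), 4))
    ax.boxplot([d if d else [0] for d in data], tick_labels=cells)
    for i, n50 in enumerate(n50s, start=1):
        if n50 is not None:
            ax.plot(i, n50, marker="D", color="blue", markersize=6)  # N50 as blue diamond
    ax.set_ylabel(label)
    ax.tick_params(axis="x", rotation=30, labelsize=7)
    fig.tight_layout()
    stem = f"{code}_{group}_boxplot"
    pdf = out_dir / f"{stem}.pdf"
    fig.savefig(pdf)
    plt.close(fig)
    rows = []
    for cell, lengths, n50 in zip(cells, data, n50s):
        if lengths:
            arr = np.asarray(lengths)
            q1, med, q3 = np.percentile(arr, [25, 50, 75])
            rows.append((cell, len(lengths), int(arr.min()), q1, med, q3, int(arr.max()), n50))
        else:
            rows.append((cell, 0, None, None, None, None, None, None))
    _write_sidecar(
        out_dir / f"{stem}.tsv",
        ["cell", "n", "min", "q1", "median", "q3", "max", "n50"],
        rows,
    )
    return pdf


def _histograms(cell_id: str, group_set: ReadGroupSet, out_dir: Path) -> Path:
    groups = group_set.groups()
    fig, axes = plt.subplots(len(groups), 1, figsize=(6, 2.5 * len(groups)), squeeze=False)
    rows = []
    for ax, (name, lengths) in zip(axes.ravel(), groups.items()):
        if lengths:
            counts, edges, _ = ax.hist(lengths, bins="auto", color="steelblue")
            for c, lo, hi in zip(counts, edges, edges[1:]):
                rows.append((name, lo, hi, int(c)))
        ax.set_title(name, fontsize=8)
        ax.set_xlabel("read length")
    fig.tight_layout()
    stem = f"D_read_length_histogram_{cell_id}"
    pdf = out_dir / f"{stem}.pdf"
    fig.savefig(pdf)
    plt.close(fig)
    _write_sidecar(out_dir / f"{stem}.tsv", ["group", "bin_left", "bin_right", "count"], rows)
    return pdf


def _frequency_plot(code: str, cell_id: str, group_set: ReadGroupSet, out_dir: Path) -> Path:
    if code == "E":
        spectrum, label = group_set.subreads_per_subed_clr, "subreads_per_subedclr"
    else:
        spectrum, label = group_set.adapters_per_clr or {}, "adapters_per_clr"
    rows = sorted(spectrum.items())
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar([k for k, _ in rows], [v for _, v in rows], color="steelblue")
    ax.set_xlabel(label.replace("_", " "))
    ax.set_ylabel("ZMW count")
    fig.tight_layout()
    stem = f"{code}_{label}_{cell_id}"
    pdf = out_dir / f"{stem}.pdf"
    fig.savefig(pdf)
    plt.close(fig)
    _write_sidecar(out_dir / f"{stem}.tsv", [label, "zmw_count"], rows)
    return pdf


def render_report(
    summaries: Sequence[QcSummary],
    group_sets: Mapping[str, ReadGroupSet],
    config: PlotSuiteConfig,
) -> list[Path]:
    """Render the selected plot suite; returns the PDF paths written.

    Barplots, boxplots and ratio plots show all SMRTcells together (one file
    each); histograms and frequency plots get one file per SMRTcell.
    """
    if not summaries:
        raise ValueError("no SMRTcell summaries to plot")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = sorted(summaries, key=lambda s: s.cell_id)
    codes = sorted(resolve_plot_set(config))
    outputs: list[Path] = []
    for code in codes:
        if code in _BAR_STATS:
            outputs.append(_barplot(code, summaries, out_dir))
        elif code in ("I", "J"):
            outputs.append(_ratio_plot(code, summaries, out_dir))
        elif code in ("G", "H"):
            outputs.append(_boxplot(code, summaries, group_sets, out_dir))
        elif code == "D":
            for s in summaries:
                outputs.append(_histograms(s.cell_id, group_sets[s.cell_id], out_dir))
        elif code in ("E", "F"):
            for s in summaries:
                outputs.append(_frequency_plot(code, s.cell_id, group_sets[s.cell_id], out_dir))
    return outputs
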