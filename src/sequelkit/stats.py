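"""Per-SMRTcell, per-read-group summary statistics.

N50 is the length of the element at which the cumulative sum of the
descending-sorted length list first reaches half the total; L50 is that
element's 1-based rank.  PSR (polymerase-to-subread ratio) is total longest-
subread bases over total subread bases; ZOR (ZMW-occupancy ratio) is the
number of subedCLRs over the number of subreads.  Empty groups report NA
(``None``), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from sequelkit.groups import ReadGroupSet, ZmwBundle, build_read_groups, group_by_zmw, longest_subread_of
from sequelkit.records import SmrtCellFiles, read_records


@dataclass(frozen=True)
class GroupStats:
    """Length statistics of one read group; all-None for an empty group."""

    n_reads: int | None
    total_bases: int | None
    mean_length: float | None
    median_length: float | None
    n50: int | None
    l50: int | None

    @classmethod
    def empty(cls) -> "GroupStats":
        return cls(None, None, None, None, None, None)


def length_stats(lengths: Sequence[int]) -> GroupStats:
    """Compute count, total, mean, median, N50 and L50 of a length list."""
    n = len(lengths)
    if n == 0:
        return GroupStats.empty()
    total = sum(lengths)
    ordered = sorted(lengths, reverse=True)
    if n % 2:
        median = float(ordered[n // 2])
    else:
        median = (ordered[n // 2 - 1] + ordered[n // 2]) / 2.0
    half = total / 2.0
    cumulative = 0
    n50 = ordered[-1]
    l50 = n
    for rank, length in enumerate(ordered, start=1):
        cumulative += length
        if cumulative >= half:
            n50, l50 = length, rank
            break
    return GroupStats(
        n_reads=n,
        total_bases=total,
        mean_length=total / n,
        median_length=median,
        n50=n50,
        l50=l50,
    )


def compute_psr(group_set: ReadGroupSet) -> float | None:
    """Longest-subread bases / subread bases, or None when no subread bases."""
    total = sum(group_set.subreads)
    if total == 0:
        return None
    longest = group_set.longest_subreads
    if longest is None:
        raise ValueError("PSR requires the longest-subreads group")
    return sum(longest) / total


def compute_zor(group_set: ReadGroupSet) -> float | None:
    """subedCLR count / subread count, or None when no subreads.

    Note: as defined this ratio is always <= 1 (each subedCLR holds at least
    one subread).
    """
    n_subreads = len(group_set.subreads)
    if n_subreads == 0:
        return None
    if group_set.subed_clrs is not None:
        n_subed = len(group_set.subed_clrs)
    else:
        n_subed = len(group_set.longest_subreads)  # one entry per subread-bearing ZMW
    return n_subed / n_subreads


@dataclass(frozen=True)
class QcSummary:
    """Per-SMRTcell QC: GroupStats per active group plus PSR and ZOR."""

    cell_id: str
    group_stats: Mapping[str, GroupStats]
    psr: float | None
    zor: float | None


@dataclass(frozen=True)
class QcOptions:
    """QC configuration: whether to use scraps and how many groups."""

    use_scraps: bool = True
    four_groups: bool = True


def summarize_bundles(
    cell_id: str,
    bundles: Mapping[int, ZmwBundle],
    with_scraps: bool,
    four_groups: bool = True,
) -> tuple[QcSummary, ReadGroupSet]:
    group_set = build_read_groups(bundles, with_scraps=with_scraps, four_groups=four_groups)
    stats = {name: length_stats(lengths) for name, lengths in group_set.groups().items()}
    # PSR needs longest-subread totals even when that group is not displayed.
    total_sub = sum(group_set.subreads)
    if total_sub == 0:
        psr = None
    else:
        longest_total = sum(
            longest_subread_of(bundles[h]).identity.length()
            for h in bundles
            if bundles[h].subread_count
        )
        psr = longest_total / total_sub
    zor = compute_zor(group_set)
    return QcSummary(cell_id=cell_id, group_stats=stats, psr=psr, zor=zor), group_set


def summarize_cell(
    cell: SmrtCellFiles,
    options: QcOptions | None = None,
) -> tuple[QcSummary, ReadGroupSet]:
    """QC summary for one SMRTcell, reading its files from disk.

    Returns the summary together with the :class:`ReadGroupSet` so plotting
    can reuse the length lists.  Only normal scraps enter the QC groups.
    """
    options = options or QcOptions()
    use_scraps = options.use_scraps and cell.has_scraps
    subreads = read_records(cell.subreads_path, "subreads", coordinates_only=True)
    scraps = None
    if use_scraps:
        scraps = read_records(cell.scraps_path, "scraps", coordinates_only=True)
    bundles = group_by_zmw(subreads, scraps, normal_only=True)
    return summarize_bundles(
        cell.cell_id,
        bundles,
        with_scraps=use_scraps,
        four_groups=options.four_groups if use_scraps else False,
    )


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.4f}" if value < 10 else f"{value:.1f}"
    return str(value)


def write_summary_table(summaries: Sequence[QcSummary], path) -> None:
    """Tab-delimited table, one row per (SMRTcell, read group).

    PSR and ZOR are cross-group ratios and appear once per cell, on its
    ``subreads`` row.
    """
    columns = ["cell", "group", "nReads", "totalBases", "mean", "median", "N50", "L50", "PSR", "ZOR"]
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for summary in summaries:
            for group, gs in summary.group_stats.items():
                psr = summary.psr if group == "subreads" else None
                zor = summary.zor if group == "subreads" else None
                row = [
                    summary.cell_id,
                    group,
                    _fmt(gs.n_reads),
                    _fmt(gs.total_bases),
                    "NA" if gs.mean_length is None else f"{gs.mean_length:.1f}",
                    "NA" if gs.median_length is None else f"{gs.median_length:.1f}",
                    _fmt(gs.n50),
                    _fmt(gs.l50),
                    _fmt(psr),
                    _fmt(zor),
                ]
                fh.write("\t".join(row) + "\n")
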