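"""The Read Filtering tool: minimum CLR length, full-pass, normal-adapter.

CLR length counts *all provided scraps* (no normal-only restriction), so
running the scraps-level criteria in a first pass and the length threshold
in a second changes which scraps count toward CLR length — the documented
two-run workflow.

A ZMW "has a complete pass" when at least one of its subreads is flanked by
adapter scraps on both sides (an adapter ending at the subread's q_start and
another starting at its q_end): one full traversal of the SMRTBell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from sequelkit.errors import ConfigError
from sequelkit.groups import ZmwBundle, group_by_zmw
from sequelkit.records import ScrapRecord, SmrtCellFiles, read_records, write_records


@dataclass
class FilterConfig:
    min_clr_length: int | None = None
    require_full_pass: bool = False
    normal_adapters_only: bool = False
    emit_binary: bool = False

    def __post_init__(self) -> None:
        if (
            self.min_clr_length is None
            and not self.require_full_pass
            and not self.normal_adapters_only
        ):
            raise ConfigError("at least one filtering criterion must be enabled")
        if self.min_clr_length is not None and self.min_clr_length < 0:
            raise ConfigError(f"min_clr_length must be >= 0, got {self.min_clr_length}")


def filter_min_clr_length(bundles: Mapping[int, ZmwBundle], threshold: int) -> set[int]:
    """Holes whose CLR length (subreads + all provided scraps) is >= threshold."""
    if threshold < 0:
        raise ConfigError(f"negative threshold: {threshold}")
    return {hole for hole, b in bundles.items() if b.clr_length >= threshold}


def zmw_has_full_pass(bundle: ZmwBundle) -> bool:
    adapter_starts = {s.identity.q_start for s in bundle.scraps if s.region_type == "A"}
    adapter_ends = {s.identity.q_end for s in bundle.scraps if s.region_type == "A"}
    return any(
        r.identity.q_start in adapter_ends and r.identity.q_end in adapter_starts
        for r in bundle.subreads
    )


def filter_full_pass(bundles: Mapping[int, ZmwBundle]) -> list[ScrapRecord]:
    """Scraps of ZMWs with >= 1 adapter-flanked subread, in bundle order.

    Subreads are untouched by this criterion; scraps of failing ZMWs are
    removed wholesale.
    """
    surviving: list[ScrapRecord] = []
    for hole in sorted(bundles):
        bundle = bundles[hole]
        if zmw_has_full_pass(bundle):
            surviving.extend(bundle.scraps)
    return surviving


def filter_normal_adapters(scraps: list[ScrapRecord]) -> list[ScrapRecord]:
    """Keep exactly the scraps with ZMW class 'N' and region type 'A'."""
    return [s for s in scraps if s.zmw_class == "N" and s.region_type == "A"]


def _output_paths(cell: SmrtCellFiles, out_dir: Path, emit_binary: bool) -> tuple[Path, Path]:
    ext = "bam" if emit_binary else "sam"
    return (
        out_dir / f"{cell.cell_id}.filtered.subreads.{ext}",
        out_dir / f"{cell.cell_id}.filtered.scraps.{ext}",
    )


def run_filter(
    cell: SmrtCellFiles,
    config: FilterConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Apply the enabled criteria (they compose as an intersection).

    The length criterion restricts *both* outputs to surviving holes; the
    full-pass and normal-adapter criteria restrict the scraps output only.
    Outputs preserve input order and record content.
    """
    if not cell.has_scraps:
        raise ConfigError("the filtering tool requires both subreads and scraps files")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subreads = read_records(cell.subreads_path, "subreads")
    scraps = read_records(cell.scraps_path, "scraps")
    bundles = group_by_zmw(subreads, scraps, normal_only=False)

    if config.min_clr_length is not None:
        surviving_holes = filter_min_clr_length(bundles, config.min_clr_length)
    else:
        surviving_holes = set(bundles)

    out_subreads = [r for r in subreads if r.identity.hole in surviving_holes]
    out_scraps = [r for r in scraps if r.identity.hole in surviving_holes]
    if config.require_full_pass:
        passing = {hole for hole, b in bundles.items() if zmw_has_full_pass(b)}
        out_scraps = [r for r in out_scraps if r.identity.hole in passing]
    if config.normal_adapters_only:
        out_scraps = filter_normal_adapters(out_scraps)

    sub_path, scraps_path = _output_paths(cell, out_dir, config.emit_binary)
    return {
        "subreads": write_records(out_subreads, sub_path, config.emit_binary),
        "scraps": write_records(out_scraps, scraps_path, config.emit_binary),
    }
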