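"""The Read Subsampling tool: longest subread per CLR and/or random CLRs.

Random selection is ZMW-atomic: a ZMW is selected or not, and every subread
(and, when provided, every scrap) of a selected ZMW is emitted.  Outputs are
exact sub-multisets of the inputs, in input order.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from pathlib import Path

from sequelkit.errors import ConfigError
from sequelkit.groups import group_by_zmw, longest_subread_of
from sequelkit.records import SmrtCellFiles, read_records, write_records

log = logging.getLogger(__name__)


@dataclass
class SubsampleConfig:
    longest: bool = False
    random_clrs: bool = False
    fraction: float | None = None
    n_zmws: int | None = None
    seed: int = 0
    emit_binary: bool = False

    def __post_init__(self) -> None:
        if not (self.longest or self.random_clrs):
            raise ConfigError("at least one of longest/random_clrs must be set")
        if self.random_clrs:
            if self.fraction is None and self.n_zmws is None:
                raise ConfigError("random CLR selection needs --fraction or --n-zmws")
            if self.fraction is not None and not (0.0 < self.fraction <= 1.0):
                raise ConfigError(f"fraction must be in (0, 1], got {self.fraction}")
            if self.n_zmws is not None and self.n_zmws < 1:
                raise ConfigError(f"n_zmws must be >= 1, got {self.n_zmws}")
        elif self.fraction is not None:
            raise ConfigError("fraction is only valid with random CLR selection")


def _output_paths(cell: SmrtCellFiles, out_dir: Path, emit_binary: bool) -> tuple[Path, Path]:
    ext = "bam" if emit_binary else "sam"
    return (
        out_dir / f"{cell.cell_id}.subsampled.subreads.{ext}",
        out_dir / f"{cell.cell_id}.subsampled.scraps.{ext}",
    )


def select_random_holes(holes: list[int], fraction: float | None, n_zmws: int | None, seed: int) -> set[int]:
    """Choose ZMWs uniformly without replacement with a seeded generator.

    With ``fraction``, the count is floor(fraction * N) with a floor of 1
    (for N >= 1); ``n_zmws`` requests an absolute count (capped at N).
    """
    if not holes:
        return set()
    if n_zmws is not None:
        k = min(n_zmws, len(holes))
    else:
        k = max(1, math.floor(fraction * len(holes)))
    rng = random.Random(seed)
    return set(rng.sample(sorted(holes), k))


def run_subsample(
    cell: SmrtCellFiles,
    config: SubsampleConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Subsample one SMRTcell; returns the written output paths by kind."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subreads = read_records(cell.subreads_path, "subreads")
    scraps = read_records(cell.scraps_path, "scraps") if cell.has_scraps else None

    if config.longest and not config.random_clrs and scraps is not None:
        log.warning(
            "%s: scraps provided with longest-only subsampling (not recommended); "
            "the scraps output is an identity copy",
            cell.cell_id,
        )

    out_subreads = subreads
    out_scraps = scraps
    if config.random_clrs:
        holes = sorted({r.identity.hole for r in subreads} | (
            {r.identity.hole for r in scraps} if scraps is not None else set()
        ))
        selected = select_random_holes(holes, config.fraction, config.n_zmws, config.seed)
        out_subreads = [r for r in out_subreads if r.identity.hole in selected]
        if out_scraps is not None:
            out_scraps = [r for r in out_scraps if r.identity.hole in selected]
    if config.longest:
        bundles = group_by_zmw(out_subreads)
        keep = {
            id(longest_subread_of(b)) for b in bundles.values() if b.subread_count
        }
        out_subreads = [r for r in out_subreads if id(r) in keep]
        # scraps (if any) pass through unchanged in longest mode

    sub_path, scraps_path = _output_paths(cell, out_dir, config.emit_binary)
    outputs = {"subreads": write_records(out_subreads, sub_path, config.emit_binary)}
    if out_scraps is not None:
        outputs["scraps"] = write_records(out_scraps, scraps_path, config.emit_binary)
    return outputs


def subsample_longest(cell: SmrtCellFiles, out_dir: str | Path, emit_binary: bool = False) -> dict[str, Path]:
    """Keep exactly the longest subread of every subread-bearing ZMW."""
    return run_subsample(cell, SubsampleConfig(longest=True, emit_binary=emit_binary), out_dir)


def subsample_random(
    cell: SmrtCellFiles,
    fraction: float,
    seed: int,
    out_dir: str | Path,
    emit_binary: bool = False,
) -> dict[str, Path]:
    """Keep all records of a random fraction of ZMWs (seed-deterministic)."""
    return run_subsample(
        cell,
        SubsampleConfig(random_clrs=True, fraction=fraction, seed=seed, emit_binary=emit_binary),
        out_dir,
    )
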