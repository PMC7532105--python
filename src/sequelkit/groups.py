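"""ZMW bundling, CLR reconstruction and the four QC read groups.

A CLR (polymerase read) is never materialised as sequence: its length is the
sum of the lengths of all member segments (subreads plus whatever scraps were
provided), which honours "all provided scraps" exactly even when segments of
the physical read are missing from the inputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from sequelkit.errors import ConfigError, IntegrityError
from sequelkit.records import Record, ScrapRecord, SubreadRecord


@dataclass
class ZmwBundle:
    """All records sharing one ZMW hole number."""

    hole: int
    subreads: list[SubreadRecord] = field(default_factory=list)
    scraps: list[ScrapRecord] = field(default_factory=list)

    @property
    def subread_count(self) -> int:
        return len(self.subreads)

    @property
    def adapter_count(self) -> int:
        return sum(1 for s in self.scraps if s.region_type == "A")

    @property
    def clr_length(self) -> int:
        return sum(r.identity.length() for r in self.subreads) + sum(
            r.identity.length() for r in self.scraps
        )

    def members(self) -> list[Record]:
        return list(self.subreads) + list(self.scraps)

    def validate_segments(self) -> None:
        """Reject overlapping segments: the CLR is a linear coordinate system."""
        spans = sorted(
            (r.identity.q_start, r.identity.q_end) for r in self.members()
        )
        for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise IntegrityError(
                    f"ZMW {self.hole}: overlapping segments "
                    f"[{s0},{e0}) and [{s1},{_e1})"
                )


def group_by_zmw(
    subreads: Sequence[SubreadRecord],
    scraps: Sequence[ScrapRecord] | None = None,
    normal_only: bool = False,
) -> dict[int, ZmwBundle]:
    """Group records into per-hole bundles.

    With ``normal_only``, scraps whose ZMW classification is not ``'N'`` are
    excluded before bundling (QC uses only normal scraps).  Overlapping
    segments within a ZMW raise :class:`IntegrityError`.
    """
    bundles: dict[int, ZmwBundle] = {}
    for rec in subreads:
        bundles.setdefault(rec.identity.hole, ZmwBundle(rec.identity.hole)).subreads.append(rec)
    if scraps is not None:
        for rec in scraps:
            if normal_only and rec.zmw_class != "N":
                continue
            bundles.setdefault(rec.identity.hole, ZmwBundle(rec.identity.hole)).scraps.append(rec)
    for bundle in bundles.values():
        bundle.validate_segments()
    return bundles


def longest_subread_of(bundle: ZmwBundle) -> SubreadRecord:
    """The longest member subread; ties broken by smallest ``q_start``."""
    if not bundle.subreads:
        raise ValueError(f"ZMW {bundle.hole} has no subreads")
    return max(bundle.subreads, key=lambda r: (r.identity.length(), -r.identity.q_start))


@dataclass
class ReadGroupSet:
    """Per-SMRTcell length lists for the active read groups.

    ``clrs``/``subed_clrs`` are ``None`` when the group is inactive for the
    chosen configuration (e.g. no scraps provided).  Spectra are counters over
    per-ZMW counts: subreads per subedCLR, and adapters per CLR (scraps mode
    only).
    """

    subreads: list[int]
    longest_subreads: list[int] | None = None
    clrs: list[int] | None = None
    subed_clrs: list[int] | None = None
    subreads_per_subed_clr: Counter = field(default_factory=Counter)
    adapters_per_clr: Counter | None = None

    def groups(self) -> dict[str, list[int]]:
        """Active group name -> length list, in the canonical order."""
        out: dict[str, list[int]] = {"subreads": self.subreads}
        if self.longest_subreads is not None:
            out["longest_subreads"] = self.longest_subreads
        if self.clrs is not None:
            out["clrs"] = self.clrs
        if self.subed_clrs is not None:
            out["subed_clrs"] = self.subed_clrs
        return out


def build_read_groups(
    bundles: Mapping[int, ZmwBundle],
    with_scraps: bool,
    four_groups: bool = True,
) -> ReadGroupSet:
    """Build the read groups from per-ZMW bundles.

    With scraps and ``four_groups``: subreads, longest subreads, CLRs and
    subedCLRs.  With scraps but two groups: subreads and subedCLRs.  Without
    scraps: subreads and longest subreads (``four_groups`` is then invalid).
    """
    if four_groups and not with_scraps:
        raise ConfigError("four read groups require scraps files")

    holes = sorted(bundles)
    subreads: list[int] = []
    longest: list[int] = []
    clrs: list[int] = []
    subed: list[int] = []
    sub_spectrum: Counter = Counter()
    adapter_spectrum: Counter = Counter()
    for hole in holes:
        b = bundles[hole]
        lengths = [r.identity.length() for r in b.subreads]
        subreads.extend(lengths)
        if lengths:
            longest.append(longest_subread_of(b).identity.length())
            sub_spectrum[len(lengths)] += 1
        if with_scraps:
            clrs.append(b.clr_length)
            adapter_spectrum[b.adapter_count] += 1
            if lengths:
                subed.append(b.clr_length)

    if not with_scraps:
        return ReadGroupSet(
            subreads=subreads,
            longest_subreads=longest,
            subreads_per_subed_clr=sub_spectrum,
        )
    if four_groups:
        return ReadGroupSet(
            subreads=subreads,
            longest_subreads=longest,
            clrs=clrs,
            subed_clrs=subed,
            subreads_per_subed_clr=sub_spectrum,
            adapters_per_clr=adapter_spectrum,
        )
    return ReadGroupSet(
        subreads=subreads,
        subed_clrs=subed,
        subreads_per_subed_clr=sub_spectrum,
        adapters_per_clr=adapter_spectrum,
    )


def dump_bundles(bundles: Mapping[int, ZmwBundle], path) -> None:
    """Tab-delimited per-ZMW summary: hole, subread_count, adapter_count, clr_length."""
    with open(path, "w") as fh:
        fh.write("hole\tsubread_count\tadapter_count\tclr_length\n")
        for hole in sorted(bundles):
            b = bundles[hole]
            fh.write(f"{hole}\t{b.subread_count}\t{b.adapter_count}\t{b.clr_length}\n")
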