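"""Deterministic generator of paired subreads/scraps fixtures.

Each simulated ZMW is laid out as a tiled polymerase read:

    [barcode?] [adapter?] subread (adapter subread)* [adapter?] [lq?]

Consecutive segments abut exactly (``q_end == next q_start``), so the
segment lengths always sum to the CLR length.  Interior adapters between
consecutive subreads are always present; the flanking adapters are each
dropped with ``p_missing_flank`` to create ZMWs with and without complete
passes.  A ZMW is, with ``p_scraps_only_zmw``, a single low-quality scrap
and nothing else.  All scraps of one ZMW share a ZMW classification, drawn
non-normal with ``p_nonnormal_class``.

``generate_cell`` writes the SAM pair plus a tab-delimited truth table from
which every QC statistic, subsampling result and filtering decision is
recomputable in closed form; ``truth_qc`` is that recomputation — it never
touches the files or the bundling code, making it an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sequelkit.records import (
    ReadIdentity,
    ScrapRecord,
    SmrtCellFiles,
    SubreadRecord,
    write_records,
)
from sequelkit.stats import GroupStats, QcSummary

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    n_zmws: int = 50
    seed: int = 0
    movie: str = ""
    mu_log: float = 8.5            # log-bases; exp(8.5) ~ 4900 b inserts
    sigma_log: float = 0.45
    mean_passes: float = 2.0       # geometric, support {1, 2, ...}
    adapter_length: int = 45
    p_scraps_only_zmw: float = 0.05
    p_nonnormal_class: float = 0.1
    class_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)  # C, M, S
    p_barcode: float = 0.15
    p_lq: float = 0.2
    p_missing_flank: float = 0.3   # per flanking adapter
    with_scraps: bool = True
    random_sequences: bool = True  # False: homopolymer fill (fast, still valid)

    @property
    def movie_name(self) -> str:
        return self.movie or f"m54006_{self.seed % 1_000_000:06d}_{self.n_zmws % 1_000_000:06d}"


@dataclass
class TruthRow:
    """Everything the generator knows about one ZMW."""

    hole: int
    subread_lengths: list[int]
    scrap_lengths: list[int]
    scrap_classes: list[str]
    scrap_types: list[str]
    has_full_pass: bool

    @property
    def clr_length(self) -> int:
        return sum(self.subread_lengths) + sum(self.scrap_lengths)

    @property
    def normal_scrap_total(self) -> int:
        return sum(l for l, c in zip(self.scrap_lengths, self.scrap_classes) if c == "N")

    @property
    def adapter_count(self) -> int:
        return sum(1 for t in self.scrap_types if t == "A")


@dataclass
class TruthTable:
    movie: str
    rows: list[TruthRow] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(
                "hole\tsubread_lengths\tscrap_lengths\tscrap_classes\tscrap_types\thas_full_pass\n"
            )
            for r in self.rows:
                fh.write(
                    "\t".join(
                        [
                            str(r.hole),
                            ";".join(map(str, r.subread_lengths)),
                            ";".join(map(str, r.scrap_lengths)),
                            ";".join(r.scrap_classes),
                            ";".join(r.scrap_types),
                            "1" if r.has_full_pass else "0",
                        ]
                    )
                    + "\n"
                )
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, movie: str = "") -> "TruthTable":
        rows = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                hole, subs, slens, sclasses, stypes, fp = line.rstrip("\n").split("\t")
                rows.append(
                    TruthRow(
                        hole=int(hole),
                        subread_lengths=[int(x) for x in subs.split(";") if x],
                        scrap_lengths=[int(x) for x in slens.split(";") if x],
                        scrap_classes=[c for c in sclasses.split(";") if c],
                        scrap_types=[t for t in stypes.split(";") if t],
                        has_full_pass=fp == "1",
                    )
                )
        return cls(movie=movie, rows=rows)


def _random_seq(rng: np.random.Generator, length: int, random_sequences: bool) -> str:
    if not random_sequences:
        return "A" * length
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _subread_length(rng: np.random.Generator, spec: FixtureSpec) -> int:
    return max(50, int(round(rng.lognormal(spec.mu_log, spec.sigma_log))))


def _simulate_zmw(rng: np.random.Generator, spec: FixtureSpec, hole: int):
    """Returns (subread segments, scrap segments, truth row); segments are
    (q_start, q_end[, class, type]) tuples tiling [0, clr_length)."""
    if rng.random() < spec.p_scraps_only_zmw:
        zmw_class = _draw_class(rng, spec)
        length = max(100, int(round(rng.lognormal(spec.mu_log, spec.sigma_log))))
        row = TruthRow(hole, [], [length], [zmw_class], ["L"], has_full_pass=False)
        return [], [(0, length, zmw_class, "L")], row

    zmw_class = _draw_class(rng, spec)
    n_passes = int(rng.geometric(1.0 / spec.mean_passes))
    sub_segments: list[tuple[int, int]] = []
    scrap_segments: list[tuple[int, int, str, str]] = []
    pos = 0
    if rng.random() < spec.p_barcode:
        blen = int(rng.integers(10, 31))
        scrap_segments.append((pos, pos + blen, zmw_class, "B"))
        pos += blen
    leading = rng.random() >= spec.p_missing_flank
    if leading:
        scrap_segments.append((pos, pos + spec.adapter_length, zmw_class, "A"))
        pos += spec.adapter_length
    for i in range(n_passes):
        if i > 0:  # interior adapters always present
            scrap_segments.append((pos, pos + spec.adapter_length, zmw_class, "A"))
            pos += spec.adapter_length
        slen = _subread_length(rng, spec)
        sub_segments.append((pos, pos + slen))
        pos += slen
    trailing = rng.random() >= spec.p_missing_flank
    if trailing:
        scrap_segments.append((pos, pos + spec.adapter_length, zmw_class, "A"))
        pos += spec.adapter_length
    if rng.random() < spec.p_lq:
        llen = int(rng.integers(50, 501))
        scrap_segments.append((pos, pos + llen, zmw_class, "L"))
        pos += llen

    # a complete pass needs a subread with adapters on both sides
    if n_passes >= 2:
        full_pass = True  # an interior subread exists or both flanks of some subread are interior adapters
        if n_passes == 2:
            full_pass = leading or trailing
        has = full_pass
    else:
        has = leading and trailing
    scrap_segments.sort()
    row = TruthRow(
        hole,
        [e - s for s, e in sub_segments],
        [e - s for s, e, _, _ in scrap_segments],
        [c for _, _, c, _ in scrap_segments],
        [t for _, _, _, t in scrap_segments],
        has_full_pass=has,
    )
    return sub_segments, scrap_segments, row


def _draw_class(rng: np.random.Generator, spec: FixtureSpec) -> str:
    if rng.random() < spec.p_nonnormal_class:
        w = np.asarray(spec.class_weights, dtype=float)
        return "CMS"[int(rng.choice(3, p=w / w.sum()))]
    return "N"


def generate_cell(spec: FixtureSpec, out_dir: str | Path) -> tuple[SmrtCellFiles, TruthTable]:
    """Write one SMRTcell's subreads (+ scraps) SAM files and truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    movie = spec.movie_name
    truth = TruthTable(movie=movie)
    subreads: list[SubreadRecord] = []
    scraps: list[ScrapRecord] = []
    for hole in range(spec.n_zmws):
        sub_segments, scrap_segments, row = _simulate_zmw(rng, spec, hole)
        truth.rows.append(row)
        for qs, qe in sub_segments:
            subreads.append(
                SubreadRecord(
                    identity=ReadIdentity(movie, hole, qs, qe),
                    sequence=_random_seq(rng, qe - qs, spec.random_sequences),
                )
            )
        for qs, qe, zmw_class, region_type in scrap_segments:
            scraps.append(
                ScrapRecord(
                    identity=ReadIdentity(movie, hole, qs, qe),
                    zmw_class=zmw_class,
                    region_type=region_type,
                    sequence=_random_seq(rng, qe - qs, spec.random_sequences),
                )
            )
    sub_path = out_dir / f"{movie}.subreads.sam"
    write_records(subreads, sub_path)
    scraps_path = None
    if spec.with_scraps:
        scraps_path = out_dir / f"{movie}.scraps.sam"
        write_records(scraps, scraps_path)
    truth.to_tsv(out_dir / f"{movie}.truth.tsv")
    cell = SmrtCellFiles(subreads_path=sub_path, scraps_path=scraps_path, cell_id=movie)
    return cell, truth


# ---------------------------------------------------------------------------
# Independent QC oracle
# ---------------------------------------------------------------------------

def _brute_stats(lengths: list[int]) -> GroupStats:
    """First-principles stats: explicit prefix scan, no shared code paths."""
    if not lengths:
        return GroupStats(None, None, None, None, None, None)
    ordered = sorted(lengths)[::-1]
    total = 0
    for x in ordered:
        total += x
    running = 0
    n50 = l50 = None
    for i, x in enumerate(ordered):
        running += x
        if 2 * running >= total:
            n50, l50 = x, i + 1
            break
    n = len(ordered)
    mid = n // 2
    median = float(ordered[mid]) if n % 2 else (ordered[mid - 1] + ordered[mid]) / 2.0
    return GroupStats(n, total, total / n, median, n50, l50)


def truth_qc(truth: TruthTable, with_scraps: bool = True, four_groups: bool = True) -> QcSummary:
    """Recompute the QC summary straight from the truth table.

    Mirrors the normal-only rule: non-normal scraps never enter the groups,
    so a scraps-only ZMW with a non-normal class contributes nothing.
    """
    subread_lengths: list[int] = []
    longest: list[int] = []
    clrs: list[int] = []
    subed: list[int] = []
    for row in truth.rows:
        subread_lengths.extend(row.subread_lengths)
        qc_len = sum(row.subread_lengths) + (row.normal_scrap_total if with_scraps else 0)
        has_normal_scrap = any(c == "N" for c in row.scrap_classes)
        if row.subread_lengths:
            longest.append(max(row.subread_lengths))
        if with_scraps and (row.subread_lengths or has_normal_scrap):
            clrs.append(qc_len)
            if row.subread_lengths:
                subed.append(qc_len)

    if with_scraps and four_groups:
        groups = {
            "subreads": subread_lengths,
            "longest_subreads": longest,
            "clrs": clrs,
            "subed_clrs": subed,
        }
    elif with_scraps:
        groups = {"subreads": subread_lengths, "subed_clrs": subed}
    else:
        groups = {"subreads": subread_lengths, "longest_subreads": longest}

    stats = {name: _brute_stats(lengths) for name, lengths in groups.items()}
    total_sub = sum(subread_lengths)
    psr = (sum(longest) / total_sub) if total_sub else None
    zor = (len(longest) / len(subread_lengths)) if subread_lengths else None
    return QcSummary(cell_id=truth.movie, group_stats=stats, psr=psr, zor=zor)
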