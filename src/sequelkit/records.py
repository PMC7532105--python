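"""Data model and SAM/BAM I/O for per-SMRTcell subreads and scraps files.

PacBio raw reads are unaligned; files carry a header but no reference
sequences.  Scraps records additionally carry two one-character tags:

* ``sz`` — ZMW classification: ``N`` (normal), ``C`` (control),
  ``M`` (malformed) or ``S`` (sentinel);
* ``sc`` — scrap region type: ``A`` (adapter), ``B`` (barcode),
  ``L`` (low-quality region) or ``F`` (filtered).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import pysam

from sequelkit.errors import AnnotationError, IntegrityError, ReadNameError

ZMW_CLASSES = frozenset("NCMS")
REGION_TYPES = frozenset("ABLF")

ZMW_CLASS_TAG = "sz"
REGION_TYPE_TAG = "sc"

_NAME_RE = re.compile(r"^(?P<movie>[^/]+)/(?P<hole>\d+)/(?P<qs>\d+)_(?P<qe>\d+)$")


@dataclass(frozen=True, order=True)
class ReadIdentity:
    """Parsed PacBio read name: movie, ZMW hole and CLR coordinates.

    Coordinates are 0-based, half-open on the polymerase read, so
    ``length() == q_end - q_start``.
    """

    movie: str
    hole: int
    q_start: int
    q_end: int

    def __post_init__(self) -> None:
        if self.hole < 0:
            raise ReadNameError(f"negative hole number: {self.hole}")
        if self.q_start < 0:
            raise ReadNameError(f"negative q_start: {self.q_start}")
        if self.q_end <= self.q_start:
            raise ReadNameError(
                f"zero- or negative-length read: q_start={self.q_start}, q_end={self.q_end}"
            )

    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def name(self) -> str:
        return f"{self.movie}/{self.hole}/{self.q_start}_{self.q_end}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_read_name(name: str) -> ReadIdentity:
    """Parse a ``movie/hole/qStart_qEnd`` read name into a :class:`ReadIdentity`.

    Raises :class:`ReadNameError` naming the offending field on any
    deviation from the convention.
    """
    if not name:
        raise ReadNameError("empty read name")
    m = _NAME_RE.match(name)
    if m is None:
        parts = name.split("/")
        if len(parts) != 3:
            raise ReadNameError(
                f"read name {name!r}: expected 3 '/'-separated fields, got {len(parts)}"
            )
        if not parts[1].isdigit():
            raise ReadNameError(f"read name {name!r}: hole number {parts[1]!r} is not an integer")
        raise ReadNameError(
            f"read name {name!r}: coordinates {parts[2]!r} are not 'qStart_qEnd' integers"
        )
    try:
        return ReadIdentity(
            movie=m.group("movie"),
            hole=int(m.group("hole")),
            q_start=int(m.group("qs")),
            q_end=int(m.group("qe")),
        )
    except ReadNameError as exc:
        raise ReadNameError(f"read name {name!r}: {exc}") from None


@dataclass
class SubreadRecord:
    """One subread: an insert-derived segment of a CLR."""

    identity: ReadIdentity
    sequence: str | None = None
    qualities: str | None = None
    extra_tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.identity.length():
            raise IntegrityError(
                f"{self.identity.name}: sequence length {len(self.sequence)} "
                f"!= coordinate length {self.identity.length()}"
            )

    @property
    def length(self) -> int:
        return self.identity.length()


@dataclass
class ScrapRecord:
    """One scrap: a non-subread CLR segment with its two annotations."""

    identity: ReadIdentity
    zmw_class: str
    region_type: str
    sequence: str | None = None
    qualities: str | None = None
    extra_tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zmw_class not in ZMW_CLASSES:
            raise AnnotationError(
                f"{self.identity.name}: invalid ZMW classification {self.zmw_class!r}"
            )
        if self.region_type not in REGION_TYPES:
            raise AnnotationError(
                f"{self.identity.name}: invalid scrap region type {self.region_type!r}"
            )
        if self.sequence is not None and len(self.sequence) != self.identity.length():
            raise IntegrityError(
                f"{self.identity.name}: sequence length {len(self.sequence)} "
                f"!= coordinate length {self.identity.length()}"
            )

    @property
    def length(self) -> int:
        return self.identity.length()


Record = Union[SubreadRecord, ScrapRecord]


@dataclass
class SmrtCellFiles:
    """Paths to the input files of one SMRTcell (scraps optional)."""

    subreads_path: Path
    scraps_path: Path | None = None
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.subreads_path = Path(self.subreads_path)
        if self.scraps_path is not None:
            self.scraps_path = Path(self.scraps_path)
        if not self.cell_id:
            stem = self.subreads_path.name
            for suffix in (".bam", ".sam", ".subreads"):
                if stem.endswith(suffix):
                    stem = stem[: -len(suffix)]
            self.cell_id = stem

    @property
    def has_scraps(self) -> bool:
        return self.scraps_path is not None


def _records_from_alignments(
    alignments: Iterator[pysam.AlignedSegment],
    kind: str,
    coordinates_only: bool,
    path: Path,
) -> Iterator[Record]:
    movie: str | None = None
    for aln in alignments:
        identity = parse_read_name(aln.query_name)
        if movie is None:
            movie = identity.movie
        elif identity.movie != movie:
            raise IntegrityError(
                f"{path}: mixed movies in one file ({movie!r} vs {identity.movie!r})"
            )
        seq = None if coordinates_only else (aln.query_sequence or None)
        qual = None
        if not coordinates_only and aln.query_qualities is not None:
            qual = pysam.qualities_to_qualitystring(aln.query_qualities)
        tags = {tag: value for tag, value in aln.get_tags()}
        if kind == "scraps":
            zmw_class = tags.pop(ZMW_CLASS_TAG, None)
            region_type = tags.pop(REGION_TYPE_TAG, None)
            if zmw_class is None:
                raise AnnotationError(
                    f"{path}: scraps record {identity.name} lacks the "
                    f"'{ZMW_CLASS_TAG}' ZMW-classification tag"
                )
            if region_type is None:
                raise AnnotationError(
                    f"{path}: scraps record {identity.name} lacks the "
                    f"'{REGION_TYPE_TAG}' region-type tag"
                )
            yield ScrapRecord(
                identity=identity,
                zmw_class=zmw_class,
                region_type=region_type,
                sequence=seq,
                qualities=qual,
                extra_tags=tags,
            )
        else:
            yield SubreadRecord(identity=identity, sequence=seq, qualities=qual, extra_tags=tags)


def read_records(
    path: str | Path,
    kind: str = "subreads",
    coordinates_only: bool = False,
) -> list[Record]:
    """Read all records of a subreads or scraps file, in file order.

    Accepts SAM text or BAM (auto-detected by htslib).  With
    ``coordinates_only`` sequences and qualities are dropped — mirroring the
    cheap coordinate-extraction pass — but identities, annotations and tags
    are retained.
    """
    if kind not in ("subreads", "scraps"):
        raise ValueError(f"kind must be 'subreads' or 'scraps', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    save = pysam.set_verbosity(0)  # silence htslib "no index" chatter
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            # until_eof also covers headerless/unaligned files without an index
            alignments = fh.fetch(until_eof=True)
            return list(_records_from_alignments(alignments, kind, coordinates_only, path))
    finally:
        pysam.set_verbosity(save)


def _build_header(movie: str | None) -> pysam.AlignmentHeader:
    header: dict = {"HD": {"VN": "1.5", "SO": "unknown"}}
    if movie is not None:
        header["RG"] = [{"ID": movie, "PL": "PACBIO", "PU": movie}]
    return pysam.AlignmentHeader.from_dict(header)


def write_records(
    records: Sequence[Record],
    path: str | Path,
    emit_binary: bool = False,
) -> Path:
    """Write records to ``path`` as SAM text (or BAM with ``emit_binary``).

    All records must share one movie; re-reading the output yields an equal
    record sequence (identity, sequence, annotations, preserved tags).
    """
    path = Path(path)
    movies = {rec.identity.movie for rec in records}
    if len(movies) > 1:
        raise IntegrityError(f"mixed movies in one output file: {sorted(movies)}")
    for rec in records:
        if rec.sequence is None:
            raise IntegrityError(
                f"record {rec.identity.name} has no sequence; "
                "coordinates-only records cannot be written"
            )
    movie = next(iter(movies)) if movies else None
    header = _build_header(movie)
    mode = "wb" if emit_binary else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for rec in records:
            aln = pysam.AlignedSegment(header)
            aln.query_name = rec.identity.name
            aln.flag = 4  # unmapped
            aln.query_sequence = rec.sequence
            if rec.qualities is not None:
                aln.query_qualities = pysam.qualitystring_to_array(rec.qualities)
            tags = []
            if isinstance(rec, ScrapRecord):
                tags.append((ZMW_CLASS_TAG, rec.zmw_class, "A"))
                tags.append((REGION_TYPE_TAG, rec.region_type, "A"))
            for tag, value in rec.extra_tags.items():
                tags.append((tag, value))
            aln.set_tags(tags)
            out.write(aln)
    return path


def iter_cells(
    subreads_paths: Iterable[str | Path],
    scraps_paths: Iterable[str | Path] | None = None,
) -> list[SmrtCellFiles]:
    """Pair subreads files with scraps files by movie name.

    Movie names are read from the first record of each file; a scraps file
    whose movie matches no subreads file (or vice versa, when scraps are
    supplied) is an error.
    """
    def movie_of(path: str | Path) -> str:
        save = pysam.set_verbosity(0)
        try:
            with pysam.AlignmentFile(str(path), check_sq=False) as fh:
                for aln in fh.fetch(until_eof=True):
                    return parse_read_name(aln.query_name).movie
        finally:
            pysam.set_verbosity(save)
        return Path(path).stem  # empty file: fall back to the file stem

    sub_by_movie: dict[str, Path] = {}
    for p in subreads_paths:
        m = movie_of(p)
        if m in sub_by_movie:
            raise IntegrityError(f"two subreads files for movie {m!r}")
        sub_by_movie[m] = Path(p)
    scraps_by_movie: dict[str, Path] = {}
    if scraps_paths is not None:
        for p in scraps_paths:
            m = movie_of(p)
            if m not in sub_by_movie:
                raise IntegrityError(f"scraps file {p} (movie {m!r}) has no matching subreads file")
            if m in scraps_by_movie:
                raise IntegrityError(f"two scraps files for movie {m!r}")
            scraps_by_movie[m] = Path(p)
    return [
        SmrtCellFiles(subreads_path=sub, scraps_path=scraps_by_movie.get(m), cell_id=m)
        for m, sub in sorted(sub_by_movie.items())
    ]
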