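import pytest

from sequelkit.records import ReadIdentity, ScrapRecord, SubreadRecord
from sequelkit.simulate import FixtureSpec, generate_cell


def sub(movie, hole, qs, qe, seq=True, **tags):
    """Hand-built subread; seq=True fills a correct-length dummy sequence."""
    sequence = "A" * (qe - qs) if seq else None
    return SubreadRecord(ReadIdentity(movie, hole, qs, qe), sequence=sequence, extra_tags=tags)


def scrap(movie, hole, qs, qe, zmw_class="N", region_type="A", seq=True, **tags):
    sequence = "C" * (qe - qs) if seq else None
    return ScrapRecord(
        ReadIdentity(movie, hole, qs, qe),
        zmw_class=zmw_class,
        region_type=region_type,
        sequence=sequence,
        extra_tags=tags,
    )


@pytest.fixture
def make_cell(tmp_path):
    """Factory: generate a synthetic SMRTcell, returning (SmrtCellFiles, TruthTable)."""

    def _make(**kwargs):
        spec = FixtureSpec(**{"n_zmws": 30, "seed": 11, **kwargs})
        return generate_cell(spec, tmp_path / f"cell_s{spec.seed}_n{spec.n_zmws}")

    return _make
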