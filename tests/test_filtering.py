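import itertools

import pytest

from sequelkit.errors import ConfigError
from sequelkit.filtering import (
    FilterConfig,
    filter_full_pass,
    filter_min_clr_length,
    filter_normal_adapters,
    run_filter,
    zmw_has_full_pass,
)
from sequelkit.groups import group_by_zmw
from sequelkit.records import SmrtCellFiles, read_records, write_records

from conftest import scrap, sub


def write_cell(tmp_path, subreads, scraps, name="m1", prefix=""):
    p1 = write_records(subreads, tmp_path / f"{prefix}{name}.subreads.sam")
    p2 = write_records(scraps, tmp_path / f"{prefix}{name}.scraps.sam")
    return SmrtCellFiles(p1, p2, cell_id=name)


class TestConfig:
    def test_no_criterion_is_config_error(self):
        with pytest.raises(ConfigError):
            FilterConfig()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            FilterConfig(min_clr_length=-1)

    def test_scraps_file_mandatory(self, tmp_path):
        p = write_records([sub("m1", 1, 0, 10)], tmp_path / "s.sam")
        with pytest.raises(ConfigError):
            run_filter(SmrtCellFiles(p), FilterConfig(min_clr_length=1), tmp_path / "o")


class TestMinClrLength:
    def _bundle(self):
        return group_by_zmw(
            [sub("m1", 1, 0, 100), sub("m1", 1, 120, 250)],
            [scrap("m1", 1, 100, 120, "N", "A")],
        )

    def test_inclusive_boundary(self):
        bundles = self._bundle()
        assert filter_min_clr_length(bundles, 250) == {1}
        assert filter_min_clr_length(bundles, 251) == set()

    def test_threshold_zero_keeps_everything(self, make_cell):
        cell, _ = make_cell(n_zmws=20, seed=2)
        subreads = read_records(cell.subreads_path, "subreads", coordinates_only=True)
        scraps = read_records(cell.scraps_path, "scraps", coordinates_only=True)
        bundles = group_by_zmw(subreads, scraps)
        assert filter_min_clr_length(bundles, 0) == set(bundles)

    def test_scraps_only_bundle_can_survive(self):
        bundles = group_by_zmw([], [scrap("m1", 7, 0, 400, "N", "L")])
        assert filter_min_clr_length(bundles, 300) == {7}

    def test_all_provided_scraps_count_toward_length(self):
        # non-normal scrap still contributes to CLR length for filtering
        bundles = group_by_zmw([sub("m1", 1, 45, 145)], [scrap("m1", 1, 0, 45, "C", "A")])
        assert filter_min_clr_length(bundles, 145) == {1}


class TestFullPass:
    def test_adapter_flanked_subread_passes(self):
        bundles = group_by_zmw(
            [sub("m1", 1, 50, 500)],
            [scrap("m1", 1, 0, 50, "N", "A"), scrap("m1", 1, 500, 550, "N", "A")],
        )
        assert zmw_has_full_pass(bundles[1])
        assert len(filter_full_pass(bundles)) == 2

    def test_missing_leading_adapter_fails(self):
        bundles = group_by_zmw([sub("m1", 1, 0, 500)], [scrap("m1", 1, 500, 550, "N", "A")])
        assert not zmw_has_full_pass(bundles[1])
        assert filter_full_pass(bundles) == []

    def test_no_subreads_fails(self):
        bundles = group_by_zmw([], [scrap("m1", 1, 0, 45, "N", "A")])
        assert not zmw_has_full_pass(bundles[1])

    def test_interior_subread_of_multipass_zmw_passes(self):
        bundles = group_by_zmw(
            [sub("m1", 1, 0, 100), sub("m1", 1, 145, 260), sub("m1", 1, 305, 400)],
            [scrap("m1", 1, 100, 145, "N", "A"), scrap("m1", 1, 260, 305, "N", "A")],
        )
        assert zmw_has_full_pass(bundles[1])

    def test_non_adapter_scrap_does_not_flank(self):
        bundles = group_by_zmw(
            [sub("m1", 1, 50, 500)],
            [scrap("m1", 1, 0, 50, "N", "B"), scrap("m1", 1, 500, 550, "N", "A")],
        )
        assert not zmw_has_full_pass(bundles[1])

    def test_truth_table_agreement(self, make_cell):
        cell, truth = make_cell(n_zmws=80, seed=23)
        subreads = read_records(cell.subreads_path, "subreads", coordinates_only=True)
        scraps = read_records(cell.scraps_path, "scraps", coordinates_only=True)
        bundles = group_by_zmw(subreads, scraps)
        for row in truth.rows:
            if row.hole in bundles:
                assert zmw_has_full_pass(bundles[row.hole]) == row.has_full_pass, row.hole


class TestNormalAdapters:
    def test_all_twelve_combinations(self):
        scraps = [
            scrap("m1", i, i * 100, i * 100 + 45, zc, rt)
            for i, (zc, rt) in enumerate(itertools.product("NCMS", "ABL"))
        ]
        kept = filter_normal_adapters(scraps)
        assert len(kept) == 1
        assert (kept[0].zmw_class, kept[0].region_type) == ("N", "A")

    @pytest.mark.parametrize("zc,rt,expect", [("N", "A", True), ("C", "A", False), ("N", "L", False)])
    def test_examples(self, zc, rt, expect):
        kept = filter_normal_adapters([scrap("m1", 1, 0, 45, zc, rt)])
        assert bool(kept) is expect


class TestRunFilter:
    @pytest.fixture
    def cell(self, tmp_path, make_cell):
        cell, _ = make_cell(n_zmws=60, seed=31)
        return cell

    def test_min_length_restricts_both_outputs(self, tmp_path, cell):
        out = run_filter(cell, FilterConfig(min_clr_length=8000), tmp_path / "o")
        subreads = read_records(cell.subreads_path, "subreads")
        scraps = read_records(cell.scraps_path, "scraps")
        bundles = group_by_zmw(
            read_records(cell.subreads_path, "subreads", coordinates_only=True),
            read_records(cell.scraps_path, "scraps", coordinates_only=True),
        )
        surviving = {h for h, b in bundles.items() if b.clr_length >= 8000}
        assert read_records(out["subreads"]) == [
            r for r in subreads if r.identity.hole in surviving
        ]
        assert read_records(out["scraps"], "scraps") == [
            r for r in scraps if r.identity.hole in surviving
        ]

    def test_scraps_criteria_leave_subreads_untouched(self, tmp_path, cell):
        out = run_filter(cell, FilterConfig(require_full_pass=True, normal_adapters_only=True),
                         tmp_path / "o")
        assert read_records(out["subreads"]) == read_records(cell.subreads_path)
        for r in read_records(out["scraps"], "scraps"):
            assert (r.zmw_class, r.region_type) == ("N", "A")

    def test_criteria_commute(self, tmp_path, cell):
        full = run_filter(
            cell,
            FilterConfig(min_clr_length=5000, require_full_pass=True, normal_adapters_only=True),
            tmp_path / "combined",
        )
        # apply each criterion independently on the raw inputs and intersect:
        # the combined run must equal that intersection in any order
        subreads = read_records(cell.subreads_path, "subreads")
        scraps = read_records(cell.scraps_path, "scraps")
        bundles = group_by_zmw(subreads, scraps)
        surviving = filter_min_clr_length(bundles, 5000)
        passing = {h for h, b in bundles.items() if zmw_has_full_pass(b)}
        expected_subs = [r for r in subreads if r.identity.hole in surviving]
        expected_scraps = [
            r for r in scraps
            if r.identity.hole in surviving and r.identity.hole in passing
            and (r.zmw_class, r.region_type) == ("N", "A")
        ]
        assert read_records(full["subreads"]) == expected_subs
        assert read_records(full["scraps"], "scraps") == expected_scraps

    def test_idempotence(self, tmp_path, cell):
        config = FilterConfig(min_clr_length=5000, require_full_pass=True,
                              normal_adapters_only=True)
        once = run_filter(cell, config, tmp_path / "once")
        cell2 = SmrtCellFiles(once["subreads"], once["scraps"], cell_id="again")
        twice = run_filter(cell2, config, tmp_path / "twice")
        assert read_records(twice["subreads"]) == read_records(once["subreads"])
        assert read_records(twice["scraps"], "scraps") == read_records(once["scraps"], "scraps")

    def test_monotone_in_threshold(self, tmp_path, cell):
        prev = None
        for t in (0, 2000, 6000, 12000, 10**7):
            out = run_filter(cell, FilterConfig(min_clr_length=t), tmp_path / f"t{t}")
            names = [r.identity.name for r in read_records(out["subreads"])]
            if prev is not None:
                assert set(names) <= set(prev)
            prev = names

    def test_two_stage_order_changes_clr_lengths(self, tmp_path):
        """Scraps-first filtering shrinks the CLR length a later threshold sees."""
        # CLR: control-class adapter [0,500) + subread [500,1000): length 1000,
        # but only 500 after the normal-adapter criterion removes the scrap.
        subreads = [sub("m1", 1, 500, 1000)]
        scraps = [scrap("m1", 1, 0, 500, "C", "A")]
        cell = write_cell(tmp_path, subreads, scraps)

        direct = run_filter(cell, FilterConfig(min_clr_length=800), tmp_path / "direct")
        assert len(read_records(direct["subreads"])) == 1  # 1000 >= 800

        stage1 = run_filter(cell, FilterConfig(normal_adapters_only=True), tmp_path / "st1")
        cell2 = SmrtCellFiles(stage1["subreads"], stage1["scraps"], cell_id="m1b")
        stage2 = run_filter(cell2, FilterConfig(min_clr_length=800), tmp_path / "st2")
        assert read_records(stage2["subreads"]) == []  # 500 < 800

    def test_idempotent_and_submultiset(self, tmp_path, cell):
        out = run_filter(cell, FilterConfig(min_clr_length=3000), tmp_path / "o")
        inputs = read_records(cell.subreads_path)
        kept = read_records(out["subreads"])
        assert all(r in inputs for r in kept)
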