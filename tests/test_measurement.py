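"""Diameter geometry, mask tracing and case reduction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pleograde as pg
from pleograde.measurement import EXCLUSION_FLAGS

from conftest import random_simple_polygon


def outline(points, nucleus_id="n", flags=()):
    return pg.NucleusOutline(nucleus_id=nucleus_id, points=tuple(points),
                             flags=frozenset(flags))


def thin_triangle(diameter_px: float) -> pg.NucleusOutline:
    """Simple polygon whose geometric diameter equals ``diameter_px``."""
    return outline([(0.0, 0.0), (diameter_px, 0.0), (diameter_px / 2, 1e-3)],
                   nucleus_id=f"d{diameter_px}")


class TestLongestAxis:
    def test_square_diagonal(self):
        sq = outline([(0, 0), (10, 0), (10, 10), (0, 10)])
        assert pg.longest_axis(sq) == pytest.approx(10 * np.sqrt(2))

    def test_circle_64gon(self):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        circ = outline(np.column_stack([30 * np.cos(theta), 30 * np.sin(theta)]))
        assert pg.longest_axis(circ) == pytest.approx(60.0, abs=0.5)

    def test_matches_brute_force_on_random_simple_polygons(self, rng):
        """Hull-pruned diameter equals the O(n^2) all-pairs maximum exactly."""
        for _ in range(200):
            pts = random_simple_polygon(rng, int(rng.integers(4, 40)))
            got = pg.longest_axis(outline(pts))
            diffs = pts[:, None, :] - pts[None, :, :]
            brute = np.sqrt((diffs**2).sum(-1)).max()
            assert got == brute

    def test_too_few_points_rejected(self):
        with pytest.raises(pg.InputError):
            pg.longest_axis(outline([(0, 0), (1, 1)]))

    def test_self_intersecting_polygon_rejected(self):
        bowtie = outline([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(pg.InputError):
            pg.longest_axis(bowtie)

    def test_unknown_flag_rejected(self):
        with pytest.raises(pg.InputError):
            outline([(0, 0), (1, 0), (0, 1)], flags={"blurry"})


class TestOutlinesFromMask:
    def test_rectangle_diagonal_pixel_centers(self):
        mask = np.zeros((30, 40), np.int32)
        mask[5:15, 7:27] = 1  # 20 x 10 px filled rectangle
        (out,) = pg.outlines_from_mask(mask)
        diag = pg.longest_axis(out, validate=False)
        assert diag == pytest.approx(np.hypot(19, 9), abs=1.5)
        # pixel-center convention makes it exact here
        assert diag == pytest.approx(np.hypot(19, 9))

    def test_all_zero_mask_empty(self):
        assert pg.outlines_from_mask(np.zeros((10, 10), np.uint16)) == []

    def test_two_labels_two_outlines(self):
        mask = np.zeros((20, 20), np.int32)
        mask[2:8, 2:8] = 3
        mask[12:18, 12:18] = 7
        outs = pg.outlines_from_mask(mask)
        assert [o.nucleus_id for o in outs] == ["3", "7"]

    def test_non_integer_mask_rejected(self):
        with pytest.raises(pg.InputError):
            pg.outlines_from_mask(np.zeros((5, 5), float))

    def test_negative_labels_rejected(self):
        mask = np.zeros((5, 5), np.int32)
        mask[2, 2] = -1
        with pytest.raises(pg.InputError):
            pg.outlines_from_mask(mask)

    def test_tiny_label_dropped(self, caplog):
        mask = np.zeros((10, 10), np.int32)
        mask[4, 4] = 1           # single pixel: no polygon
        mask[6:9, 2:9] = 2
        with caplog.at_level("WARNING", logger="pleograde.measurement"):
            outs = pg.outlines_from_mask(mask)
        assert [o.nucleus_id for o in outs] == ["2"]
        assert "dropped" in caplog.text

    def test_traced_region_diameter_close_to_truth(self):
        spec = pg.random_field_spec(10, image_width=600, image_height=500, seed=17)
        mask, _, truth = pg.generate_field(spec)
        outs = pg.outlines_from_mask(mask)
        measured = [pg.longest_axis(o, validate=False) * spec.calibration for o in outs]
        for got, want in zip(measured, truth):
            assert abs(got - want) <= 1.0 * spec.calibration  # within 1 px


class TestMeasureCase:
    def test_topk_reduction_hand_example(self):
        outs = [thin_triangle(d) for d in (10, 20, 30, 90, 100, 110)]
        rec = pg.measure_case("c1", outs, pg.Calibration(6.5), k_extreme=3)
        assert rec.lns == pytest.approx(100 * 6.5)
        assert rec.sns == pytest.approx(20 * 6.5)
        assert rec.nsd == pytest.approx(520.0)

    def test_single_nucleus_degenerates(self):
        with pytest.warns(UserWarning, match="truncated"):
            rec = pg.measure_case("c", [thin_triangle(40)], pg.Calibration(6.5),
                                  k_extreme=3)
        assert rec.lns == rec.sns == pytest.approx(260.0)
        assert rec.nsd == 0.0

    def test_all_flagged_rejected(self):
        outs = [outline([(0, 0), (10, 0), (5, 5)], flags={"multinucleated"})]
        with pytest.raises(pg.InputError):
            pg.measure_case("c", outs, pg.Calibration())

    @pytest.mark.parametrize("flag", sorted(EXCLUSION_FLAGS))
    def test_flagged_nuclei_excluded(self, flag):
        outs = [thin_triangle(10), thin_triangle(20),
                outline([(0, 0), (500, 0), (250, 1e-3)], flags={flag})]
        rec = pg.measure_case("c", outs, pg.Calibration(1.0), k_extreme=1)
        assert rec.lns == pytest.approx(20.0)  # the flagged giant is ignored

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_calibration_linearity(self, scale):
        outs = [thin_triangle(d) for d in (15, 40, 80)]
        base = pg.measure_case("c", outs, pg.Calibration(1.0), k_extreme=2)
        scaled = pg.measure_case("c", outs, pg.Calibration(scale), k_extreme=2)
        assert scaled.lns == pytest.approx(base.lns * scale, rel=1e-12)
        assert scaled.sns == pytest.approx(base.sns * scale, rel=1e-12)
        assert scaled.nsd == pytest.approx(base.nsd * scale, rel=1e-9)

    def test_lns_monotone_when_adding_large_nucleus(self, rng):
        diameters = list(rng.uniform(10, 100, 8))
        outs = [thin_triangle(d) for d in diameters]
        before = pg.measure_case("c", outs, pg.Calibration(1.0), k_extreme=3)
        after = pg.measure_case(
            "c", outs + [thin_triangle(max(diameters) + 5)],
            pg.Calibration(1.0), k_extreme=3,
        )
        assert after.lns >= before.lns
        assert after.sns <= before.sns + 1e-12

    def test_invalid_k_rejected(self):
        with pytest.raises(pg.InputError):
            pg.measure_case("c", [thin_triangle(10)], pg.Calibration(), k_extreme=0)

    def test_end_to_end_on_synthetic_field(self):
        """Measured LNS/SNS agree with ground-truth extremes within 1 px."""
        spec = pg.random_field_spec(9, image_width=600, image_height=500, seed=23)
        mask, _, truth = pg.generate_field(spec)
        rec = pg.measure_case("f", pg.outlines_from_mask(mask),
                              pg.Calibration(spec.calibration), k_extreme=3,
                              validate=False)
        want = np.sort(truth)
        tol = 1.0 * spec.calibration
        assert abs(rec.lns - want[-3:].mean()) <= tol
        assert abs(rec.sns - want[:3].mean()) <= tol


class TestCaseRecordAndIO:
    def test_record_invariants(self):
        with pytest.raises(pg.InputError):
            pg.CaseRecord("c", sns=10.0, lns=5.0, nsd=-5.0)
        with pytest.raises(pg.InputError):
            pg.CaseRecord("c", sns=5.0, lns=10.0, nsd=4.0)  # nsd != lns - sns
        with pytest.raises(pg.InputError):
            pg.CaseRecord("c", sns=5.0, lns=10.0, nsd=5.0, original_score=4)

    def test_csv_roundtrip(self, tmp_path, phase1_cohort):
        path = tmp_path / "cohort.csv"
        pg.write_cases_csv(phase1_cohort, path)
        assert pg.read_cases_csv(path) == phase1_cohort
        header = path.read_text().splitlines()[0]
        assert header == "case_id,sns_um,lns_um,nsd_um,original_score"

    def test_outline_json_roundtrip(self, tmp_path):
        outs = [thin_triangle(10), outline([(0, 0), (3, 0), (0, 4)],
                                           nucleus_id="b", flags={"multinucleated"})]
        path = tmp_path / "outlines.json"
        pg.write_outlines_json(outs, path)
        assert pg.read_outlines_json(path) == outs
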