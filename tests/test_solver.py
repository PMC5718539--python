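"""Acquisition plans, pairing arithmetic, averaging, and jaw-error cancellation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidiso import SimulationTruth, aggregate, pair_measurements, pair_shift, plan_acquisition
from epidiso.geometry import ROOM_AXES, jaw_outward_room
from epidiso.measurement import JawMeasurement
from epidiso.solver import DIMENSION_TABLE, SolverError, jaw_error_invariance_check, pair_dimension


def _jm(gantry, collimator, jaw, d):
    return JawMeasurement(
        image_ref=f"G{gantry:03.0f}_C{collimator:03.0f}",
        jaw=jaw,
        gantry_deg=gantry,
        collimator_deg=collimator,
        d_mm=d,
        n_rays=11,
        ray_spread_mm=0.01,
    )


class TestPlanAcquisition:
    @pytest.mark.parametrize(
        "vendor,mode,count",
        [
            ("siemens", "minimal", 6),
            ("varian", "minimal", 4),
            ("elekta", "minimal", 4),
            ("siemens", "full", 16),
            ("varian", "full", 8),
            ("elekta", "full", 8),
        ],
    )
    def test_image_counts(self, vendor, mode, count):
        assert len(plan_acquisition(vendor, mode)) == count

    @pytest.mark.parametrize("vendor", ["siemens", "varian", "elekta"])
    @pytest.mark.parametrize("mode", ["minimal", "full"])
    def test_every_view_has_collimator_partner(self, vendor, mode):
        plan = plan_acquisition(vendor, mode)
        views = {(v.gantry_deg, v.collimator_deg) for v in plan.views}
        for g, c in views:
            assert (g, (c + 180.0) % 360.0) in views

    @pytest.mark.parametrize("vendor", ["siemens", "varian"])
    def test_full_plan_covers_cardinal_gantry(self, vendor):
        plan = plan_acquisition(vendor, "full")
        assert {v.gantry_deg for v in plan.views} == {0.0, 90.0, 180.0, 270.0}

    def test_unknown_vendor_rejected(self):
        with pytest.raises(SolverError):
            plan_acquisition("tomo", "full")


class TestPairShift:
    @pytest.mark.parametrize(
        "d1,d2,s", [(51.0, 49.0, 1.0), (50.0, 50.0, 0.0), (49.3, 50.7, -0.7)]
    )
    def test_examples(self, d1, d2, s):
        assert pair_shift(d1, d2) == pytest.approx(s)

    @given(
        d1=st.floats(40, 60, allow_nan=False),
        d2=st.floats(40, 60, allow_nan=False),
        offset=st.floats(-2, 2, allow_nan=False),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_constant_jaw_offset_cancels_exactly(self, d1, d2, offset):
        # the module's defining property: Eq.(1) is invariant under a
        # constant per-jaw calibration error added to both distances
        assert pair_shift(d1 + offset, d2 + offset) == pytest.approx(pair_shift(d1, d2))

    def test_non_finite_rejected(self):
        with pytest.raises(SolverError):
            pair_shift(np.nan, 50.0)


class TestDimensionMapping:
    def test_table_matches_iec_geometry(self):
        for (jaw, g, c_ref), (dim, sign) in DIMENSION_TABLE.items():
            d = jaw_outward_room(jaw, g, c_ref)
            k = int(np.argmax(np.abs(d)))
            assert ROOM_AXES[k] == dim
            assert int(np.sign(d[k])) == sign

    @pytest.mark.parametrize(
        "gantry,c1,c2,expected",
        [
            (0.0, 90.0, 270.0, "lateral"),
            (90.0, 90.0, 270.0, "vertical"),
            (0.0, 0.0, 180.0, "longitudinal"),
        ],
    )
    def test_y2_pair_dimensions(self, gantry, c1, c2, expected):
        ms = [_jm(gantry, c1, "Y2", 51.0), _jm(gantry, c2, "Y2", 49.0)]
        (pair,) = pair_measurements(ms)
        assert pair.dimension == expected
        assert pair.s_mm == pytest.approx(1.0)

    def test_mapping_validated_against_renderer(self):
        """A pure unit offset along each room axis must surface as S_bar
        of -offset in that dimension only (renderer as oracle)."""
        from epidiso.pipeline import analyze_images
        from epidiso.synthetic import render_session

        plan = plan_acquisition("varian", "minimal")
        for axis_idx, dim in enumerate(ROOM_AXES):
            offset = [0.0, 0.0, 0.0]
            offset[axis_idx] = 1.0
            truth = SimulationTruth(
                phantom_offset_mm=tuple(offset), noise_sd=0.0, seed=9
            )
            result = analyze_images(render_session(truth, plan))
            for d in ROOM_AXES:
                expected = -1.0 if d == dim else 0.0
                assert result.S_bar_mm[d] == pytest.approx(expected, abs=0.1), (dim, d)


class TestPairMeasurements:
    def test_unpaired_strict_lists_missing_views(self):
        ms = [_jm(0.0, 90.0, "Y2", 51.0)]
        with pytest.raises(SolverError, match="missing views.*collimator 270"):
            pair_measurements(ms)

    def test_permissive_returns_available_pairs(self):
        ms = [
            _jm(0.0, 90.0, "Y2", 51.0),
            _jm(0.0, 270.0, "Y2", 49.0),
            _jm(90.0, 90.0, "Y2", 50.0),
        ]
        pairs = pair_measurements(ms, strict=False)
        assert len(pairs) == 1

    def test_every_measurement_used_once(self):
        plan = plan_acquisition("varian", "full")
        ms = []
        for v in plan.views:
            for jaw in v.jaws:
                ms.append(_jm(v.gantry_deg, v.collimator_deg, jaw, 50.0))
        pairs = pair_measurements(ms)
        assert len(pairs) == len(ms) // 2


class TestAggregate:
    def test_single_pair_per_dimension(self):
        ms = [
            _jm(0.0, 90.0, "Y2", 51.0),
            _jm(0.0, 270.0, "Y2", 49.0),
            _jm(90.0, 90.0, "Y2", 50.5),
            _jm(90.0, 270.0, "Y2", 49.5),
            _jm(0.0, 0.0, "Y2", 50.2),
            _jm(0.0, 180.0, "Y2", 49.8),
        ]
        res = aggregate(pair_measurements(ms))
        assert res.n_per_dimension == {"lateral": 1, "vertical": 1, "longitudinal": 1}
        # signs: see the dimension table; magnitudes equal the pair shifts
        assert abs(res.S_bar_mm["lateral"]) == pytest.approx(1.0)
        assert abs(res.S_bar_mm["vertical"]) == pytest.approx(0.5)
        assert abs(res.S_bar_mm["longitudinal"]) == pytest.approx(0.2)

    def test_lateral_mean_over_two_gantry_angles(self):
        # room-frame lateral shifts of +1.0 (gantry 0) and +0.6 (gantry 180)
        # average to +0.8; the raw pair shifts carry opposite signs because
        # the panel axis flips with the gantry
        ms = [
            _jm(0.0, 90.0, "Y2", 49.0),
            _jm(0.0, 270.0, "Y2", 51.0),
            _jm(180.0, 90.0, "Y2", 50.6),
            _jm(180.0, 270.0, "Y2", 50.0 - 0.6),
            _jm(0.0, 0.0, "Y2", 50.0),
            _jm(0.0, 180.0, "Y2", 50.0),
            _jm(90.0, 90.0, "Y2", 50.0),
            _jm(90.0, 270.0, "Y2", 50.0),
        ]
        res = aggregate(pair_measurements(ms))
        lat_pairs = {p.gantry_deg: p.s_room_mm for p in res.pair_shifts if p.dimension == "lateral"}
        assert lat_pairs[0.0] == pytest.approx(1.0)
        assert lat_pairs[180.0] == pytest.approx(0.6)
        assert res.S_bar_mm["lateral"] == pytest.approx(0.8)
        assert res.n_per_dimension["lateral"] == 2

    def test_missing_dimension_named(self):
        ms = [_jm(0.0, 90.0, "Y2", 51.0), _jm(0.0, 270.0, "Y2", 49.0)]
        with pytest.raises(SolverError, match="longitudinal"):
            aggregate(pair_measurements(ms, strict=False))

    def test_couch_sign_convention_applied(self):
        ms = [
            _jm(0.0, 90.0, "Y2", 51.0),
            _jm(0.0, 270.0, "Y2", 49.0),
            _jm(90.0, 90.0, "Y2", 50.0),
            _jm(90.0, 270.0, "Y2", 50.0),
            _jm(0.0, 0.0, "Y2", 50.0),
            _jm(0.0, 180.0, "Y2", 50.0),
        ]
        plain = aggregate(pair_measurements(ms))
        flipped = aggregate(pair_measurements(ms), couch_signs=(-1, 1, 1))
        assert flipped.couch_shift_mm["lateral"] == -plain.couch_shift_mm["lateral"]
        assert abs(flipped.couch_shift_mm["lateral"]) == pytest.approx(
            abs(plain.S_bar_mm["lateral"])
        )

    def test_deterministic_reaggregation(self):
        ms = [
            _jm(0.0, 90.0, "Y2", 51.234),
            _jm(0.0, 270.0, "Y2", 49.117),
            _jm(90.0, 90.0, "Y2", 50.01),
            _jm(90.0, 270.0, "Y2", 49.99),
            _jm(0.0, 0.0, "Y2", 50.3),
            _jm(0.0, 180.0, "Y2", 49.9),
        ]
        a = aggregate(pair_measurements(ms))
        b = aggregate(pair_measurements(ms))
        assert a.S_bar_mm == b.S_bar_mm


class TestJawErrorInvariance:
    def test_simulated_sessions_cancel(self):
        base = dict(phantom_offset_mm=(0.5, -1.0, 1.5), seed=11)
        t_a = SimulationTruth(**base)
        t_b = SimulationTruth(
            **base, jaw_offsets_mm={"X1": 2.0, "X2": -2.0, "Y1": 1.0, "Y2": 2.0}
        )
        delta = jaw_error_invariance_check(t_a, t_b)
        assert delta < 0.1

    def test_mispairing_breaks_cancellation(self):
        """Pairing Y2 against Y1 leaks half the differential jaw offset."""
        q = 0.7  # phantom center along the jaw axis
        dy2, dy1 = 2.0, 0.0
        d1 = 50.0 + dy2 - q  # Y2 at collimator c
        d2_correct = 50.0 + dy2 + q  # Y2 at c+180
        d2_wrong = 50.0 + dy1 + q  # Y1 at c+180 (same panel side, wrong jaw)
        assert pair_shift(d1, d2_correct) == pytest.approx(-q)
        assert pair_shift(d1, d2_wrong) - (-q) == pytest.approx((dy2 - dy1) / 2)
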