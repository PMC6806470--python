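"""Timelines, moving-target accumulation and course simulation."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from proton_interplay import (
    MotionTrace,
    accumulate_fraction,
    build_timeline,
    modulator_period_s,
    simulate_course,
)
from proton_interplay.delivery import BEAM_OFF, FULL_BEAM


def interp_static(plan, field, points):
    g = plan.field_grids[field][FULL_BEAM]
    f = RegularGridInterpolator(tuple(g.grid.coords(i) for i in range(3)), g.values)
    return f(points)


def zero_trace(n_seconds):
    return MotionTrace(np.arange(float(n_seconds)), np.zeros((n_seconds, 3)), 1.0)


class TestTimeline:
    def test_ds_2gy_beam_on_is_60s(self):
        tl = build_timeline("DS", 2.0, 2.0)
        assert tl.beam_on_s == pytest.approx(60.0)
        assert tl.delivery_span_s == pytest.approx(60.0)
        assert tl.end_s == pytest.approx(85.0)

    def test_us_sbrt_span_is_224s(self, layers14):
        tl = build_timeline("US", 7.25, 2.0, layers14, delay_s=25.0, switch_s=0.5)
        assert tl.beam_on_s == pytest.approx(217.5)
        assert tl.delivery_span_s == pytest.approx(224.0, abs=1e-6)

    def test_single_layer_us_has_no_gaps(self, peak_model):
        from proton_interplay import build_layer_set, solve_layer_weights

        one = solve_layer_weights(peak_model, build_layer_set(30.1, 0.6, 0.6))
        tl = build_timeline("US", 2.0, 2.0, one)
        assert tl.delivery_span_s == pytest.approx(60.0)
        assert not any(s.source == BEAM_OFF and s.start_s > 0 for s in tl.segments)

    def test_segments_contiguous_and_ordered(self, small_layers):
        tl = build_timeline("US", 2.0, 2.0, small_layers)
        for a, b in zip(tl.segments, tl.segments[1:]):
            assert b.start_s == pytest.approx(a.end_s)
            assert b.end_s >= b.start_s
        layer_order = [s.source for s in tl.segments if isinstance(s.source, int)]
        assert layer_order == sorted(layer_order)  # distal (0) to proximal

    def test_beam_on_time_matches_dose_over_rate(self, small_layers):
        tl = build_timeline("US", 3.3, 1.7, small_layers)
        on = sum(s.end_s - s.start_s for s in tl.segments if isinstance(s.source, int))
        assert on == pytest.approx(3.3 / 1.7 * 60.0, rel=1e-12)

    def test_modulator_period_at_600_rpm(self):
        assert modulator_period_s() == pytest.approx(0.1)

    def test_invalid_inputs(self, small_layers):
        with pytest.raises(ValueError):
            build_timeline("PBS", 2.0, 2.0)
        with pytest.raises(ValueError):
            build_timeline("DS", 0.0, 2.0)
        with pytest.raises(ValueError):
            build_timeline("US", 2.0, 2.0, None)


class TestAccumulation:
    def test_zero_motion_ds_equals_static(self, small_plan, small_ctv):
        tl = build_timeline("DS", 2.0, 2.0)
        fd = accumulate_fraction(
            small_plan.field_grids["RAO"], tl, zero_trace(90), small_ctv
        )
        static = interp_static(small_plan, "RAO", small_ctv.voxel_centers())
        np.testing.assert_allclose(fd.values, static, rtol=1e-9)

    def test_zero_motion_us_equals_ds(self, small_plan, small_layers, small_ctv):
        ds = accumulate_fraction(
            small_plan.field_grids["RAO"], build_timeline("DS", 2.0, 2.0),
            zero_trace(90), small_ctv,
        )
        us = accumulate_fraction(
            small_plan.field_grids["RAO"], build_timeline("US", 2.0, 2.0, small_layers),
            zero_trace(95), small_ctv,
        )
        np.testing.assert_allclose(us.values, ds.values, rtol=1e-6)

    def test_constant_offset_equals_shifted_static(self, small_plan, small_ctv, make_constant_trace):
        offset = (0.0, 2.0, 5.0)  # (LR, SI, AP)
        tl = build_timeline("DS", 2.0, 2.0)
        fd = accumulate_fraction(
            small_plan.field_grids["RAO"], tl, make_constant_trace(offset, 90), small_ctv
        )
        shifted = small_ctv.voxel_centers() + np.array([0.0, 5.0, 2.0])  # grid order
        np.testing.assert_allclose(
            fd.values, interp_static(small_plan, "RAO", shifted), rtol=1e-9
        )

    def test_lateral_motion_within_margin_conserves_mean_dose(
        self, small_plan, small_ctv, make_constant_trace
    ):
        tl = build_timeline("DS", 2.0, 2.0)
        still = accumulate_fraction(
            small_plan.field_grids["RAO"], tl, zero_trace(90), small_ctv
        )
        moved = accumulate_fraction(
            small_plan.field_grids["RAO"], tl,
            make_constant_trace((0.0, 3.0, 3.0), 90), small_ctv,
        )
        assert abs(moved.values.mean() / still.values.mean() - 1.0) < 0.01

    def test_ds_time_reversal_invariant_us_not(self, small_plan, small_layers, small_ctv):
        rng = np.random.default_rng(4)
        # trace length equals the delay-free DS beam-on time, so reversal
        # permutes exactly the displacements the constant DS source visits
        n = 60
        disp = np.cumsum(rng.normal(0.0, 0.4, size=(n, 3)), axis=0)
        fwd = MotionTrace(np.arange(float(n)), disp, 1.0)
        rev = MotionTrace(np.arange(float(n)), disp[::-1], 1.0)

        tl_ds = build_timeline("DS", 2.0, 2.0, delay_s=0.0)
        a = accumulate_fraction(small_plan.field_grids["RAO"], tl_ds, fwd, small_ctv)
        b = accumulate_fraction(small_plan.field_grids["RAO"], tl_ds, rev, small_ctv)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

        n_us = 64  # 60 s beam-on + 7 x 0.5 s switch gaps
        disp = np.cumsum(rng.normal(0.0, 0.4, size=(n_us, 3)), axis=0)
        fwd = MotionTrace(np.arange(float(n_us)), disp, 1.0)
        rev = MotionTrace(np.arange(float(n_us)), disp[::-1], 1.0)
        tl_us = build_timeline("US", 2.0, 2.0, small_layers, delay_s=0.0)
        ua = accumulate_fraction(small_plan.field_grids["RAO"], tl_us, fwd, small_ctv)
        ub = accumulate_fraction(small_plan.field_grids["RAO"], tl_us, rev, small_ctv)
        assert np.abs(ua.values - ub.values).max() > 1e-3

    def test_matches_bruteforce_second_voxel_loop(self, small_plan, small_layers):
        """Independent re-implementation: explicit loops, hand-rolled trilinear."""

        class CubeCTV:
            def voxel_centers(self):
                ax = np.array([-4.0, -2.0, 0.0, 2.0, 4.0])
                xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
                return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

        ctv = CubeCTV()
        rng = np.random.default_rng(9)
        n = 30
        disp = np.cumsum(rng.normal(0.0, 0.5, size=(n, 3)), axis=0)
        trace = MotionTrace(np.arange(float(n)), disp, 1.0)
        tl = build_timeline("US", 0.8, 2.0, small_layers, delay_s=1.3, switch_s=0.5)
        assert tl.end_s <= n

        fast = accumulate_fraction(small_plan.field_grids["RAO"], tl, trace, ctv)

        def trilinear(grid_obj, p):
            g = grid_obj.grid
            idx = []
            frac = []
            for ax in range(3):
                u = (p[ax] - g.origin_mm[ax]) / g.spacing_mm[ax]
                i = int(np.floor(u))
                i = min(max(i, 0), g.shape[ax] - 2)
                idx.append(i)
                frac.append(u - i)
            v = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = (
                            (frac[0] if dx else 1 - frac[0])
                            * (frac[1] if dy else 1 - frac[1])
                            * (frac[2] if dz else 1 - frac[2])
                        )
                        v += w * grid_obj.values[idx[0] + dx, idx[1] + dy, idx[2] + dz]
            return v

        pts = ctv.voxel_centers()
        disp_xyz = trace.disp_xyz()
        slow = np.zeros(len(pts))
        for t in range(int(np.ceil(tl.end_s))):
            for seg in tl.segments:
                if seg.source == BEAM_OFF or seg.scale == 0.0:
                    continue
                overlap = min(seg.end_s, t + 1.0) - max(seg.start_s, float(t))
                if overlap <= 1e-12:
                    continue
                grid_obj = small_plan.field_grids["RAO"][seg.source]
                for i, p in enumerate(pts):
                    slow[i] += overlap * seg.scale * trilinear(grid_obj, p + disp_xyz[t])
        np.testing.assert_allclose(fast.values, slow, rtol=1e-9, atol=1e-12)

    def test_trace_too_short_rejected(self, small_plan, small_ctv):
        tl = build_timeline("DS", 2.0, 2.0)
        with pytest.raises(ValueError, match="timeline"):
            accumulate_fraction(
                small_plan.field_grids["RAO"], tl, zero_trace(40), small_ctv
            )

    def test_out_of_grid_motion_rejected(self, small_plan, small_ctv, make_constant_trace):
        tl = build_timeline("DS", 2.0, 2.0)
        with pytest.raises(ValueError, match="pad"):
            accumulate_fraction(
                small_plan.field_grids["RAO"], tl,
                make_constant_trace((0.0, 0.0, 80.0), 90), small_ctv,
            )

    def test_ten_hz_trace_rejected(self, small_plan, small_ctv):
        tr = MotionTrace(np.arange(900) / 10.0, np.zeros((900, 3)), 10.0)
        tl = build_timeline("DS", 2.0, 2.0)
        with pytest.raises(ValueError, match="1 Hz"):
            accumulate_fraction(small_plan.field_grids["RAO"], tl, tr, small_ctv)


class TestCourse:
    def test_zero_motion_course_equals_static(self, small_plan, small_ctv):
        # 14 fractions alternate LAO/RAO equally; with no motion the course
        # equals the two-field static composite at the CTV voxels
        traces = [zero_trace(90) for _ in range(14)]
        course, fractions = simulate_course(small_plan, traces, "DS", 2.0)
        assert len(fractions) == 14
        pts = small_ctv.voxel_centers()
        static = 0.5 * (
            interp_static(small_plan, "LAO", pts) + interp_static(small_plan, "RAO", pts)
        )
        np.testing.assert_allclose(course.values, static, rtol=1e-9)

    def test_course_is_mean_of_fraction_doses(self, small_plan):
        rng = np.random.default_rng(2)
        traces = [
            MotionTrace(
                np.arange(90.0), np.cumsum(rng.normal(0, 0.3, (90, 3)), axis=0), 1.0
            )
            for _ in range(4)
        ]
        course, fractions = simulate_course(small_plan, traces, "US", 2.0)
        np.testing.assert_allclose(
            course.values, np.mean([f.values for f in fractions], axis=0), rtol=1e-12
        )

    def test_fields_alternate_starting_lao(self, small_plan):
        traces = [zero_trace(90) for _ in range(5)]
        _, fractions = simulate_course(small_plan, traces, "DS", 2.0)
        assert [f.field for f in fractions] == ["LAO", "RAO", "LAO", "RAO", "LAO"]

    def test_fraction_averaging_shrinks_variance(self, small_plan, small_ctv):
        """Course-dose variance across seeds is about 1/n of fraction variance."""
        n_frac, n_seeds = 4, 8
        rng = np.random.default_rng(12)
        singles, courses = [], []
        for _ in range(n_seeds):
            traces = [
                MotionTrace(
                    np.arange(90.0),
                    np.cumsum(rng.normal(0, 0.25, (90, 3)), axis=0),
                    1.0,
                )
                for _ in range(n_frac)
            ]
            course, fractions = simulate_course(small_plan, traces, "DS", 2.0)
            singles.extend(f.values for f in fractions)
            courses.append(course.values)
        var_single = np.var(np.asarray(singles), axis=0).mean()
        var_course = np.var(np.asarray(courses), axis=0).mean()
        assert var_course <= var_single / n_frac * 1.6

    def test_no_traces_rejected(self, small_plan):
        with pytest.raises(ValueError):
            simulate_course(small_plan, [], "DS", 2.0)
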