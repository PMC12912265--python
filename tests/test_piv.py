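import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yolkflow.io import CalibratedStack
from yolkflow.piv import (
    PivParams,
    PivParameterError,
    VectorField,
    compare_quadrants,
    compute_piv,
    directional_summary,
    filter_vectors,
    quadrant_of,
    vector_angles_deg,
)
from yolkflow.synth import FlowScenario, make_flow_stack

from .conftest import shifted_pair_stack


def _field(dx, dy, s2n=None, pixel_size=0.25, frame_interval=0.5):
    """Hand-built VectorField with velocities derived via the calibration."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    stack = CalibratedStack(np.zeros((2, 16, 16)), pixel_size, frame_interval)
    return VectorField(
        rows=np.zeros_like(dx), cols=np.zeros_like(dx), dx=dx, dy=dy,
        vx=np.asarray(stack.px_per_frame_to_um_per_min(dx)),
        vy=np.asarray(stack.px_per_frame_to_um_per_min(dy)),
        s2n=np.full(dx.shape, 10.0) if s2n is None else np.asarray(s2n, dtype=float),
        valid=np.ones(dx.shape, dtype=bool), frame_pair=0,
    )


class TestComputePiv:
    def test_identity_pair_zero_displacement(self, puncta_texture):
        stack = shifted_pair_stack(puncta_texture, (0, 0))
        (field,) = compute_piv(stack, PivParams())
        assert np.all(np.isfinite(field.s2n))
        # sub-pixel refinement wobbles within the texture's flank asymmetry
        np.testing.assert_allclose(field.dx, 0.0, atol=0.02)
        np.testing.assert_allclose(field.dy, 0.0, atol=0.02)

    @pytest.mark.parametrize("shift", [(3, 0), (0, -4), (-2, 5)])
    def test_integer_circular_shift_recovered(self, puncta_texture, shift):
        stack = shifted_pair_stack(puncta_texture, shift)
        (field,) = compute_piv(stack, PivParams())
        np.testing.assert_allclose(field.dy, shift[0], atol=0.05)
        np.testing.assert_allclose(field.dx, shift[1], atol=0.05)

    def test_uniform_flow_recovered_from_generator(self):
        scn = FlowScenario(kind="uniform", vx=0.0, vy=-0.5, n_frames=8, seed=3)
        stack, _ = make_flow_stack(scn, pixel_size=0.25, shape=(220, 220))
        fields = compute_piv(stack, PivParams())
        vy = np.concatenate([f.vy for f in fields])
        assert vy.mean() == pytest.approx(-0.5, rel=0.10)

    def test_constant_window_flagged_invalid(self):
        frames = np.ones((2, 80, 80))
        stack = CalibratedStack(frames, 0.25, 0.5)
        (field,) = compute_piv(stack, PivParams(window_um=10.0))
        assert not field.valid.any()
        assert np.all(field.s2n == 0.0)

    def test_window_larger_than_frame_rejected(self):
        stack = CalibratedStack(np.zeros((2, 32, 32)), 0.25, 0.5)
        with pytest.raises(PivParameterError):
            compute_piv(stack, PivParams(window_um=14.8))  # 60 px > 32

    def test_vector_count_matches_tiling(self, puncta_texture):
        params = PivParams()
        stack = shifted_pair_stack(puncta_texture, (1, 0))
        (field,) = compute_piv(stack, params)
        win = params.window_px(stack)
        step = win // 2
        per_dim = len(range(params.search_margin_px,
                            200 - params.search_margin_px - win + 1, step))
        assert field.n_vectors == per_dim**2

    def test_velocity_consistent_with_displacement(self, puncta_texture):
        stack = shifted_pair_stack(puncta_texture, (2, 1))
        (field,) = compute_piv(stack, PivParams())
        np.testing.assert_allclose(
            field.vy, np.asarray(stack.px_per_frame_to_um_per_min(field.dy)), rtol=1e-12
        )


class TestFilterVectors:
    def test_speed_above_cap_invalid(self):
        # 1.2 µm/min against the 1.0 µm/min cap is removed
        dx_for_1p2 = 1.2 / 60 * 0.5 / 0.25
        field = _field([dx_for_1p2], [0.0])
        out = filter_vectors(field, PivParams(speed_cap=1.0))
        assert not out.valid.any()
        assert out.dx[0] == field.dx[0]  # values untouched

    def test_s2n_threshold_selects_exactly(self):
        field = _field([0.001, 0.001], [0.0, 0.0], s2n=[0.5, 1.5])
        out = filter_vectors(field, PivParams(s2n_threshold=1.0))
        assert list(out.valid) == [False, True]

    def test_empty_field_passes_through(self):
        field = _field([], [])
        out = filter_vectors(field, PivParams())
        assert out.n_vectors == 0

    @given(
        s2n_lo=st.floats(0.5, 2.0), s2n_hi=st.floats(0.5, 2.0),
        cap_lo=st.floats(0.1, 2.0), cap_hi=st.floats(0.1, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_filter_monotone_in_thresholds(self, s2n_lo, s2n_hi, cap_lo, cap_hi):
        """Raising s2n threshold or lowering the cap never revalidates."""
        rng = np.random.default_rng(0)
        field = _field(rng.uniform(-0.02, 0.02, 30), rng.uniform(-0.02, 0.02, 30),
                       s2n=rng.uniform(0.0, 3.0, 30))
        lo = filter_vectors(field, PivParams(s2n_threshold=min(s2n_lo, s2n_hi),
                                             speed_cap=max(cap_lo, cap_hi)))
        hi = filter_vectors(field, PivParams(s2n_threshold=max(s2n_lo, s2n_hi),
                                             speed_cap=min(cap_lo, cap_hi)))
        assert not np.any(hi.valid & ~lo.valid)


class TestDirectionalSummary:
    def test_upward_vector_in_up_quadrant(self):
        field = _field([0.0], [-1.0])
        summ = directional_summary([field])
        assert summ.quadrant_fractions["up"] == 1.0

    def test_axis_vectors_fill_all_quadrants(self):
        field = _field([1.0, -1.0, 0.0, 0.0], [0.0, 0.0, -1.0, 1.0])
        summ = directional_summary([field])
        assert all(v == pytest.approx(0.25) for v in summ.quadrant_fractions.values())

    def test_uniform_angles_quadrants_within_3sd(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(0, 2 * np.pi, 1000)
        field = _field(np.cos(theta) * 0.01, np.sin(theta) * 0.01)
        summ = directional_summary([field])
        sd = np.sqrt(0.25 * 0.75 / 1000)
        for frac in summ.quadrant_fractions.values():
            assert abs(frac - 0.25) < 3 * sd

    def test_rose_counts_sum_to_n_valid(self):
        rng = np.random.default_rng(5)
        field = _field(rng.normal(size=50) * 0.01, rng.normal(size=50) * 0.01)
        field.valid[::3] = False
        summ = directional_summary([field], rose_bins=24)
        assert summ.rose_counts.sum() == summ.n_valid == int(field.valid.sum())
        assert sum(summ.quadrant_fractions.values()) == pytest.approx(1.0)

    def test_no_valid_vectors_is_error(self):
        field = _field([1.0], [0.0])
        field.valid[:] = False
        with pytest.raises(ValueError, match="no valid vectors"):
            directional_summary([field])

    def test_boundary_angle_goes_counterclockwise(self):
        # half-open sectors: 45° starts "up", 315° (-45°) starts "right"
        assert quadrant_of(np.array([45.0]))[0] == 1
        assert quadrant_of(np.array([315.0]))[0] == 0
        assert quadrant_of(np.array([44.999]))[0] == 0
        assert quadrant_of(np.array([314.999]))[0] == 3

    def test_mean_speed_is_arithmetic_mean_of_magnitudes(self):
        field = _field([0.01, 0.03], [0.0, 0.0])
        summ = directional_summary([field])
        speeds = np.hypot(field.vx, field.vy)
        assert summ.mean_speed_um_min == pytest.approx(speeds.mean())


class TestCompareQuadrants:
    def test_perfect_fit(self):
        res = compare_quadrants([25, 25, 25, 25], [0.25] * 4)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_worked_value(self):
        res = compare_quadrants([30, 20, 25, 25], [0.25] * 4)
        assert res.statistic == pytest.approx(2.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5724, abs=1e-4)
        assert res.df == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_quadrants([1, 2, 3], [0.25] * 4)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            compare_quadrants([1, 2, 3, 4], [0.5, 0.5, 0.0, 0.0])


class TestEquivariance:
    def test_rotation_by_90_rotates_vectors(self):
        scn = FlowScenario(kind="uniform", vx=0.0, vy=-0.5, n_frames=6, seed=4)
        stack, _ = make_flow_stack(scn, pixel_size=0.25, shape=(220, 220))
        rot = CalibratedStack(np.rot90(stack.frames, k=1, axes=(1, 2)).copy(), 0.25, 0.5)
        params = PivParams(speed_cap=5.0)
        v0 = compute_piv(stack, params)
        v1 = compute_piv(rot, params)
        vy0 = np.concatenate([f.vy for f in v0]).mean()
        vx1 = np.concatenate([f.vx for f in v1]).mean()
        vy1 = np.concatenate([f.vy for f in v1]).mean()
        # upward flow becomes leftward flow under CCW array rotation
        assert vx1 == pytest.approx(vy0, rel=0.10)
        assert abs(vy1) < 0.1 * abs(vy0) + 0.02

    def test_angles_convention(self):
        assert vector_angles_deg(np.array([0.0]), np.array([-1.0]))[0] == pytest.approx(90.0)
        assert vector_angles_deg(np.array([1.0]), np.array([0.0]))[0] == pytest.approx(0.0)


class TestNoiseFloor:
    def test_zero_flow_has_no_systematic_component(self):
        """Identical underlying frames plus independent noise must yield
        pooled mean velocity components indistinguishable from zero."""
        from yolkflow.synth import NoiseModel

        scn = FlowScenario(kind="uniform", vx=0.0, vy=0.0, n_frames=8, seed=8,
                           noise=NoiseModel(photon_budget=200))
        stack, _ = make_flow_stack(scn, pixel_size=0.25, shape=(220, 220))
        fields = compute_piv(stack, PivParams(speed_cap=50.0))
        for comp in ("vx", "vy"):
            v = np.concatenate([getattr(f, comp)[f.valid] for f in fields])
            se = v.std(ddof=1) / np.sqrt(v.size)
            assert abs(v.mean()) < 4 * se + 1e-3
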