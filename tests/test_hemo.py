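import numpy as np
import pytest

from ivusffr.geometry import contours_to_centerline, label_branch_nodes, split_at_branches
from ivusffr.hemo import (
    MMHG_PA,
    BoundaryConditions,
    FluidParams,
    compute_ffr_profile,
    dichotomize,
    hyperemic_velocity,
    segment_pressure_drop,
    timi_resting_velocity,
)
from ivusffr.phantoms import StenosisSpec, VesselSpec
from ivusffr.pipeline import phantom_to_segmented
from ivusffr.suite import _bundle_without_rendering


class TestVelocities:
    @pytest.mark.parametrize(
        "path, frames, fps, expected", [(30.0, 45.0, 30.0, 20.0), (60.0, 60.0, 30.0, 30.0)]
    )
    def test_timi_arithmetic(self, path, frames, fps, expected):
        assert timi_resting_velocity(path, frames, fps) == pytest.approx(expected)

    def test_timi_zero_frames(self):
        with pytest.raises(ValueError):
            timi_resting_velocity(30.0, 0.0, 30.0)

    def test_hyperemic_factor(self):
        assert hyperemic_velocity(20.0, 2.0) == 40.0
        assert hyperemic_velocity(20.0, 1.0) == 20.0
        with pytest.raises(ValueError):
            hyperemic_velocity(20.0, 0.5)


class TestSegmentPressureDrop:
    def test_poiseuille_closed_form(self):
        # uniform r = 1.5 mm, L = 100 mm, Q = 1 mL/s: dP = 8 mu L Q / (pi r^4)
        s = np.linspace(0.0, 100.0, 201)
        area = np.full_like(s, np.pi * 1.5**2)
        expected_pa = 8 * 0.0035 * 0.1 * 1e-6 / (np.pi * (1.5e-3) ** 4)
        dp = segment_pressure_drop(s, area, 1.0)
        assert dp == pytest.approx(expected_pa / MMHG_PA, rel=1e-12)
        assert expected_pa == pytest.approx(176.0, abs=0.2)

    def test_zero_flow(self):
        s = np.linspace(0, 10, 11)
        assert segment_pressure_drop(s, np.full_like(s, 7.0), 0.0) == 0.0

    def test_expansion_loss_value(self):
        # A_s = A_d / 4, A_d = 7.069 mm^2, Q = 1 mL/s -> 525 * 9 * (Q/A_d)^2 Pa
        a_d = np.pi * 1.5**2
        s = np.array([0.0, 1.0, 2.0])
        area = np.array([a_d, a_d / 4, a_d])
        fluid = FluidParams()
        dp_total = segment_pressure_drop(s, area, 1.0, fluid, is_stenosis=True)
        dp_visc = segment_pressure_drop(s, area, 1.0, fluid, is_stenosis=False)
        expected = 0.5 * 1050 * (1e-6 / (a_d * 1e-6)) ** 2 * 9.0
        assert expected == pytest.approx(94.6, abs=0.2)
        assert (dp_total - dp_visc) * MMHG_PA == pytest.approx(expected, rel=1e-12)

    def test_bad_geometry(self):
        with pytest.raises(ValueError):
            segment_pressure_drop([0.0, 1.0], [1.0, -1.0], 1.0)


class TestFFRProfile:
    def test_no_flow_gives_unit_vffr(self, uniform_tube):
        seg, bc = uniform_tube
        result = compute_ffr_profile(seg, BoundaryConditions(pa=bc.pa, velocity=0.0))
        assert np.allclose(result.vffr, 1.0)

    def test_uniform_tube_matches_poiseuille(self, uniform_tube):
        seg, bc = uniform_tube
        result = compute_ffr_profile(seg, bc)
        assert result.distal_vffr == pytest.approx((90 - 1.32) / 90, rel=5e-3)
        assert np.all(np.diff(result.vffr) <= 1e-15)

    def test_diverting_flow_to_a_side_branch_raises_distal_vffr(self):
        # same tube geometry either way; the only change is that half the
        # flow leaves through a labeled symmetric junction at mid-length
        from ivusffr.geometry import contours_to_centerline, label_branch_nodes, split_at_branches

        n = 4096
        corr = 1.0 / np.sqrt(n * np.sin(2 * np.pi / n) / (2 * np.pi))
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        circle = np.column_stack((1.5 * corr * np.cos(t), 1.5 * corr * np.sin(t)))
        model = contours_to_centerline([circle] * 101, 1.0, 1.0)
        a0 = model.area[0]
        bc = BoundaryConditions(pa=90.0, velocity=1.0 / a0 * 1e3)  # Q = 1 mL/s

        plain = compute_ffr_profile(split_at_branches(model), bc, law="hk")
        d_sym = 3.0 * 2 ** (-3.0 / 7.0)
        labeled = label_branch_nodes(model, [50], [d_sym])
        branch = compute_ffr_profile(split_at_branches(labeled), bc, law="hk")

        # flow halves at the symmetric junction...
        assert branch.flow[-1] == pytest.approx(0.5 * branch.flow[0], rel=1e-6)
        # ...so the distal pressure loss shrinks
        assert branch.distal_vffr > plain.distal_vffr

    def test_distal_vffr_decreases_with_severity_and_velocity(self):
        vffrs = []
        for sev in (0.2, 0.4, 0.6):
            spec = VesselSpec(
                length=50.0, inlet_radius=1.6,
                stenoses=(StenosisSpec(center_s=25.0, extent=8.0, severity=sev),),
            )
            seg, _, _ = phantom_to_segmented(_bundle_without_rendering(spec), pullback_speed=0.5)
            vffrs.append(compute_ffr_profile(seg, BoundaryConditions(pa=90, velocity=250)).distal_vffr)
        assert vffrs[0] > vffrs[1] > vffrs[2]

        spec = VesselSpec(
            length=50.0, inlet_radius=1.6,
            stenoses=(StenosisSpec(center_s=25.0, extent=8.0, severity=0.5),),
        )
        seg, _, _ = phantom_to_segmented(_bundle_without_rendering(spec), pullback_speed=0.5)
        v1 = compute_ffr_profile(seg, BoundaryConditions(pa=90, velocity=150)).distal_vffr
        v2 = compute_ffr_profile(seg, BoundaryConditions(pa=90, velocity=300)).distal_vffr
        assert v2 < v1

    def test_nonphysical_pressure_aborts(self):
        spec = VesselSpec(
            length=60.0, inlet_radius=1.5,
            stenoses=(StenosisSpec(center_s=30.0, extent=8.0, severity=0.85),),
        )
        seg, _, _ = phantom_to_segmented(_bundle_without_rendering(spec), pullback_speed=0.5)
        with pytest.raises(ValueError, match="non-physical"):
            compute_ffr_profile(seg, BoundaryConditions(pa=90, velocity=400))

    def test_viscous_term_second_order_convergence(self):
        # tapered tube: analytic integral of 8 pi mu Q / A(s)^2 available in
        # closed form (A = pi r^2, r linear in s)
        mu, q = 0.0035, 1.0e-6
        r0, r1, length = 1.8e-3, 1.2e-3, 0.06
        k = (r1 - r0) / length
        exact = 8 * mu * q / np.pi * (r0**-3 - r1**-3) / (3 * k)

        def numeric(n):
            s = np.linspace(0.0, 60.0, n)
            r = 1.8 + (1.2 - 1.8) * s / 60.0
            return segment_pressure_drop(s, np.pi * r**2, 1.0) * MMHG_PA

        errs = [abs(numeric(n) - exact) for n in (26, 51, 101)]
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        assert all(3.3 < r < 4.7 for r in ratios)  # O(ds^2)


def test_dichotomize_inclusive_threshold(uniform_tube):
    seg, bc = uniform_tube
    result = compute_ffr_profile(seg, bc)
    for target, expected in [(0.79, True), (0.80, True), (0.81, False)]:
        result.pressure = result.pressure * 0 + target * bc.pa
        assert dichotomize(result) is expected
    with pytest.raises(ValueError):
        dichotomize(result, threshold=1.5)
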