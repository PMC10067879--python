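import numpy as np
import pytest

from ivusffr.fractal import LAWS
from ivusffr.phantoms import (
    BranchSpec,
    StenosisSpec,
    VesselSpec,
    make_bifurcated_tree,
    make_single_vessel,
    render_ivus_pullback,
)


class TestSingleVessel:
    def test_constant_tube(self):
        s, r, table = make_single_vessel(VesselSpec(length=60.0, inlet_radius=1.5), ds=0.5)
        assert np.allclose(r, 1.5)
        assert table == []

    def test_single_gaussian_stenosis_throat(self):
        spec = VesselSpec(
            length=60.0, inlet_radius=1.5,
            stenoses=(StenosisSpec(center_s=30.0, extent=8.0, severity=0.5),),
        )
        s, r, table = make_single_vessel(spec, ds=0.05)
        i = np.argmin(r)
        assert s[i] == pytest.approx(30.0, abs=0.05)
        assert r[i] == pytest.approx(0.75, rel=1e-6)
        assert table[0]["percent_diameter_stenosis"] == pytest.approx(50.0, abs=0.01)

    def test_two_stenoses_local_minima(self):
        # oracle: evaluate the multiplicative profile formula on a fine grid
        spec = VesselSpec(
            length=60.0, inlet_radius=1.5,
            stenoses=(
                StenosisSpec(center_s=20.0, extent=8.0, severity=0.3),
                StenosisSpec(center_s=45.0, extent=8.0, severity=0.6),
            ),
        )
        s, r, _ = make_single_vessel(spec, ds=0.01)
        near_20 = (s > 15) & (s < 25)
        near_45 = (s > 40) & (s < 50)
        assert r[near_20].min() == pytest.approx(1.05, abs=1e-3)
        assert r[near_45].min() == pytest.approx(0.60, abs=1e-3)

    def test_rejects_vanishing_lumen(self):
        # taper drains the whole inlet radius before the distal end
        spec = VesselSpec(length=60.0, inlet_radius=1.0, taper=0.02)
        with pytest.raises(ValueError, match="zero"):
            make_single_vessel(spec)

    def test_percent_ds_equals_severity_without_taper(self):
        for sev in (0.3, 0.5, 0.7):
            spec = VesselSpec(
                length=60.0, inlet_radius=1.5,
                stenoses=(StenosisSpec(center_s=30.0, extent=8.0, severity=sev),),
            )
            _, _, table = make_single_vessel(spec, ds=0.05)
            assert table[0]["percent_diameter_stenosis"] == pytest.approx(100 * sev, abs=0.05)


class TestBifurcatedTree:
    @pytest.mark.parametrize("law", ["hk", "murray", "finet"])
    @pytest.mark.parametrize("main_fraction", [0.9, 1.0, 1.1])
    def test_triplets_satisfy_law(self, law, main_fraction):
        spec = VesselSpec(
            length=60.0, inlet_radius=1.8, taper=0.005,
            branches=(
                BranchSpec(node_s=20.0, law=law, main_fraction=main_fraction),
                BranchSpec(node_s=40.0, law=law, main_fraction=main_fraction),
            ),
        )
        nodes = make_bifurcated_tree(spec)
        assert len(nodes) == 2
        for nd in nodes:
            d_back = LAWS[law].mother_diameter(nd["d_mb"], nd["d_sb"])
            assert abs(d_back / nd["d_mov"] - 1.0) < 1e-9

    def test_rejects_main_fraction_above_law_bound(self):
        spec = VesselSpec(
            length=60.0, inlet_radius=1.8,
            branches=(BranchSpec(node_s=30.0, law="hk", main_fraction=1.4),),
        )
        with pytest.raises(ValueError, match="bound"):
            make_bifurcated_tree(spec)


class TestRenderedPullback:
    def test_mask_area_matches_disk(self):
        spec = VesselSpec(length=10.0, inlet_radius=1.5)
        b = render_ivus_pullback(spec, pixel_size=0.05, frame_size=128, noise_amplitude=0.0)
        expected = np.pi * 1.5**2 / 0.05**2  # ~2827 px
        for mask in b.lumen_masks:
            assert abs(mask.sum() / expected - 1.0) < 0.03

    def test_mask_derived_radius_recovers_profile_within_one_pixel(self):
        spec = VesselSpec(
            length=30.0, inlet_radius=1.6, taper=0.01,
            stenoses=(StenosisSpec(center_s=15.0, extent=8.0, severity=0.4),),
        )
        b = render_ivus_pullback(spec, pixel_size=0.05, frame_size=128)
        r_mask = np.sqrt(b.lumen_masks.sum(axis=(1, 2)) / np.pi) * b.pixel_size
        r_true = np.interp(b.frame_arclengths(), b.s, b.radius)
        assert np.max(np.abs(r_mask - r_true)) < b.pixel_size

    def test_zero_noise_gives_piecewise_constant_rings(self):
        spec = VesselSpec(length=5.0, inlet_radius=1.2)
        b = render_ivus_pullback(spec, frame_size=96, noise_amplitude=0.0)
        assert len(np.unique(b.frames[0])) <= 3

    def test_determinism(self):
        spec = VesselSpec(length=10.0, inlet_radius=1.2, seed=9)
        b1 = render_ivus_pullback(spec, frame_size=96)
        b2 = render_ivus_pullback(spec, frame_size=96)
        assert np.array_equal(b1.frames, b2.frames)

    def test_lumen_too_large_for_frame(self):
        spec = VesselSpec(length=5.0, inlet_radius=2.0)
        with pytest.raises(ValueError, match="fit"):
            render_ivus_pullback(spec, pixel_size=0.05, frame_size=64)

    def test_contours_have_exact_disk_area(self):
        from shapely.geometry import Polygon

        spec = VesselSpec(length=10.0, inlet_radius=1.4)
        b = render_ivus_pullback(spec, frame_size=96)
        poly = Polygon(b.contours(n_vertices=128)[0])
        assert poly.area == pytest.approx(np.pi * 1.4**2, rel=1e-9)
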