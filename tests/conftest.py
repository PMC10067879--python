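import numpy as np
import pytest

from ivusffr.hemo import BoundaryConditions
from ivusffr.phantoms import StenosisSpec, VesselSpec
from ivusffr.pipeline import phantom_to_segmented
from ivusffr.suite import _bundle_without_rendering


@pytest.fixture(scope="session")
def uniform_tube():
    """r = 1.5 mm, L = 100 mm tube segmented at 0.5 mm spacing, with the
    boundary conditions that drive exactly Q = 1 mL/s through it."""
    spec = VesselSpec(length=100.0, inlet_radius=1.5)
    bundle = _bundle_without_rendering(spec)
    seg, _, _ = phantom_to_segmented(bundle, pullback_speed=0.5)
    a0 = seg.pieces[0].area[0]  # mm^2
    bc = BoundaryConditions(pa=90.0, velocity=1.0 / a0 * 1e3)  # Q = 1 mL/s
    return seg, bc


@pytest.fixture(scope="session")
def stenosed_bundle():
    """Tapered vessel with one 50 % stenosis at s = 30 mm."""
    spec = VesselSpec(
        length=60.0,
        inlet_radius=1.8,
        taper=0.008,
        stenoses=(StenosisSpec(center_s=30.0, extent=8.0, severity=0.5),),
        seed=11,
    )
    return _bundle_without_rendering(spec)


@pytest.fixture(scope="session")
def overfit_frames():
    """Ten rendered 64x64 frames with ground-truth lumen/MA masks."""
    from ivusffr.phantoms import render_ivus_pullback

    spec = VesselSpec(
        length=45.0,
        inlet_radius=1.1,
        taper=0.004,
        stenoses=(StenosisSpec(center_s=22.0, extent=10.0, severity=0.45),),
        seed=3,
    )
    bundle = render_ivus_pullback(spec, frame_size=64, frame_spacing=5.0, noise_amplitude=0.10)
    frames = bundle.frames[:10]
    masks = np.stack([bundle.lumen_masks[:10], bundle.ma_masks[:10]], axis=1)
    return bundle, frames, masks
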