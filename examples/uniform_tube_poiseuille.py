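"""Closed-form sanity check: virtual FFR of an unobstructed uniform tube.

A straight tube of radius 1.5 mm and length 100 mm carrying 1 mL/s of blood
loses pressure only to viscous friction, for which Hagen-Poiseuille gives
dP = 8 mu L Q / (pi r^4) ~ 1.32 mmHg.  At a mean aortic pressure of 90 mmHg
the distal vFFR should therefore be (90 - 1.32)/90 ~ 0.985.
"""

import numpy as np

from ivusffr.hemo import BoundaryConditions, compute_ffr_profile
from ivusffr.phantoms import VesselSpec
from ivusffr.pipeline import phantom_to_segmented
from ivusffr.suite import _bundle_without_rendering

spec = VesselSpec(length=100.0, inlet_radius=1.5)
seg, _, _ = phantom_to_segmented(_bundle_without_rendering(spec), pullback_speed=0.5)

a0 = seg.pieces[0].area[0]  # mm^2
bc = BoundaryConditions(pa=90.0, velocity=1.0 / a0 * 1e3)  # velocity for Q = 1 mL/s
result = compute_ffr_profile(seg, bc)

dp_pa = 8 * 0.0035 * 0.1 * 1e-6 / (np.pi * 1.5e-3**4)
expected = (90.0 - dp_pa / 133.322) / 90.0

print(f"inlet flow:          {result.flow[0]:.3f} mL/s")
print(f"computed distal vFFR: {result.distal_vffr:.5f}")
print(f"Poiseuille oracle:    {expected:.5f}")
print(f"relative error:       {abs(result.distal_vffr / expected - 1):.2e}")
print("A healthy vessel loses almost no pressure: vFFR stays near 1.")
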