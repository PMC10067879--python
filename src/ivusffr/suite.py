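"""Seeded phantom suites: the standing study conditions for evaluation.

Two suites are defined once and reused by the tests, the examples and the
acceptance script:

* ``phantom_suite`` — bifurcated, law-consistent vessels for the
  single-tube-fractal vs explicit-branch method comparison.  Dimensions and
  boundary conditions are drawn from ranges a coronary physiologist would
  call typical: 50-80 mm analysed length, 1.6-2.1 mm inlet radius, mild
  diffuse taper, one or two focal stenoses of 30-70 % diameter, one or two
  bifurcations, mean aortic pressure 85-100 mmHg, resting velocity
  120-200 mm/s doubled under hyperemia.
* ``stenosis_suite`` — single-tube tapered vessels with one programmed
  stenosis and 2 % multiplicative radius noise on the measured contours,
  for detector-recovery evaluation.
"""

from __future__ import annotations

import numpy as np

from .geometry import CenterlineModel, contours_to_centerline
from .hemo import BoundaryConditions, hyperemic_velocity
from .phantoms import BranchSpec, PhantomBundle, StenosisSpec, VesselSpec, make_single_vessel
from .pipeline import phantom_to_segmented

__all__ = ["phantom_suite", "stenosis_suite"]


def _bundle_without_rendering(spec: VesselSpec, frame_spacing: float = 0.5) -> PhantomBundle:
    """Geometry-only bundle (no image rendering) for solver-level suites."""
    from .phantoms import make_bifurcated_tree

    s, r, table = make_single_vessel(spec, ds=0.1)
    n_frames = int(np.floor(spec.length / frame_spacing)) + 1
    empty = np.zeros((n_frames, 1, 1), dtype=np.float32)
    return PhantomBundle(
        spec=spec, s=s, radius=r, branch_nodes=make_bifurcated_tree(spec),
        stenosis_table=table, frames=empty,
        lumen_masks=empty.astype(np.uint8), ma_masks=empty.astype(np.uint8),
        pixel_size=0.05, frame_spacing=frame_spacing,
    )


def phantom_suite(n: int = 20, seed: int = 0, law: str = "hk"):
    """Law-consistent bifurcated vessels with boundary conditions.

    Returns a list of ``(SegmentedCenterline, BoundaryConditions)`` pairs,
    ready for both the single-tube and the network solver.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    attempts = 0
    while len(pairs) < n and attempts < 50 * n:
        attempts += 1
        length = rng.uniform(50.0, 80.0)
        inlet_r = rng.uniform(1.6, 2.1)
        taper = rng.uniform(0.004, 0.010)
        n_sten = int(rng.integers(1, 3))
        n_branch = int(rng.integers(1, 3))
        # keep stenoses and junctions separated so pieces stay well formed
        slots = np.sort(rng.uniform(0.15, 0.85, size=n_sten + n_branch)) * length
        while np.min(np.diff(slots, prepend=0.0)) < 8.0:
            slots = np.sort(rng.uniform(0.15, 0.85, size=n_sten + n_branch)) * length
        which = rng.permutation(n_sten + n_branch)
        stenoses, branches = [], []
        for pos, k in zip(slots, which):
            if k < n_sten:
                # 30-70 % diameter stenoses: the angiographic inclusion range
                # of intermediate lesions referred for FFR
                stenoses.append(
                    StenosisSpec(
                        center_s=float(pos),
                        extent=float(rng.uniform(6.0, 12.0)),
                        severity=float(rng.uniform(0.3, 0.7)),
                    )
                )
            else:
                # D_sb/D_mb roughly 0.7-1.1: side branches of real coronary
                # bifurcations are at most comparable to, usually smaller
                # than, the continuing main branch
                branches.append(
                    BranchSpec(
                        node_s=float(pos), law=law,
                        main_fraction=float(rng.uniform(0.95, 1.15)),
                        stub_length=float(rng.uniform(4.0, 8.0)),
                    )
                )
        spec = VesselSpec(
            length=float(length), inlet_radius=float(inlet_r), taper=float(taper),
            stenoses=tuple(stenoses), branches=tuple(branches),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bc = BoundaryConditions(
            pa=float(rng.uniform(85.0, 100.0)),
            velocity=hyperemic_velocity(float(rng.uniform(100.0, 160.0)), 2.0),
        )
        try:
            bundle = _bundle_without_rendering(spec)
            seg, _, _ = phantom_to_segmented(bundle, pullback_speed=0.5)
            # the steady fixed-inflow closure cannot represent flow-limiting
            # lesions; a draw whose predicted distal pressure is non-positive
            # is outside the model's validity and is redrawn
            from .hemo import compute_ffr_profile

            compute_ffr_profile(seg, bc, law=law)
        except ValueError:
            continue
        pairs.append((seg, bc))
    return pairs


def stenosis_suite(n: int = 20, seed: int = 0, radius_noise_frac: float = 0.02):
    """Tapered single-tube vessels, one stenosis each, noisy measured radii.

    Returns a list of ``(CenterlineModel, truth)`` with ``truth`` the
    programmed throat location and percent diameter stenosis.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = VesselSpec(
            length=60.0,
            inlet_radius=float(rng.uniform(1.5, 2.0)),
            taper=float(rng.uniform(0.004, 0.012)),
            stenoses=(
                StenosisSpec(
                    center_s=float(rng.uniform(15.0, 45.0)),
                    extent=float(rng.uniform(6.0, 10.0)),
                    severity=float(rng.uniform(0.3, 0.7)),
                ),
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bundle = _bundle_without_rendering(spec)
        contours = bundle.contours(
            radius_noise_frac=radius_noise_frac,
            rng=np.random.default_rng(spec.seed + 1),
        )
        model = contours_to_centerline(contours, 0.5, 1.0)
        out.append((model, bundle.stenosis_table[0]))
    return out
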