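"""Synthetic vessel, bifurcation-tree and IVUS pullback phantoms.

Every test in this package runs on phantoms generated here: tapering vessels
with programmed Gaussian- or cosine-shaped stenoses, bifurcation nodes whose
daughter diameters satisfy a chosen fractal law exactly, and IVUS-like
grayscale frames (dark lumen disk, bright media-adventitia annulus,
multiplicative speckle) with exact ground-truth masks.

The radius profile is multiplicative:

    r(s) = (inlet_radius - taper * s) * prod_k (1 - severity_k * shape_k(s))
           * prod_j step_j(s)

where ``shape_k`` is 1 at the stenosis throat and ``step_j`` is the smooth
diameter step-down (D_mb / D_mov) that a real vessel shows distal to each
bifurcation.  Frames are rendered distal -> proximal, the acquisition order
of a motorized pullback.

This is a geometric phantom, not an ultrasound simulator: no ray physics,
no NURD or motion artifacts, no guidewire shadow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fractal import FractalLaw, get_law

__all__ = [
    "StenosisSpec",
    "BranchSpec",
    "VesselSpec",
    "PhantomBundle",
    "make_single_vessel",
    "make_bifurcated_tree",
    "make_phantom",
    "render_ivus_pullback",
]


@dataclass(frozen=True)
class StenosisSpec:
    """One programmed narrowing.

    severity is the fractional diameter reduction at the throat (0.5 -> 50%
    diameter stenosis against the local healthy lumen); extent is the full
    width of the narrowing along the vessel.
    """

    center_s: float  # mm
    extent: float  # mm
    severity: float  # in (0, 1)
    shape: str = "gaussian"  # or "cosine"

    def __post_init__(self):
        if not 0 < self.severity < 1:
            raise ValueError("severity must be in (0, 1)")
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        if self.shape not in ("gaussian", "cosine"):
            raise ValueError("shape must be 'gaussian' or 'cosine'")

    def profile(self, s) -> np.ndarray:
        """Shape function in [0, 1], equal to 1 at the throat."""
        s = np.asarray(s, dtype=float)
        if self.shape == "gaussian":
            sigma = self.extent / 4.0
            return np.exp(-((s - self.center_s) ** 2) / (2.0 * sigma**2))
        x = s - self.center_s
        out = 0.5 * (1.0 + np.cos(2.0 * np.pi * x / self.extent))
        return np.where(np.abs(x) <= self.extent / 2.0, out, 0.0)


@dataclass(frozen=True)
class BranchSpec:
    """One bifurcation node.

    main_fraction scales the main-branch diameter relative to the law's
    symmetric split (1.0 -> symmetric daughters); stub_length is used by the
    explicit-branch comparator model.
    """

    node_s: float  # mm
    law: str = "hk"
    main_fraction: float = 1.0
    stub_length: float = 5.0  # mm

    def __post_init__(self):
        # > 1 means a main branch larger than the symmetric solution, i.e. a
        # side branch smaller than the main — the anatomically common case.
        # The law-specific upper bound (D_sb must stay positive) is enforced
        # when the tree is built against the local mother diameter.
        if self.main_fraction <= 0:
            raise ValueError("main_fraction must be positive")
        get_law(self.law)


@dataclass(frozen=True)
class VesselSpec:
    length: float  # mm
    inlet_radius: float  # mm
    taper: float = 0.0  # mm radius loss per mm, >= 0
    stenoses: tuple[StenosisSpec, ...] = ()
    branches: tuple[BranchSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "stenoses", tuple(self.stenoses))
        object.__setattr__(
            self, "branches", tuple(sorted(self.branches, key=lambda b: b.node_s))
        )
        if self.length <= 0 or self.inlet_radius <= 0 or self.taper < 0:
            raise ValueError("invalid vessel dimensions")
        for st in self.stenoses:
            if not 0 <= st.center_s <= self.length:
                raise ValueError("stenosis center outside vessel")
        for br in self.branches:
            if not 0 < br.node_s < self.length:
                raise ValueError("branch node must be strictly inside the vessel")


_STEP_WIDTH = 1.0  # mm, smooth diameter transition across a bifurcation


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _healthy_radius(spec: VesselSpec, s: np.ndarray, branch_factors) -> np.ndarray:
    """Taper line times bifurcation step-downs (no stenoses)."""
    r = spec.inlet_radius - spec.taper * np.asarray(s, dtype=float)
    for br, f in branch_factors:
        t = _smoothstep((np.asarray(s) - (br.node_s - _STEP_WIDTH / 2)) / _STEP_WIDTH)
        r = r * (1.0 + (f - 1.0) * t)
    return r


def _branch_factors(spec: VesselSpec):
    """Per-branch (spec, D_mb/D_mov) factors plus the ground-truth node table.

    Processed proximal -> distal so each node's mother diameter includes the
    step-downs of all upstream nodes.
    """
    factors: list[tuple[BranchSpec, float]] = []
    nodes = []
    for br in spec.branches:
        law: FractalLaw = get_law(br.law)
        s_prox = np.array([br.node_s - _STEP_WIDTH / 2])
        d_mov = 2.0 * float(_healthy_radius(spec, s_prox, factors)[0])
        d_mb = br.main_fraction * law.symmetric_daughter(d_mov)
        if d_mb >= law.d_mb_bound(d_mov):
            raise ValueError(
                f"branch at s={br.node_s}: main_fraction {br.main_fraction} puts "
                f"D_mb at/above the {law.name} bound (D_sb would be <= 0)"
            )
        d_sb = law.solve_side_branch(d_mov, d_mb)
        if d_sb <= 0 or d_mb <= 0:
            raise ValueError(f"branch at s={br.node_s}: non-positive daughter diameter")
        factors.append((br, d_mb / d_mov))
        nodes.append(
            {"s": br.node_s, "d_mov": d_mov, "d_mb": d_mb, "d_sb": d_sb,
             "law": law.name, "stub_length": br.stub_length}
        )
    return factors, nodes


def radius_profile(spec: VesselSpec, s) -> np.ndarray:
    """Ground-truth lumen radius r(s), mm."""
    s = np.asarray(s, dtype=float)
    factors, _ = _branch_factors(spec)
    r = _healthy_radius(spec, s, factors)
    for st in spec.stenoses:
        r = r * (1.0 - st.severity * st.profile(s))
    return r


def make_single_vessel(spec: VesselSpec, ds: float = 0.1):
    """Sample the radius profile and tabulate ground-truth stenoses.

    Returns ``(s, r, table)`` with s proximal -> distal at spacing ``ds`` and
    one table row per programmed stenosis: throat location and percent
    diameter stenosis against the local healthy reference.
    """
    if ds <= 0:
        raise ValueError("ds must be positive")
    s = np.arange(0.0, spec.length + ds / 2, ds)
    r = radius_profile(spec, s)
    if np.any(r <= 0):
        raise ValueError("programmed radius profile reaches zero; reject spec")
    factors, _ = _branch_factors(spec)
    healthy = _healthy_radius(spec, s, factors)
    table = []
    for st in spec.stenoses:
        i = int(np.argmin(np.abs(s - st.center_s)))
        table.append(
            {
                "throat_s": float(s[i]),
                "percent_diameter_stenosis": 100.0 * (1.0 - r[i] / healthy[i]),
                "severity": st.severity,
                "extent": st.extent,
            }
        )
    return s, r, table


def make_bifurcated_tree(spec: VesselSpec):
    """Ground-truth branch-node table with law-consistent daughter diameters.

    Each row carries (s, D_mov, D_mb, D_sb); the triplet satisfies the node's
    fractal law exactly by construction.
    """
    _, nodes = _branch_factors(spec)
    return nodes


@dataclass
class PhantomBundle:
    """Everything one synthetic pullback provides: geometry ground truth,
    rendered frames and exact masks. Frames/masks are distal -> proximal;
    ``s``/``radius`` are proximal -> distal."""

    spec: VesselSpec
    s: np.ndarray  # mm, proximal -> distal
    radius: np.ndarray  # mm, ground truth r(s)
    branch_nodes: list
    stenosis_table: list
    frames: np.ndarray  # (n, H, W) float in [0,1], distal -> proximal
    lumen_masks: np.ndarray  # (n, H, W) uint8
    ma_masks: np.ndarray  # (n, H, W) uint8
    pixel_size: float  # mm / px
    frame_spacing: float  # mm between frames
    wall_thickness: float = 0.5

    def frame_arclengths(self) -> np.ndarray:
        """s of each frame, in stack (distal -> proximal) order."""
        n = len(self.frames)
        return self.spec.length - np.arange(n) * self.frame_spacing

    def contours(self, n_vertices: int = 256, radius_noise_frac: float = 0.0,
                 rng: np.random.Generator | None = None):
        """Analytic per-frame lumen contours (mm), distal -> proximal.

        Circle radii are corrected so the polygon area equals the true disk
        area exactly; optional multiplicative per-frame radius noise emulates
        segmentation error.
        """
        if rng is None:
            rng = np.random.default_rng(self.spec.seed + 1)
        # inscribed n-gon area deficit correction
        corr = 1.0 / np.sqrt(n_vertices * np.sin(2 * np.pi / n_vertices) / (2 * np.pi))
        theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        out = []
        for s_f in self.frame_arclengths():
            r = float(np.interp(s_f, self.s, self.radius)) * corr
            if radius_noise_frac > 0:
                r *= 1.0 + radius_noise_frac * rng.standard_normal()
            out.append(np.column_stack((r * np.cos(theta), r * np.sin(theta))))
        return out


def render_ivus_pullback(
    spec: VesselSpec,
    *,
    pixel_size: float = 0.05,
    frame_size: int = 128,
    frame_spacing: float = 1.0,
    wall_thickness: float = 0.5,
    noise_amplitude: float = 0.15,
    lumen_intensity: float = 0.20,
    wall_intensity: float = 0.85,
    background_intensity: float = 0.45,
    seed: int | None = None,
) -> PhantomBundle:
    """Render the IVUS-like image stack for a vessel spec.

    Each frame is a bright media-adventitia annulus (lumen radius to lumen
    radius + wall thickness) around a darker lumen disk, with multiplicative
    Gaussian speckle; masks are the exact rasterized disk (lumen) and outer
    disk (region inside the MA border). Same seed -> bit-identical stack.
    """
    if seed is None:
        seed = spec.seed
    s, r, table = make_single_vessel(spec, ds=min(0.1, frame_spacing / 2))
    nodes = make_bifurcated_tree(spec)
    n_frames = int(np.floor(spec.length / frame_spacing)) + 1
    s_frames = spec.length - np.arange(n_frames) * frame_spacing  # distal -> proximal

    half = frame_size * pixel_size / 2.0
    max_r = float(np.interp(s_frames, s, r).max())
    if max_r >= half:
        raise ValueError(
            f"lumen radius {max_r:.2f} mm does not fit a {frame_size} px frame "
            f"at {pixel_size} mm/px (half-width {half:.2f} mm)"
        )

    yy, xx = np.mgrid[0:frame_size, 0:frame_size]
    c = (frame_size - 1) / 2.0
    dist_mm = np.hypot(xx - c, yy - c) * pixel_size

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, frame_size, frame_size), dtype=np.float32)
    lumen = np.empty_like(frames, dtype=np.uint8)
    ma = np.empty_like(lumen)
    for k, s_f in enumerate(s_frames):
        r_f = float(np.interp(s_f, s, r))
        img = np.full((frame_size, frame_size), background_intensity, dtype=np.float64)
        img[dist_mm <= r_f + wall_thickness] = wall_intensity
        img[dist_mm <= r_f] = lumen_intensity
        if noise_amplitude > 0:
            img = img * (1.0 + noise_amplitude * rng.standard_normal(img.shape))
        frames[k] = np.clip(img, 0.0, 1.0)
        lumen[k] = (dist_mm <= r_f).astype(np.uint8)
        ma[k] = (dist_mm <= r_f + wall_thickness).astype(np.uint8)

    return PhantomBundle(
        spec=spec,
        s=s,
        radius=r,
        branch_nodes=nodes,
        stenosis_table=table,
        frames=frames,
        lumen_masks=lumen,
        ma_masks=ma,
        pixel_size=pixel_size,
        frame_spacing=frame_spacing,
        wall_thickness=wall_thickness,
    )


def make_phantom(spec: VesselSpec, **render_kwargs) -> PhantomBundle:
    """Convenience alias: render the full bundle for a spec."""
    return render_ivus_pullback(spec, **render_kwargs)
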