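"""Reduced-order hemodynamics: per-segment pressure drop and the virtual FFR
profile.

The pressure field along the reconstructed vessel is obtained by marching a
steady reduced-order model from the proximal inlet to the distal end.  The
per-segment closure is the standard stenosis pressure-drop model of the
Young–Tsai family:

* a viscous (Poiseuille) term integrated along the segment,
  ``dP_visc = int 8 pi mu Q / A(s)^2 ds``, exact for fully developed laminar
  flow in a slowly varying tube, and
* a Bernoulli-type expansion loss charged once per stenosis,
  ``dP_exp = (rho K_t / 2) (Q/A_d)^2 (A_d/A_s - 1)^2``, with ``A_s`` the
  throat area and ``A_d`` the area at the downstream recovery point,
  representing the kinetic energy lost in the post-stenotic jet.

Flow is piecewise constant between junctions; at each labeled bifurcation the
flow is reduced by the configured fractal law's split (the side branch is not
imaged, so its take-off is inferred from diameters alone).  The inlet carries
the mean aortic pressure Pa and the hyperemic velocity; the outlet is treated
as fully developed outflow, i.e. no added outlet resistance.  Virtual FFR at
any point is P(s)/Pa; the distal value against the 0.80 cutoff gives the
ischemia call.

Unit policy: SI internally (Pa, m, m^3/s); mmHg / mm / mL/s at every public
interface; 1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fractal import junction_flow_split
from .geometry import SegmentedCenterline

__all__ = [
    "MMHG_PA",
    "FluidParams",
    "BoundaryConditions",
    "FFRResult",
    "timi_resting_velocity",
    "hyperemic_velocity",
    "segment_pressure_drop",
    "compute_ffr_profile",
    "dichotomize",
]

MMHG_PA = 133.322  # Pa per mmHg


@dataclass(frozen=True)
class FluidParams:
    """Blood model constants.

    viscosity: dynamic viscosity mu, Pa*s (0.0035 = typical blood at high shear)
    density:   rho, kg/m^3
    k_t:       dimensionless expansion-loss coefficient of the Bernoulli term
    """

    viscosity: float = 0.0035
    density: float = 1050.0
    k_t: float = 1.0

    def __post_init__(self):
        if min(self.viscosity, self.density, self.k_t) <= 0:
            raise ValueError("fluid parameters must be positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Inlet boundary conditions for the marching solve.

    pa: mean aortic pressure, mmHg (inlet pressure)
    velocity: hyperemic inlet blood velocity, mm/s
    hyperemia_factor: rest->hyperemia multiplier used when the velocity was
        derived from a resting (TIMI) measurement; recorded for provenance.
    """

    pa: float  # mmHg
    velocity: float  # mm/s, hyperemic
    hyperemia_factor: float = 2.0
    fluid: FluidParams = field(default_factory=FluidParams)

    def __post_init__(self):
        if self.pa <= 0:
            raise ValueError("aortic pressure must be positive")
        if self.velocity < 0:
            raise ValueError("inlet velocity must be >= 0")


def timi_resting_velocity(path_length: float, frame_count: float, frame_rate: float) -> float:
    """Resting flow velocity from TIMI frame counting.

    Contrast traverses ``path_length`` mm in ``frame_count`` angiographic
    frames at ``frame_rate`` fps: v = path_length * frame_rate / frame_count
    (mm/s).
    """
    if path_length <= 0 or frame_count <= 0 or frame_rate <= 0:
        raise ValueError("path_length, frame_count and frame_rate must be positive")
    return path_length * frame_rate / frame_count


def hyperemic_velocity(v_rest: float, factor: float = 2.0) -> float:
    """Convert resting to hyperemic velocity by an empirical multiplier.

    The multiplier models adenosine-induced maximal vasodilation; it is
    configurable because published rest->hyperemia conversions vary.
    """
    if factor < 1:
        raise ValueError("hyperemia factor must be >= 1 (hyperemia increases flow)")
    if v_rest < 0:
        raise ValueError("resting velocity must be >= 0")
    return factor * v_rest


def _viscous_drop_pa(s_mm: np.ndarray, area_mm2: np.ndarray, q_ml_s: float, mu: float) -> np.ndarray:
    """Cumulative viscous pressure drop (Pa) at each sample, trapezoid rule."""
    s = np.asarray(s_mm, dtype=float) * 1e-3
    a = np.asarray(area_mm2, dtype=float) * 1e-6
    q = q_ml_s * 1e-6
    integrand = 8.0 * np.pi * mu * q / a**2
    mids = 0.5 * (integrand[1:] + integrand[:-1]) * np.diff(s)
    return np.concatenate(([0.0], np.cumsum(mids)))


def expansion_drop_pa(a_throat_mm2: float, a_distal_mm2: float, q_ml_s: float, fluid: FluidParams) -> float:
    """Bernoulli expansion loss (Pa) across one stenosis, throat -> recovery."""
    a_s = a_throat_mm2 * 1e-6
    a_d = a_distal_mm2 * 1e-6
    q = q_ml_s * 1e-6
    return 0.5 * fluid.density * fluid.k_t * (q / a_d) ** 2 * (a_d / a_s - 1.0) ** 2


def segment_pressure_drop(
    s_mm,
    area_mm2,
    q_ml_s: float,
    fluid: FluidParams = FluidParams(),
    *,
    is_stenosis: bool = False,
) -> float:
    """Total pressure drop (mmHg) across one piece at flow ``q_ml_s``.

    The viscous term is always integrated over the samples; the expansion
    term is added only for stenosis pieces (charged once, throat to the
    piece's distal recovery point), so smooth tapers are never double
    charged.
    """
    s = np.asarray(s_mm, dtype=float)
    a = np.asarray(area_mm2, dtype=float)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(a)) and np.all(a > 0)):
        raise ValueError("non-finite or non-positive geometry")
    if q_ml_s < 0:
        raise ValueError("flow must be >= 0")
    dp = _viscous_drop_pa(s, a, q_ml_s, fluid.viscosity)[-1]
    if is_stenosis:
        dp += expansion_drop_pa(float(a.min()), float(a[-1]), q_ml_s, fluid)
    return float(dp / MMHG_PA)


@dataclass
class FFRResult:
    """Pressure and virtual FFR along the centerline.

    P(s) in mmHg, Q(s) in mL/s (piecewise constant between junctions),
    vffr(s) = P(s)/Pa.  ``ischemic`` uses the 0.80 cutoff on the distal value.
    """

    s: np.ndarray
    pressure: np.ndarray  # mmHg
    flow: np.ndarray  # mL/s at each sample
    pa: float
    law: str

    @property
    def vffr(self) -> np.ndarray:
        return self.pressure / self.pa

    @property
    def distal_vffr(self) -> float:
        return float(self.vffr[-1])

    @property
    def ischemic(self) -> bool:
        return dichotomize(self)

    def to_dict(self) -> dict:
        return {
            "s_mm": self.s.tolist(),
            "pressure_mmhg": self.pressure.tolist(),
            "flow_ml_s": self.flow.tolist(),
            "vffr": self.vffr.tolist(),
            "pa_mmhg": self.pa,
            "law": self.law,
            "distal_vffr": self.distal_vffr,
            "ischemic": bool(self.ischemic),
        }


def compute_ffr_profile(
    seg: SegmentedCenterline,
    bc: BoundaryConditions,
    law: str = "hk",
) -> FFRResult:
    """March the reduced-order model proximal -> distal over the pieces.

    P(0) = Pa and Q(0) = V * A(0).  Normal and stenosis pieces subtract their
    pressure drop at the current flow (stenosis pieces include the expansion
    loss at their distal boundary).  A junction piece is traversed at the
    mother flow; at its distal boundary the flow drops to the main-branch
    share of the configured fractal law.  No outlet resistance is applied
    (fully developed outflow).
    """
    fluid = bc.fluid
    a0 = seg.pieces[0].area[0]  # mm^2
    q = bc.velocity * 1e-3 * a0 * 1e-6 * 1e6  # mm/s * mm^2 -> mL/s
    p = bc.pa  # mmHg

    s_out: list[np.ndarray] = []
    p_out: list[np.ndarray] = []
    q_out: list[np.ndarray] = []
    for piece in seg.pieces:
        cum = _viscous_drop_pa(piece.s, piece.area, q, fluid.viscosity) / MMHG_PA
        p_piece = p - cum
        if piece.kind == "stenosis":
            p_piece = p_piece.copy()
            p_piece[-1] -= expansion_drop_pa(float(piece.area.min()), float(piece.area[-1]), q, fluid) / MMHG_PA
        s_out.append(piece.s)
        p_out.append(p_piece)
        q_out.append(np.full_like(piece.s, q))
        p = float(p_piece[-1])
        if p <= 0:
            raise ValueError(
                f"non-physical solution: pressure fell to {p:.3g} mmHg at s={piece.s_end:.1f} mm"
            )
        if piece.kind == "junction":
            node = piece.node
            q = junction_flow_split(q, node.d_mov, node.d_mb, law).q_mb

    # merge pieces, dropping the duplicated boundary samples
    s_all = [s_out[0]]
    p_all = [p_out[0]]
    q_all = [q_out[0]]
    for si, pi, qi in zip(s_out[1:], p_out[1:], q_out[1:]):
        s_all.append(si[1:])
        p_all.append(pi[1:])
        q_all.append(qi[1:])
    return FFRResult(
        s=np.concatenate(s_all),
        pressure=np.concatenate(p_all),
        flow=np.concatenate(q_all),
        pa=bc.pa,
        law=law if isinstance(law, str) else law.name,
    )


def dichotomize(result: FFRResult, threshold: float = 0.80) -> bool:
    """Ischemia call: True iff distal vFFR <= threshold (inclusive cutoff)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return bool(result.distal_vffr <= threshold)
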