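"""Bifurcation fractal scaling laws.

A coronary bifurcation relates the mother-vessel diameter ``D_mov`` to the
daughter diameters ``D_mb`` (main branch, the vessel the pullback continues
into) and ``D_sb`` (side branch, unimaged).  Three empirical laws are
supported:

======  =============================================  ==================
name    diameter relation                              flow rule
======  =============================================  ==================
HK      D_mov^(7/3) = D_mb^(7/3) + D_sb^(7/3)          Q proportional D^(7/3)
Murray  D_mov^3     = D_mb^3     + D_sb^3              Q proportional D^3
Finet   D_mov       = 0.678 (D_mb + D_sb)              Q proportional D
======  =============================================  ==================

Given the two diameters visible in a single-tube IVUS reconstruction
(``D_mov`` just proximal of the junction and ``D_mb`` just distal), each law
yields the invisible side-branch diameter and hence the fraction of flow that
leaves through the side branch.  Finet's law is a diameter relation only; its
flow rule here is the linear ``Q ~ D`` split applied to the inferred daughter
pair, the simplest rule consistent with the law (an interpretation, since no
flow rule is part of the original relation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "FractalLaw",
    "JunctionFlow",
    "get_law",
    "infer_side_branch_diameter",
    "junction_flow_split",
    "LAWS",
]

FINET_COEFF = 0.678


@dataclass(frozen=True)
class FractalLaw:
    """One bifurcation scaling law: diameter relation plus flow rule."""

    name: str
    exponent: float | None  # power-law exponent; None for Finet's linear law

    def symmetric_daughter(self, d_mov: float) -> float:
        """Daughter diameter of the symmetric split (D_mb == D_sb)."""
        if self.exponent is not None:
            return d_mov * 2.0 ** (-1.0 / self.exponent)
        return d_mov / FINET_COEFF / 2.0

    def d_mb_bound(self, d_mov: float) -> float:
        """Supremum of admissible D_mb (above it D_sb would be <= 0)."""
        if self.exponent is not None:
            return d_mov
        return d_mov / FINET_COEFF

    def solve_side_branch(self, d_mov: float, d_mb: float) -> float:
        if self.exponent is not None:
            k = self.exponent
            return (d_mov**k - d_mb**k) ** (1.0 / k)
        return d_mov / FINET_COEFF - d_mb

    def flow_weight(self, d: float) -> float:
        """Unnormalised flow carried by a daughter of diameter ``d``."""
        if self.exponent is not None:
            return d**self.exponent
        return d

    def mother_diameter(self, d_mb: float, d_sb: float) -> float:
        """Re-substitute a daughter pair into the relation (consistency check)."""
        if self.exponent is not None:
            k = self.exponent
            return (d_mb**k + d_sb**k) ** (1.0 / k)
        return FINET_COEFF * (d_mb + d_sb)


LAWS: dict[str, FractalLaw] = {
    "hk": FractalLaw("hk", 7.0 / 3.0),
    "murray": FractalLaw("murray", 3.0),
    "finet": FractalLaw("finet", None),
}


def get_law(law: str | FractalLaw) -> FractalLaw:
    if isinstance(law, FractalLaw):
        return law
    try:
        return LAWS[law.lower()]
    except KeyError:
        raise ValueError(f"unknown fractal law {law!r}; choose from {sorted(LAWS)}") from None


def infer_side_branch_diameter(
    d_mov: float, d_mb: float, law: str | FractalLaw = "hk", *, strict: bool = False
) -> float:
    """Side-branch diameter implied by the law, from the two visible diameters.

    Parameters
    ----------
    d_mov, d_mb
        Mother and main-branch diameters (mm), measured at the two ends of the
        junction.
    law
        ``"hk"`` (default), ``"murray"`` or ``"finet"``.
    strict
        If False (default), a measured ``d_mb`` at or above the law's
        admissible bound (possible with noisy measurements) is clamped to
        0.99x the bound with a warning; if True it raises.
    """
    law = get_law(law)
    if d_mov <= 0 or d_mb <= 0:
        raise ValueError("diameters must be positive")
    bound = law.d_mb_bound(d_mov)
    if d_mb >= bound:
        if strict:
            raise ValueError(
                f"{law.name}: D_mb={d_mb:.4g} mm >= admissible bound "
                f"{bound:.4g} mm for D_mov={d_mov:.4g} mm"
            )
        warnings.warn(
            f"{law.name}: D_mb={d_mb:.4g} mm at/above law bound {bound:.4g} mm; "
            "clamping to 0.99x bound",
            stacklevel=2,
        )
        d_mb = 0.99 * bound
    return law.solve_side_branch(d_mov, d_mb)


@dataclass(frozen=True)
class JunctionFlow:
    """Flow split at one bifurcation. Q_mb + Q_sb == Q_mov exactly."""

    q_mov: float
    q_mb: float
    q_sb: float
    d_mov: float
    d_mb: float
    d_sb: float
    law: str


def junction_flow_split(
    q_mov: float,
    d_mov: float,
    d_mb: float,
    law: str | FractalLaw = "hk",
    *,
    strict: bool = False,
) -> JunctionFlow:
    """Apportion mother flow between main and side branch by the law's flow rule.

    ``Q_mb = Q_mov * f(D_mb) / (f(D_mb) + f(D_sb))`` with ``f`` the law's flow
    weight and ``D_sb`` inferred from the diameter relation; ``Q_sb`` is the
    exact complement, so conservation holds to machine precision.  For the
    power laws this equals ``Q_mov * (D_mb/D_mov)**exponent``.
    """
    lw = get_law(law)
    if q_mov < 0:
        raise ValueError("Q_mov must be >= 0")
    d_sb = infer_side_branch_diameter(d_mov, d_mb, lw, strict=strict)
    bound = lw.d_mb_bound(d_mov)
    if d_mb >= bound:  # keep diameters consistent with the clamped inference
        d_mb = 0.99 * bound
    w_mb = lw.flow_weight(d_mb)
    w_sb = lw.flow_weight(d_sb)
    q_mb = q_mov * w_mb / (w_mb + w_sb)
    return JunctionFlow(
        q_mov=q_mov, q_mb=q_mb, q_sb=q_mov - q_mb, d_mov=d_mov, d_mb=d_mb, d_sb=d_sb, law=lw.name
    )
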