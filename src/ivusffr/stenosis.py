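"""Stenosis detection on the lumen radius profile.

A stenosed vessel is identified by comparing the measured radius r(s) with a
healthy reference lumen at the same location.  No population template is
available per-patient, so the reference is estimated per vessel as a robust
linear (tapered) fit of r(s) that iteratively discards narrowed samples —
the standard reference-lumen construction used by QCA-style detectors.

Percent diameter stenosis is %DS = 100 * (1 - d_throat / d_ref(throat)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import CenterlineModel

__all__ = ["HealthyReference", "StenosisSegment", "fit_healthy_reference", "detect_stenoses"]


_RAMP_WIDTH = 1.0  # mm; caliber step-down is ramped across the junction


def _step_profile(s, steps) -> np.ndarray:
    """Multiplicative caliber step-downs at labeled branch nodes.

    Healthy coronary arteries lose caliber at every bifurcation (the main
    branch is narrower than the mother vessel), so the reference lumen is the
    taper line times a D_mb/D_mov factor per node, ramped smoothly over the
    junction region rather than stepped at a point.
    """
    s = np.asarray(s, dtype=float)
    out = np.ones_like(s)
    for s_node, factor in steps:
        t = np.clip((s - (s_node - _RAMP_WIDTH / 2)) / _RAMP_WIDTH, 0.0, 1.0)
        t = t * t * (3.0 - 2.0 * t)
        out = out * (1.0 + (factor - 1.0) * t)
    return out


@dataclass(frozen=True)
class HealthyReference:
    """Reference (healthy) radius: a taper line times per-branch step-downs.

    r_ref(s) = (intercept + slope * s) * prod_j step_j(s), where the step
    factors D_mb/D_mov come from the labeled branch nodes (empty tuple for a
    vessel without branches, leaving the spec's plain linear reference).
    """

    intercept: float  # mm
    slope: float  # mm per mm, <= 0 for a tapering vessel
    inlier_fraction: float
    steps: tuple = ()  # ((s_node, D_mb/D_mov), ...)
    fallback: bool = False  # constant 95th-percentile reference was used

    def __call__(self, s) -> np.ndarray:
        line = self.intercept + self.slope * np.asarray(s, dtype=float)
        return line * _step_profile(s, self.steps)


@dataclass(frozen=True)
class StenosisSegment:
    s_start: float  # mm
    s_end: float
    throat_s: float
    percent_diameter_stenosis: float  # %DS in (0, 100)


def fit_healthy_reference(
    model: CenterlineModel,
    *,
    drop_ratio: float = 0.9,
    max_iter: int = 20,
    min_inlier_fraction: float = 0.5,
) -> HealthyReference:
    """Robust linear fit of r(s), ignoring narrowed samples.

    Iterates {fit a line to current inliers; drop samples with
    r < drop_ratio * fit} starting from all samples, until the inlier set is
    stable or ``max_iter`` is reached.  If fewer than half the samples remain
    inliers the vessel is diffusely narrowed and the fit is unreliable; a
    constant 95th-percentile reference is used instead, with a warning.
    """
    s = model.s
    if len(s) < 10:
        raise ValueError("need at least 10 samples to fit a reference")
    # divide out the known caliber step-downs at labeled branch nodes so a
    # single line can be fitted to the whole vessel
    steps = tuple((nd.s, nd.d_mb / nd.d_mov) for nd in model.branch_nodes)
    r = model.radius / _step_profile(s, steps)
    inliers = np.ones_like(s, dtype=bool)
    for _ in range(max_iter):
        coef = np.polyfit(s[inliers], r[inliers], 1)
        fit = np.polyval(coef, s)
        new = r >= drop_ratio * fit
        if new.sum() < 2:
            break
        if np.array_equal(new, inliers):
            inliers = new
            break
        inliers = new
    frac = float(inliers.mean())
    if frac < min_inlier_fraction:
        warnings.warn(
            f"only {100 * frac:.0f}% inliers after reference fit; vessel looks "
            "diffusely narrowed — falling back to constant 95th-percentile reference",
            stacklevel=2,
        )
        return HealthyReference(
            intercept=float(np.percentile(r, 95)),
            slope=0.0,
            inlier_fraction=frac,
            steps=steps,
            fallback=True,
        )
    coef = np.polyfit(s[inliers], r[inliers], 1)
    return HealthyReference(
        intercept=float(coef[1]), slope=float(coef[0]), inlier_fraction=frac, steps=steps
    )


def detect_stenoses(
    model: CenterlineModel,
    reference: HealthyReference,
    trigger: float = 0.20,
    *,
    merge_gap_mm: float = 2.0,
    boundary_ratio: float = 0.95,
) -> list[StenosisSegment]:
    """Locate stenotic portions of the centerline.

    A sample is stenotic where ``r(s) < (1 - trigger) * r_ref(s)``.
    Contiguous stenotic runs closer than ``merge_gap_mm`` are merged, and
    each run is expanded outward to the nearest samples where the lumen has
    recovered to ``boundary_ratio * r_ref`` (the proximal/distal shoulders).
    """
    if not 0 < trigger < 1:
        raise ValueError("trigger must be in (0, 1)")
    s, r = model.s, model.radius
    r_ref = reference(s)
    stenotic = r < (1.0 - trigger) * r_ref
    if not stenotic.any():
        return []

    # contiguous runs of stenotic samples
    idx = np.flatnonzero(stenotic)
    runs = []
    start = idx[0]
    for a, b in zip(idx, idx[1:]):
        if b != a + 1:
            runs.append((start, a))
            start = b
    runs.append((start, idx[-1]))

    # merge runs separated by < merge_gap_mm
    merged = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = merged[-1]
        if s[a] - s[pb] < merge_gap_mm:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))

    healthy = r >= boundary_ratio * r_ref
    segments = []
    for a, b in merged:
        lo = a
        while lo > 0 and not healthy[lo]:
            lo -= 1
        hi = b
        while hi < len(s) - 1 and not healthy[hi]:
            hi += 1
        throat = lo + int(np.argmin(r[lo : hi + 1] / r_ref[lo : hi + 1]))
        pds = 100.0 * (1.0 - r[throat] / r_ref[throat])
        segments.append(
            StenosisSegment(
                s_start=float(s[lo]),
                s_end=float(s[hi]),
                throat_s=float(s[throat]),
                percent_diameter_stenosis=float(pds),
            )
        )
    return segments
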