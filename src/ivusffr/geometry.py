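"""Centerline and cross-sectional-area model of an IVUS pullback.

An IVUS pullback acquired at constant speed maps frame index to arclength
along the vessel.  Because the downstream reduced-order solver only needs the
arclength ``s`` and the lumen cross-sectional area ``A(s)``, the canonical
internal form is the straightened 1-D parametrization: ``s`` in mm, 0 at the
proximal inlet, strictly increasing toward the distal end; areas in mm^2.
True 3-D tortuosity is deliberately not modelled (no angiographic
co-registration is assumed).

Frames arrive distal->proximal, the acquisition order of a motorized
pullback; they are reversed on load unless flagged as pre-ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "BranchNode",
    "CenterlineModel",
    "Piece",
    "SegmentedCenterline",
    "contours_to_centerline",
    "label_branch_nodes",
    "split_at_branches",
    "split_pieces_at_intervals",
]


@dataclass(frozen=True)
class BranchNode:
    """A labeled bifurcation on the centerline.

    ``d_mov`` is the mother-vessel diameter just proximal of the node,
    ``d_mb`` the main-branch diameter carried through the pullback (operator
    or phantom provided; a single-tube pullback does not image the side
    branch, so ``D_sb`` is always inferred later from a fractal law).
    """

    s: float  # arclength, mm
    d_mov: float  # mm
    d_mb: float  # mm


@dataclass
class CenterlineModel:
    """Arclength-sampled lumen: s (mm, strictly increasing), A(s) (mm^2)."""

    s: np.ndarray
    area: np.ndarray
    frame_index: np.ndarray  # original frame index per sample
    branch_nodes: list[BranchNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.s.ndim != 1 or self.s.shape != self.area.shape:
            raise ValueError("s and area must be 1-D arrays of equal length")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        if np.any(self.area <= 0):
            raise ValueError("areas must be positive everywhere")

    @property
    def radius(self) -> np.ndarray:
        """Effective lumen radius sqrt(A/pi), mm."""
        return np.sqrt(self.area / np.pi)

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0])

    def to_frame(self):
        import pandas as pd

        node_s = {round(n.s, 9) for n in self.branch_nodes}
        return pd.DataFrame(
            {
                "s_mm": self.s,
                "area_mm2": self.area,
                "radius_mm": self.radius,
                "is_branch_node": [round(float(si), 9) in node_s for si in self.s],
            }
        )


def _polygon_area_mm2(contour) -> float:
    poly = Polygon(np.asarray(contour, dtype=float))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return float(poly.area)


def contours_to_centerline(
    contours,
    pullback_speed: float,
    frame_rate: float,
    *,
    already_ordered: bool = False,
) -> CenterlineModel:
    """Build the centerline model from per-frame lumen contours.

    Parameters
    ----------
    contours
        Sequence with one entry per frame: an (n, 2) array of lumen polygon
        vertices in mm, or None for a flagged frame (failed segmentation).
        Assumed distal->proximal (pullback order) unless ``already_ordered``.
    pullback_speed, frame_rate
        mm/s and frames/s; frame spacing = speed / rate.

    Flagged frames are filled by linear interpolation of the area; at least
    two valid frames are required.
    """
    if pullback_speed <= 0 or frame_rate <= 0:
        raise ValueError("pullback_speed and frame_rate must be positive")
    contours = list(contours)
    n = len(contours)
    valid = [c is not None for c in contours]
    if sum(valid) < 2:
        raise ValueError("need at least 2 valid frames")

    spacing = pullback_speed / frame_rate
    order = np.arange(n) if already_ordered else np.arange(n)[::-1]
    s = np.arange(n, dtype=float) * spacing
    area = np.full(n, np.nan)
    frame_index = np.empty(n, dtype=int)
    for pos, idx in enumerate(order):
        frame_index[pos] = idx
        if valid[idx]:
            area[pos] = _polygon_area_mm2(contours[idx])
    good = np.isfinite(area)
    area = np.interp(s, s[good], area[good])
    return CenterlineModel(s=s, area=area, frame_index=frame_index)


def label_branch_nodes(
    model: CenterlineModel,
    node_frames,
    d_mb,
    *,
    window_mm: float = 2.0,
) -> CenterlineModel:
    """Attach branch nodes at the given frame indices.

    The node arclength comes from the frame position; ``D_mov`` is the median
    effective diameter over a ``window_mm`` window just proximal of the node
    (robust to the lumen already opening into the ostium at the node itself);
    ``D_mb`` is taken as provided (labeled measurement).
    """
    node_frames = list(node_frames)
    d_mb = list(np.atleast_1d(np.asarray(d_mb, dtype=float)))
    if len(node_frames) != len(d_mb):
        raise ValueError("one D_mb per node frame required")
    nodes = []
    pos_of_frame = {int(f): i for i, f in enumerate(model.frame_index)}
    diam = 2.0 * model.radius
    for fr, dmb in zip(node_frames, d_mb):
        if int(fr) not in pos_of_frame:
            raise ValueError(f"frame {fr} not in pullback")
        pos = pos_of_frame[int(fr)]
        if pos in (0, len(model.s) - 1):
            raise ValueError(f"branch node at frame {fr} lies at the vessel end")
        s_node = float(model.s[pos])
        win = (model.s >= s_node - window_mm) & (model.s < s_node)
        if not win.any():
            win = np.zeros_like(win)
            win[pos - 1] = True
        d_mov = float(np.median(diam[win]))
        nodes.append(BranchNode(s=s_node, d_mov=d_mov, d_mb=float(dmb)))
    nodes.sort(key=lambda nd: nd.s)
    return replace(model, branch_nodes=list(model.branch_nodes) + nodes)


@dataclass(frozen=True)
class Piece:
    """One tile of the segmented centerline: normal, junction or stenosis.

    ``s``/``area`` include interpolated samples at both boundaries so that
    consecutive pieces share their boundary point and trapezoidal integrals
    over pieces sum to the integral over the whole vessel.
    """

    kind: str  # "normal" | "junction" | "stenosis"
    s_start: float
    s_end: float
    s: np.ndarray
    area: np.ndarray
    node: BranchNode | None = None

    @property
    def length(self) -> float:
        return self.s_end - self.s_start


@dataclass
class SegmentedCenterline:
    pieces: list[Piece]
    model: CenterlineModel

    @property
    def length(self) -> float:
        return sum(p.length for p in self.pieces)


def _slice_piece(model: CenterlineModel, a: float, b: float, kind: str, node=None) -> Piece:
    inner = (model.s > a) & (model.s < b)
    s = np.concatenate(([a], model.s[inner], [b]))
    area = np.interp(s, model.s, model.area)
    return Piece(kind=kind, s_start=a, s_end=b, s=s, area=area, node=node)


def split_at_branches(model: CenterlineModel, junction_halfwidth: float = 1.0) -> SegmentedCenterline:
    """Split the centerline into normal pieces and junction pieces.

    Each branch node becomes a junction piece ``[s - hw, s + hw]``; the
    remaining intervals are normal pieces. With n nodes the result has
    ``2 n + 1`` pieces tiling [0, L] exactly.
    """
    hw = float(junction_halfwidth)
    if hw <= 0:
        raise ValueError("junction_halfwidth must be positive")
    nodes = sorted(model.branch_nodes, key=lambda nd: nd.s)
    s0, s1 = float(model.s[0]), float(model.s[-1])
    for nd in nodes:
        if nd.s - hw <= s0 or nd.s + hw >= s1:
            raise ValueError(f"junction at s={nd.s} mm reaches the vessel end")
    bad = [
        (a.s, b.s) for a, b in zip(nodes, nodes[1:]) if b.s - a.s <= 2 * hw
    ]
    if bad:
        raise ValueError(f"overlapping junctions at node pairs {bad}")

    pieces: list[Piece] = []
    cursor = s0
    for nd in nodes:
        pieces.append(_slice_piece(model, cursor, nd.s - hw, "normal"))
        pieces.append(_slice_piece(model, nd.s - hw, nd.s + hw, "junction", node=nd))
        cursor = nd.s + hw
    pieces.append(_slice_piece(model, cursor, s1, "normal"))
    return SegmentedCenterline(pieces=pieces, model=model)


def split_pieces_at_intervals(seg: SegmentedCenterline, intervals) -> SegmentedCenterline:
    """Re-tile normal pieces so given (s_start, s_end) intervals become
    stenosis pieces. Junction pieces are never re-labeled; interval parts
    falling inside a junction are truncated to it."""
    out: list[Piece] = []
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    for p in seg.pieces:
        if p.kind != "normal":
            out.append(p)
            continue
        cuts = []
        for a, b in ivs:
            a2, b2 = max(a, p.s_start), min(b, p.s_end)
            if b2 - a2 > 1e-12:
                cuts.append((a2, b2))
        cursor = p.s_start
        for a, b in cuts:
            if a - cursor > 1e-12:
                out.append(_slice_piece(seg.model, cursor, a, "normal"))
            out.append(_slice_piece(seg.model, a, b, "stenosis"))
            cursor = b
        if p.s_end - cursor > 1e-12:
            out.append(_slice_piece(seg.model, cursor, p.s_end, "normal"))
    return SegmentedCenterline(pieces=out, model=seg.model)
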