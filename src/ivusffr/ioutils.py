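"""File formats and run configuration.

Interchange formats are deliberately plain: contour sets as JSON, tables as
CSV, structured results as JSON, image/mask stacks as multi-page TIFF or
numbered PNG.  The contour JSON schema is::

    {
      "pixel_size_mm": 0.05,
      "pullback": {"speed_mm_s": 1.0, "frame_rate_fps": 1.0},
      "frames": [
        {"index": 0, "lumen": [[x_mm, y_mm], ...], "ma": [[...]] | null},
        ...
      ]
    }

Frames are listed in acquisition (distal -> proximal) order; a frame whose
``lumen`` is null is flagged (failed segmentation) and interpolated by the
geometry module.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ContourSet",
    "read_contours",
    "write_contours",
    "write_frames",
    "read_frames",
    "RunConfig",
    "config_hash",
]


@dataclass
class ContourSet:
    """Per-frame lumen (and optional media-adventitia) polygons in mm."""

    lumen: list  # per frame: (k, 2) array or None
    ma: list
    pixel_size_mm: float
    speed_mm_s: float
    frame_rate_fps: float


def write_contours(path, contours: ContourSet) -> None:
    frames = []
    for i, (lu, ma) in enumerate(zip(contours.lumen, contours.ma)):
        frames.append(
            {
                "index": i,
                "lumen": None if lu is None else np.asarray(lu, dtype=float).tolist(),
                "ma": None if ma is None else np.asarray(ma, dtype=float).tolist(),
            }
        )
    doc = {
        "pixel_size_mm": contours.pixel_size_mm,
        "pullback": {
            "speed_mm_s": contours.speed_mm_s,
            "frame_rate_fps": contours.frame_rate_fps,
        },
        "frames": frames,
    }
    Path(path).write_text(json.dumps(doc))


def read_contours(path) -> ContourSet:
    doc = json.loads(Path(path).read_text())
    if "pullback" not in doc:
        raise ValueError("contour file missing required 'pullback' block")
    if "frames" not in doc:
        raise ValueError("contour file missing 'frames'")
    frames = sorted(doc["frames"], key=lambda f: f["index"])
    lumen = [None if f["lumen"] is None else np.asarray(f["lumen"], dtype=float) for f in frames]
    ma = [None if f.get("ma") is None else np.asarray(f["ma"], dtype=float) for f in frames]
    return ContourSet(
        lumen=lumen,
        ma=ma,
        pixel_size_mm=float(doc.get("pixel_size_mm", float("nan"))),
        speed_mm_s=float(doc["pullback"]["speed_mm_s"]),
        frame_rate_fps=float(doc["pullback"]["frame_rate_fps"]),
    )


def write_frames(path, stack: np.ndarray) -> None:
    """Write an image or mask stack as multi-page TIFF (or .png prefix)."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.dtype in (np.float32, np.float64):
        stack = (np.clip(stack, 0, 1) * 255).astype(np.uint8)
    elif stack.dtype != np.uint8:
        stack = stack.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, stack)
    else:
        from PIL import Image

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack):
            Image.fromarray(frame).save(path / f"frame_{i:04d}.png")


def read_frames(path) -> np.ndarray:
    path = Path(path)
    if path.is_dir():
        from PIL import Image

        files = sorted(path.glob("frame_*.png"))
        return np.stack([np.asarray(Image.open(f)) for f in files])
    import tifffile

    return tifffile.imread(path)


_DEFAULTS: dict = {
    "seed": 0,
    "law": "hk",
    "vessel": {
        "length": 60.0,
        "inlet_radius": 1.8,
        "taper": 0.008,
        "stenoses": [],  # dicts: center_s, extent, severity, shape
        "branches": [],  # dicts: node_s, law, main_fraction, stub_length
    },
    "render": {
        "pixel_size": 0.05,
        "frame_size": 128,
        "frame_spacing": 1.0,
        "noise_amplitude": 0.15,
        "wall_thickness": 0.5,
    },
    "segmentation": {"mode": "analytic", "steps": 300, "radius_noise_frac": 0.0},
    "detection": {"trigger": 0.20, "merge_gap_mm": 2.0, "boundary_ratio": 0.95},
    "geometry": {"junction_halfwidth": 1.0},
    "boundary": {
        "pa_mmhg": 90.0,
        "timi": None,  # [path_length_mm, frame_count, frame_rate_fps]
        "resting_velocity_mm_s": 150.0,
        "hyperemia_factor": 2.0,
        "viscosity": 0.0035,
        "density": 1050.0,
        "k_t": 1.0,
    },
    "compare_branch": False,
    "stub_length": 5.0,
    "threshold": 0.80,
}


def _merge_strict(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for k, v in override.items():
        if k not in defaults:
            raise KeyError(f"unknown config key {path + k!r}")
        if isinstance(defaults[k], dict) and isinstance(v, dict):
            out[k] = _merge_strict(defaults[k], v, path + k + ".")
        else:
            out[k] = v
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated full-pipeline configuration (unknown keys rejected)."""

    data: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULTS)))

    @classmethod
    def from_dict(cls, override: dict | None = None) -> "RunConfig":
        return cls(data=_merge_strict(_DEFAULTS, override or {}))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def __getitem__(self, key):
        return self.data[key]


def config_hash(config: RunConfig) -> str:
    """Stable hash of the effective configuration, embedded in every output."""
    blob = json.dumps(config.data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
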