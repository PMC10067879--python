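"""Masked-image multiscale L1 objective and alternating min-max training.

The objective is

    L(theta_S, theta_C) = (1/N) sum_n  (1/L) sum_i || f_C^i(x_n o S(x_n))
                                                   - f_C^i(x_n o y_n) ||_1

where ``o`` is the elementwise product (a *masked image*: prediction or
ground-truth mask applied to the input frame), ``f_C^i`` the critic's layer-i
feature map, and each layer term is averaged over its element count so all
scales contribute comparably.  The segmentor descends this loss, the critic
ascends it; training alternates one ascent and one descent step.  Critic
weights are clipped to a small box after each ascent step, the standard
stabilisation for feature-matching min-max objectives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .model import Critic, CriticConfig, Segmentor, SegmentorConfig
from .nn import Adam, Tensor, l1_mean

__all__ = [
    "masked_image",
    "multiscale_l1_loss",
    "TrainSchedule",
    "TrainState",
    "train_segan",
    "segment_pullback",
    "SegmentedFrame",
]


def masked_image(x, m):
    """Elementwise product of image and mask (numpy arrays or Tensors)."""
    if isinstance(x, Tensor) or isinstance(m, Tensor):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if not isinstance(m, Tensor):
            m = Tensor(m)
        if x.data.shape != m.data.shape and not _broadcastable(x.data.shape, m.data.shape):
            raise ValueError("image and mask shapes incompatible")
        return x * m
    x = np.asarray(x, dtype=np.float32)
    m = np.asarray(m, dtype=np.float32)
    if x.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if m.min() < 0 or m.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    return x * m


def _broadcastable(a, b):
    try:
        np.broadcast_shapes(a, b)
        return True
    except ValueError:
        return False


def multiscale_l1_loss(critic: Critic, masked_pred, masked_gt) -> Tensor:
    """(1/L) sum over critic layers of the per-element mean absolute
    feature difference. Non-negative; zero iff all layer features agree."""
    if not isinstance(masked_pred, Tensor):
        masked_pred = Tensor(masked_pred)
    if not isinstance(masked_gt, Tensor):
        masked_gt = Tensor(masked_gt)
    fp = critic.features(masked_pred)
    fg = critic.features(masked_gt)
    loss = l1_mean(fp[0], fg[0])
    for a, b in zip(fp[1:], fg[1:]):
        loss = loss + l1_mean(a, b)
    return loss * (1.0 / len(fp))


def _standardize(frames: np.ndarray) -> np.ndarray:
    """Per-frame zero-mean unit-variance normalisation (network input space)."""
    mean = frames.mean(axis=(-2, -1), keepdims=True)
    std = frames.std(axis=(-2, -1), keepdims=True)
    return ((frames - mean) / np.maximum(std, 1e-6)).astype(np.float32)


@dataclass(frozen=True)
class TrainSchedule:
    steps: int = 2000  # alternating iterations (one critic + one segmentor each)
    lr: float = 2e-4  # segmentor learning rate
    critic_lr: float | None = None  # defaults to lr; a slower critic stabilises
    critic_clip: float = 0.05  # weight box after each ascent step; None disables
    log_every: int = 100


@dataclass
class TrainState:
    segmentor: Segmentor
    critic: Critic
    seed: int
    step: int = 0
    loss_history: list = field(default_factory=list)


def train_segan(
    images,
    gt_masks,
    seg_config: SegmentorConfig | None = None,
    critic_config: CriticConfig | None = None,
    schedule: TrainSchedule = TrainSchedule(),
    seed: int = 0,
) -> TrainState:
    """Alternating min-max training on labeled frames.

    Parameters
    ----------
    images : (N, H, W) array in [0, 1]
    gt_masks : (N, C, H, W) binary array, C = segmentor output channels
    seed : seeds both parameter initialisation and any sampling; the run is
        fully deterministic (full-batch training), so equal seed and data
        give an identical loss trajectory.
    """
    x = np.asarray(images, dtype=np.float32)
    y = np.asarray(gt_masks, dtype=np.float32)
    if x.ndim != 3 or x.shape[0] == 0:
        raise ValueError("need at least one training image of shape (N, H, W)")
    n, h, w = x.shape
    if seg_config is None:
        seg_config = SegmentorConfig(input_size=h, out_channels=y.shape[1])
    if critic_config is None:
        critic_config = CriticConfig(in_channels=seg_config.out_channels)
    if h != seg_config.input_size or w != seg_config.input_size:
        raise ValueError("frames must match seg_config.input_size")
    if y.shape != (n, seg_config.out_channels, h, w):
        raise ValueError("gt_masks must be (N, out_channels, H, W)")

    rng = np.random.default_rng(seed)
    segmentor = Segmentor(seg_config, rng)
    critic = Critic(critic_config, rng)
    opt_s = Adam(segmentor.params, lr=schedule.lr)
    critic_lr = schedule.lr if schedule.critic_lr is None else schedule.critic_lr
    opt_c = Adam(critic.params, lr=critic_lr, maximize=True)

    # per-frame standardization: with raw [0,1] intensities a dark target
    # region makes the all-zero mask a cheap local minimum of the masked-image
    # L1; zero-mean unit-variance frames give every region O(1) magnitude
    x4 = _standardize(x)[:, None]  # (N, 1, H, W), broadcasts over mask channels
    gt_masked = Tensor(x4 * y)
    state = TrainState(segmentor=segmentor, critic=critic, seed=seed)

    for step in range(schedule.steps):
        # critic ascent
        xt = Tensor(x4)
        pred_masked = Tensor(x4) * segmentor(xt)  # gradient to critic only matters
        loss_c = multiscale_l1_loss(critic, pred_masked, gt_masked)
        loss_c.backward()
        opt_c.step()
        if schedule.critic_clip is not None:
            critic.clip_weights(schedule.critic_clip)

        # segmentor descent (fresh forward through the updated critic)
        xt = Tensor(x4)
        pred_masked = Tensor(x4) * segmentor(xt)
        loss_s = multiscale_l1_loss(critic, pred_masked, gt_masked)
        loss_s.backward()
        opt_s.step()

        val = loss_s.item()
        if not np.isfinite(val):
            raise FloatingPointError(
                f"non-finite loss {val} at step {step}; lower the learning rate "
                "or tighten the critic clip"
            )
        state.step = step + 1
        if step % schedule.log_every == 0 or step == schedule.steps - 1:
            state.loss_history.append((step, val))
    return state


@dataclass(frozen=True)
class SegmentedFrame:
    """Per-frame segmentation result in physical coordinates.

    ``contour`` is a closed (k, 2) polygon in mm, origin at the frame centre;
    None when the frame is flagged (empty mask after thresholding) — its
    area is interpolated downstream by the geometry module.
    """

    index: int
    mask: np.ndarray  # (H, W) uint8, largest connected component
    contour: np.ndarray | None
    flagged: bool


def _mask_to_contour(mask: np.ndarray, pixel_size: float) -> np.ndarray | None:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # (row, col)
    c = (np.asarray(mask.shape, dtype=float) - 1) / 2.0
    xy = np.column_stack((contour[:, 1] - c[1], contour[:, 0] - c[0])) * pixel_size
    return xy


def segment_pullback(
    state: TrainState,
    frames,
    pixel_size: float,
    *,
    channel: int = 0,
    threshold: float = 0.5,
    batch: int = 8,
) -> list[SegmentedFrame]:
    """Run the trained segmentor over a frame stack.

    Probability maps are thresholded at 0.5, the largest connected component
    kept, and its boundary extracted (marching squares) as a closed polygon
    in mm.  Frames whose mask is empty are flagged rather than failed.
    """
    frames = np.asarray(frames, dtype=np.float32)
    results = []
    for start in range(0, len(frames), batch):
        chunk = _standardize(frames[start : start + batch])
        probs = state.segmentor(Tensor(chunk[:, None])).data[:, channel]
        for k, pm in enumerate(probs):
            mask = pm > threshold
            if mask.any():
                lbl = measure.label(mask)
                largest = np.argmax(np.bincount(lbl.ravel())[1:]) + 1
                mask = lbl == largest
            contour = _mask_to_contour(mask, pixel_size) if mask.any() else None
            results.append(
                SegmentedFrame(
                    index=start + k,
                    mask=mask.astype(np.uint8),
                    contour=contour,
                    flagged=contour is None,
                )
            )
    return results
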