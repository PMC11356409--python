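"""Tversky loss and the multi-scale deep-supervision objective.

The Tversky index generalises Dice with separate penalties for false
positives (alpha) and false negatives (beta); alpha + beta = 1, and
alpha = beta = 0.5 recovers soft Dice exactly.  Deep supervision attaches
one Tversky term to every decoder level, comparing each soft mask against
the label bilinearly downsampled to that level's size, with a per-level
coefficient lambda_d that grows toward the finest level (default 2^d in
decoder order, d = 0 at the coarsest).

Targets may be soft: when the label is a fused pseudo-label in [0, 1]
(student training) the same soft-count formulas apply unchanged, so the
fusion weights are preserved rather than discarded by thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ganet import PredictionPyramid
from .nn import Tensor, bilinear_resize_np

LEVEL_WEIGHT_SCHEMES = ("constant", "linear", "pow2", "pow3")


@dataclass
class LossConfig:
    """Tversky and deep-supervision settings.

    alpha weights false positives, beta false negatives; defaults penalise
    false negatives harder (0.3/0.7) for sensitivity to small lesions.
    """

    alpha: float = 0.3
    beta: float = 0.7
    smooth: float = 1e-6
    level_weight_scheme: str = "pow2"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("alpha + beta must equal 1")
        if self.smooth < 0:
            raise ValueError("smooth must be nonnegative")
        if self.level_weight_scheme not in LEVEL_WEIGHT_SCHEMES:
            raise ValueError(
                f"unknown scheme {self.level_weight_scheme!r}; "
                f"choose from {LEVEL_WEIGHT_SCHEMES}")


def tversky_loss(pred, target, cfg: LossConfig | None = None):
    """1 - Tversky index with soft counts.

    TP = sum(P*y), FP = sum(P*(1-y)), FN = sum((1-P)*y);
    TI = (TP + s) / (TP + alpha*FP + beta*FN + s).  Returns a Tensor when
    ``pred`` is a Tensor (for backprop), else a float.
    """
    cfg = cfg or LossConfig()
    if isinstance(pred, Tensor):
        p = pred
        y = Tensor.as_tensor(target)
        if p.shape != y.shape:
            raise ValueError(
                f"shape mismatch: pred {p.shape} vs target {y.shape}")
        tp = (p * y).sum()
        fp = (p * (1.0 - y)).sum()
        fn = ((1.0 - p) * y).sum()
        return 1.0 - (tp + cfg.smooth) / (tp + cfg.alpha * fp
                                          + cfg.beta * fn + cfg.smooth)
    p = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {y.shape}")
    tp = float((p * y).sum())
    fp = float((p * (1.0 - y)).sum())
    fn = float(((1.0 - p) * y).sum())
    return 1.0 - (tp + cfg.smooth) / (tp + cfg.alpha * fp
                                      + cfg.beta * fn + cfg.smooth)


def downsample_label(label: np.ndarray, target_size: tuple[int, int]
                     ) -> np.ndarray:
    """Bilinear downsampling of a (possibly soft) label to a decoder size."""
    label = np.asarray(label, dtype=np.float32)
    th, tw = target_size
    if th > label.shape[-2] or tw > label.shape[-1]:
        raise ValueError(
            f"target size {target_size} exceeds label size "
            f"{label.shape[-2:]}; only downsampling is supported")
    if (th, tw) == label.shape[-2:]:
        return label
    return bilinear_resize_np(label, (th, tw))


def level_weight(d: int, depth: int, scheme: str = "pow2") -> float:
    """Coefficient lambda_d for decoder-order level d (0 = coarsest).

    The finest level receives the largest weight; ``pow2`` gives 1, 2, 4,
    ... up the decoder.  ``linear`` uses d+1 so the coarsest (Identify)
    level keeps nonzero supervision.
    """
    if not 0 <= d < depth:
        raise ValueError(f"level index {d} outside [0, {depth})")
    if scheme == "constant":
        return 1.0
    if scheme == "linear":
        return float(d + 1)
    if scheme == "pow2":
        return float(2 ** d)
    if scheme == "pow3":
        return float(3 ** d)
    raise ValueError(f"unknown scheme {scheme!r}")


def multiscale_loss(pyramid: PredictionPyramid, label,
                    cfg: LossConfig | None = None):
    """Sum over levels of lambda_d * Tversky(P_d, downsample(label)).

    ``label`` is at full input resolution, shaped (H, W) or (N, 1, H, W) to
    match the pyramid's batch; it may be binary or a soft pseudo-label.
    """
    cfg = cfg or LossConfig()
    depth = len(pyramid.masks)
    label = np.asarray(label, dtype=np.float32)
    if label.ndim == 2:
        label = label[None, None]
    elif label.ndim == 3:
        label = label[:, None]
    total = None
    # pyramid index 0 = finest = decoder-order index depth-1
    for m, pred in enumerate(pyramid.masks):
        d = depth - 1 - m
        lam = level_weight(d, depth, cfg.level_weight_scheme)
        target = downsample_label(label, tuple(pred.shape[-2:]))
        term = tversky_loss(pred, Tensor(target), cfg) * lam \
            if isinstance(pred, Tensor) \
            else lam * tversky_loss(pred, target, cfg)
        total = term if total is None else total + term
    return total
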