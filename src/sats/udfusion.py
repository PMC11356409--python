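"""Uncertainty and Distance Fusion of teacher pseudo-labels.

One reconstruction autoencoder is pre-trained per source domain on images
alone (MSE objective).  At inference, feeding a target image through every
autoencoder yields per-domain reconstruction errors D_i; a softmax over
-D_i gives a per-image *distribution weight* simplex u (closer domain ->
larger weight).  Each teacher's soft prediction also carries a per-pixel
entropy field U_i = -y log y, and a per-pixel softmax over -U_i gives the
*uncertainty weights* v_i(p, q) (more confident teacher -> larger weight).
The fused pseudo-label is the convex combination

    Yhat(p, q) = sum_i (u_i + v_i(p, q)) / 2 * yhat_i(p, q).

Ablation fusion modes: ``mean`` (w = 1/k), ``uncertainty_only`` (w = v),
``distance_only`` (w = u); all modes produce per-pixel simplex weights, so
the fused label always lies inside the convex hull of the predictions.

The printed entropy is the single term -y log y (maximum e^-1 at
y = e^-1); full two-term binary entropy is available via ``binary=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, Module, Tensor, bilinear_resize,
                 no_grad)
from .synthetic import DomainDataset

ENTROPY_EPS = 1e-8


class FusionMode(str, Enum):
    UDFUSION = "udfusion"
    MEAN = "mean"
    UNCERTAINTY_ONLY = "uncertainty_only"
    DISTANCE_ONLY = "distance_only"


@dataclass
class FusionWeights:
    """Everything UDFusion computes for one target image."""

    distances: np.ndarray | None    # (k,) reconstruction distances D_i
    u: np.ndarray                   # (k,) distribution-weight simplex
    U_maps: np.ndarray | None       # (k, H, W) entropy fields
    v_maps: np.ndarray              # (k, H, W) per-pixel simplex
    w_maps: np.ndarray              # (k, H, W) fused per-pixel simplex
    fused: np.ndarray               # (H, W) pseudo-label in [0, 1]


# -- reconstruction autoencoder ----------------------------------------------

class Autoencoder(Module):
    """3-level strided convolutional encoder-decoder, image -> image.

    The 8x-downsampled bottleneck forces the network to memorise its
    domain's colour and texture statistics, so reconstruction error acts as
    a (inverse) domain-similarity score.
    """

    def __init__(self, seed: int = 0, base_channels: int = 8):
        super().__init__()
        rng = np.random.default_rng([seed, 40503])
        c = base_channels
        self.enc = [
            Conv2d(3, c, 3, rng, stride=2, padding=1),
            Conv2d(c, 2 * c, 3, rng, stride=2, padding=1),
            Conv2d(2 * c, 4 * c, 3, rng, stride=2, padding=1),
        ]
        self.enc_bn = [BatchNorm2d(c), BatchNorm2d(2 * c),
                       BatchNorm2d(4 * c)]
        self.dec = [
            Conv2d(4 * c, 2 * c, 3, rng, padding=1),
            Conv2d(2 * c, c, 3, rng, padding=1),
            Conv2d(c, 3, 3, rng, padding=1),
        ]
        self.dec_bn = [BatchNorm2d(2 * c), BatchNorm2d(c)]

    def __call__(self, x: Tensor) -> Tensor:
        for conv, bn in zip(self.enc, self.enc_bn):
            x = bn(conv(x)).relu()
        for i, conv in enumerate(self.dec):
            hw = (x.shape[-2] * 2, x.shape[-1] * 2)
            x = conv(bilinear_resize(x, hw))
            if i < len(self.dec_bn):
                x = self.dec_bn[i](x).relu()
        return x.sigmoid()

    def reconstruct(self, images: np.ndarray, batch_size: int = 16
                    ) -> np.ndarray:
        """Eval-mode reconstructions for NHWC float images."""
        was_training = self.training
        self.eval()
        outs = []
        with no_grad():
            for s in range(0, len(images), batch_size):
                x = np.transpose(images[s:s + batch_size], (0, 3, 1, 2))
                outs.append(self(Tensor(x)).data)
        if was_training:
            self.train()
        return np.transpose(np.concatenate(outs, axis=0), (0, 2, 3, 1))


@dataclass
class AETrainConfig:
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    base_channels: int = 8


def train_autoencoder(dataset: DomainDataset,
                      train_cfg: AETrainConfig | None = None
                      ) -> tuple[Autoencoder, list[float]]:
    """Fit a reconstruction autoencoder on a domain's images (labels unused).

    Returns the trained model and the per-epoch mean MSE training curve.
    """
    cfg = train_cfg or AETrainConfig()
    if len(dataset) == 0:
        raise ValueError("cannot train an autoencoder on an empty dataset")
    model = Autoencoder(seed=cfg.seed, base_channels=cfg.base_channels)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng([cfg.seed, dataset.domain_id, 60013])
    images = np.transpose(dataset.images, (0, 3, 1, 2))
    n = len(images)
    curve = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for s in range(0, n, cfg.batch_size):
            batch = Tensor(images[order[s:s + cfg.batch_size]])
            opt.zero_grad()
            recon = model(batch)
            diff = recon - batch
            loss = (diff * diff).mean()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        curve.append(float(np.mean(epoch_losses)))
    return model, curve


def reconstruction_distance(ae: Autoencoder, image: np.ndarray) -> float:
    """Mean squared reconstruction residual of one HWC image (>= 0)."""
    recon = ae.reconstruct(image[None])[0]
    return float(np.mean((recon - image) ** 2))


# -- fusion weights -----------------------------------------------------------

def distribution_weights(distances: np.ndarray) -> np.ndarray:
    """softmax(-D): smaller reconstruction distance -> larger weight."""
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 1 or d.size < 1:
        raise ValueError("distances must be a length-k vector, k >= 1")
    if not np.isfinite(d).all():
        raise ValueError("distances must be finite")
    z = -d + d.min()           # shift for numerical stability
    e = np.exp(z)
    return e / e.sum()


def pixel_uncertainty(y_hat: np.ndarray, binary: bool = False,
                      eps: float = ENTROPY_EPS) -> np.ndarray:
    """Per-pixel prediction entropy of a soft mask.

    Default is the single-term entropy -y ln(y + eps) (zero at y = 0 and
    y = 1, maximum e^-1 at y = e^-1); ``binary=True`` switches to the full
    binary entropy -y ln y - (1-y) ln(1-y).
    """
    y = np.asarray(y_hat, dtype=np.float64)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("soft mask values must lie in [0, 1]")
    u = -y * np.log(y + eps)
    if binary:
        u = u - (1.0 - y) * np.log(1.0 - y + eps)
    return np.maximum(u, 0.0)


def uncertainty_weights(u_maps: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over teachers of negated entropy fields.

    ``u_maps`` has shape (k, H, W); the result sums to 1 across teachers at
    every pixel, with lower entropy earning a larger weight.
    """
    u = np.asarray(u_maps, dtype=np.float64)
    if u.ndim != 3:
        raise ValueError("u_maps must be a (k, H, W) stack")
    z = -u + u.min(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def fuse_pseudo_label(predictions: np.ndarray, u: np.ndarray,
                      v_maps: np.ndarray,
                      mode: FusionMode | str = FusionMode.UDFUSION,
                      distances: np.ndarray | None = None,
                      U_maps: np.ndarray | None = None
                      ) -> tuple[np.ndarray, FusionWeights]:
    """Convex fusion of k teacher predictions into one pseudo-label.

    ``predictions``, ``v_maps``: (k, H, W); ``u``: (k,) simplex.  Returns
    the fused soft mask and the full set of fusion weights.
    """
    mode = FusionMode(mode)
    preds = np.asarray(predictions, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v_maps, dtype=np.float64)
    if preds.ndim != 3:
        raise ValueError("predictions must be a (k, H, W) stack")
    k = preds.shape[0]
    if u.shape != (k,) or v.shape != preds.shape:
        raise ValueError(
            f"weight shapes (u {u.shape}, v {v.shape}) do not match "
            f"{k} predictions of shape {preds.shape[1:]}")
    if mode is FusionMode.UDFUSION:
        w = (u[:, None, None] + v) / 2.0
    elif mode is FusionMode.MEAN:
        w = np.full_like(preds, 1.0 / k)
    elif mode is FusionMode.UNCERTAINTY_ONLY:
        w = v.copy()
    else:  # DISTANCE_ONLY
        w = np.broadcast_to(u[:, None, None], preds.shape).copy()
    fused = np.sum(w * preds, axis=0)
    weights = FusionWeights(distances=None if distances is None
                            else np.asarray(distances, dtype=np.float64),
                            u=u, U_maps=U_maps, v_maps=v, w_maps=w,
                            fused=fused)
    return fused, weights


def udfusion(predictions: np.ndarray, distances: np.ndarray,
             mode: FusionMode | str = FusionMode.UDFUSION,
             binary_entropy: bool = False
             ) -> tuple[np.ndarray, FusionWeights]:
    """Full pipeline for one image: distances + predictions -> pseudo-label."""
    preds = np.asarray(predictions, dtype=np.float64)
    u = distribution_weights(distances)
    U_maps = np.stack([pixel_uncertainty(p, binary=binary_entropy)
                       for p in preds])
    v = uncertainty_weights(U_maps)
    fused, weights = fuse_pseudo_label(preds, u, v, mode,
                                       distances=distances, U_maps=U_maps)
    return fused, weights
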