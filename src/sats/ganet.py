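"""Granular Attention Network: coarse-to-fine attention segmenter.

A ResBlock encoder halves the spatial size at every level while doubling
channels.  At the deepest level an *Identify* block applies channel
self-attention followed by spatial self-attention and emits an initial
coarse mask.  *Refine* blocks then walk back up the decoder: at each level
the encoder feature is passed through an overall spatial attention, split
into foreground/background streams gated by the previous (upsampled) coarse
mask P and its complement (1-P), and recombined as

    z' = O_prev - gamma1 * Attn_fg(P * z) + gamma2 * Attn_bg((1 - P) * z)

so falsely-predicted foreground features are subtracted from the previous
block's features and missed background (i.e. missed polyp) features are
added back.  Every decoder level emits a sigmoid mask; the full stack is
returned as a :class:`PredictionPyramid` for deep supervision.

Attention conventions: all Q/K/V projections are 1x1 convolutions, single
head, no positional encoding, softmax scores scaled by sqrt(c) with c the
channel width of the block.  Channel attention attends over the c channels
(c x c matrix); spatial attention treats the w*h positions as tokens
((w*h) x (w*h) matrix), which makes it equivariant to spatial permutations.
gamma1/gamma2 are learnable scalars initialised at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (Conv2d, Module, Parameter, ResBlock, Tensor,
                 bilinear_resize, no_grad, softmax)


@dataclass
class GANetConfig:
    """Architecture hyper-parameters.

    depth
        Number of encoder levels D (>= 2).  Level d has spatial size
        input/2^(d+1); the Identify block sits at level D-1 and there are
        D-1 Refine blocks, so the pyramid holds D supervised masks.
    base_channels
        Channel width at the finest encoder level; doubles per level.
    gamma_init
        Initial value of the learnable foreground/background correction
        scalars gamma1, gamma2.
    """

    depth: int = 4
    base_channels: int = 8
    attention_dim: int | None = None
    gamma_init: float = 1.0
    sigmoid_on_predictions: bool = True

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")

    def channels(self, level: int) -> int:
        return self.base_channels * 2 ** level


@dataclass
class PredictionPyramid:
    """Soft masks from every supervised decoder level, index 0 = finest.

    ``masks[-1]`` is the Identify block's initial mask at the coarsest
    level; ``full_res`` is the finest mask bilinearly upsampled to the
    input resolution (the inference output).
    """

    masks: list = field(default_factory=list)
    full_res: Tensor | None = None

    def numpy(self) -> list[np.ndarray]:
        return [m.data for m in self.masks]


# -- flatten/unflatten (the reshape pair between 3-D and token features) -----

def spatial_flatten(x):
    """(..., c, w, h) -> (..., c, w*h); flat index j*h + k for position (j,k)."""
    if isinstance(x, Tensor):
        *lead, c, w, h = x.shape
        return x.reshape(*lead, c, w * h)
    x = np.asarray(x)
    return x.reshape(*x.shape[:-2], x.shape[-2] * x.shape[-1])


def spatial_unflatten(x, w: int, h: int):
    """Exact inverse of :func:`spatial_flatten`."""
    shape = x.shape
    if shape[-1] != w * h:
        raise ValueError(
            f"cannot unflatten last dim {shape[-1]} into {w}x{h}")
    if isinstance(x, Tensor):
        return x.reshape(*shape[:-1], w, h)
    return np.asarray(x).reshape(*shape[:-1], w, h)


def _ensure_nchw(x) -> Tensor:
    t = Tensor.as_tensor(x)
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    return t


class ChannelAttention(Module):
    """Self-attention over channels: A = softmax(Q K^T / sqrt(c)), c x c."""

    def __init__(self, channels: int, rng, attention_dim: int | None = None):
        super().__init__()
        self.channels = channels
        a = attention_dim or channels
        self.q = Conv2d(channels, a, 1, rng)
        self.k = Conv2d(channels, a, 1, rng)
        self.v = Conv2d(channels, channels, 1, rng)

    def __call__(self, z, return_attn: bool = False):
        z = _ensure_nchw(z)
        n, c, w, h = z.shape
        q = spatial_flatten(self.q(z))            # (n, a, wh)
        k = spatial_flatten(self.k(z))
        v = spatial_flatten(self.v(z))
        scores = (q @ k.transpose(0, 2, 1)) * float(1.0 / np.sqrt(c))
        attn = softmax(scores, axis=-1)           # (n, a, a) rows sum to 1
        out = spatial_unflatten(attn @ v, w, h)
        return (out, attn) if return_attn else out


class SpatialAttention(Module):
    """Self-attention over positions: tokens are the w*h pixels."""

    def __init__(self, channels: int, rng, attention_dim: int | None = None):
        super().__init__()
        self.channels = channels
        a = attention_dim or channels
        self.q = Conv2d(channels, a, 1, rng)
        self.k = Conv2d(channels, a, 1, rng)
        self.v = Conv2d(channels, channels, 1, rng)

    def __call__(self, z, return_attn: bool = False):
        z = _ensure_nchw(z)
        n, c, w, h = z.shape
        q = spatial_flatten(self.q(z)).transpose(0, 2, 1)   # (n, wh, a)
        k = spatial_flatten(self.k(z))                      # (n, a, wh)
        v = spatial_flatten(self.v(z)).transpose(0, 2, 1)   # (n, wh, c)
        scores = (q @ k) * float(1.0 / np.sqrt(c))          # (n, wh, wh)
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1)                 # (n, c, wh)
        out = spatial_unflatten(out, w, h)
        return (out, attn) if return_attn else out


def masked_attention(z, gate, attn: SpatialAttention) -> Tensor:
    """Spatial attention over gated features ``attn(gate * z)``.

    ``gate`` is a soft mask in [0,1] with the same spatial size as ``z``
    (broadcast over channels); foreground streams use the previous coarse
    mask, background streams its complement.
    """
    z = _ensure_nchw(z)
    gate = _ensure_nchw(gate) if not isinstance(gate, Tensor) else gate
    if gate.ndim == 2:
        gate = gate.reshape(1, 1, *gate.shape)
    elif gate.ndim == 3:
        gate = gate.reshape(gate.shape[0], 1, *gate.shape[1:])
    if gate.shape[-2:] != z.shape[-2:]:
        raise ValueError(
            f"gate spatial size {gate.shape[-2:]} != feature {z.shape[-2:]}")
    return attn(z * gate)


class IdentifyBlock(Module):
    """Channel then spatial attention on the deepest feature + initial mask."""

    def __init__(self, channels: int, rng, attention_dim=None,
                 sigmoid: bool = True):
        super().__init__()
        self.attn_ch = ChannelAttention(channels, rng, attention_dim)
        self.attn_sp = SpatialAttention(channels, rng, attention_dim)
        self.head = Conv2d(channels, 1, 1, rng)
        self.sigmoid = sigmoid

    def __call__(self, z_deep) -> tuple[Tensor, Tensor]:
        o_sp = self.attn_sp(self.attn_ch(z_deep))
        p = self.head(o_sp)
        if self.sigmoid:
            p = p.sigmoid()
        return o_sp, p


class RefineBlock(Module):
    """Foreground/background attention correction at one decoder level.

    Expects ``o_prev`` and ``p_prev`` already upsampled to this level's
    spatial size and ``o_prev`` channel-aligned to ``z``; with
    gamma1 = gamma2 = 0 the output feature equals ``o_prev`` exactly.
    """

    def __init__(self, channels: int, rng, attention_dim=None,
                 gamma_init: float = 1.0, sigmoid: bool = True):
        super().__init__()
        self.attn_all = SpatialAttention(channels, rng, attention_dim)
        self.attn_fg = SpatialAttention(channels, rng, attention_dim)
        self.attn_bg = SpatialAttention(channels, rng, attention_dim)
        self.gamma1 = Parameter(np.float32(gamma_init))
        self.gamma2 = Parameter(np.float32(gamma_init))
        self.head = Conv2d(channels, 1, 1, rng)
        self.sigmoid = sigmoid

    def __call__(self, z, o_prev, p_prev) -> tuple[Tensor, Tensor]:
        z = _ensure_nchw(z)
        o_prev = _ensure_nchw(o_prev)
        if o_prev.shape != z.shape:
            raise ValueError(
                f"o_prev shape {o_prev.shape} does not match feature "
                f"shape {z.shape}; upsample and channel-align it first")
        z_all = self.attn_all(z)
        z_fg = masked_attention(z_all, p_prev, self.attn_fg)
        one = Tensor(np.float32(1.0))
        p_bg = one - (p_prev if isinstance(p_prev, Tensor)
                      else Tensor(p_prev))
        z_bg = masked_attention(z_all, p_bg, self.attn_bg)
        z_out = o_prev - self.gamma1 * z_fg + self.gamma2 * z_bg
        p = self.head(z_out)
        if self.sigmoid:
            p = p.sigmoid()
        return z_out, p


class GANet(Module):
    """Full encoder + Identify + Refine stack."""

    def __init__(self, cfg: GANetConfig, seed: int = 0, in_channels: int = 3):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng([seed, 2654435761])
        chans = [cfg.channels(d) for d in range(cfg.depth)]
        self.encoder = []
        prev = in_channels
        for d in range(cfg.depth):
            self.encoder.append(ResBlock(prev, chans[d], rng, stride=2))
            prev = chans[d]
        self.identify = IdentifyBlock(chans[-1], rng, cfg.attention_dim,
                                      sigmoid=cfg.sigmoid_on_predictions)
        # refine blocks for levels D-2 .. 0 plus a 1x1 alignment conv that
        # maps the previous level's channels down to this level's
        self.refines = []
        self.aligns = []
        for d in range(cfg.depth - 2, -1, -1):
            self.refines.append(RefineBlock(
                chans[d], rng, cfg.attention_dim, cfg.gamma_init,
                sigmoid=cfg.sigmoid_on_predictions))
            self.aligns.append(Conv2d(chans[d + 1], chans[d], 1, rng))

    # -- operations ----------------------------------------------------------
    def encode(self, image) -> list[Tensor]:
        """Run the ResBlock encoder; returns [z_0 (finest) ... z_{D-1}]."""
        x = Tensor.as_tensor(image)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        h, w = x.shape[-2:]
        factor = 2 ** self.cfg.depth
        if h % factor or w % factor:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2^depth = "
                f"{factor}; pad to "
                f"{-(-h // factor) * factor}x{-(-w // factor) * factor}")
        if x.data.min() < 0 or x.data.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        feats = []
        for block in self.encoder:
            x = block(x)
            feats.append(x)
        return feats

    def forward(self, image) -> PredictionPyramid:
        """Coarse-to-fine forward pass producing all supervised masks."""
        feats = self.encode(image)
        o, p = self.identify(feats[-1])
        coarse_to_fine = [p]
        for i, d in enumerate(range(self.cfg.depth - 2, -1, -1)):
            target_hw = feats[d].shape[-2:]
            o_up = self.aligns[i](bilinear_resize(o, target_hw))
            p_up = bilinear_resize(p, target_hw)
            o, p = self.refines[i](feats[d], o_up, p_up)
            coarse_to_fine.append(p)
        masks = list(reversed(coarse_to_fine))
        in_hw = (feats[0].shape[-2] * 2, feats[0].shape[-1] * 2)
        full = bilinear_resize(masks[0], in_hw)
        return PredictionPyramid(masks=masks, full_res=full)

    __call__ = forward

    def predict(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Eval-mode soft masks at input resolution for NHWC float images."""
        was_training = self.training
        self.eval()
        outs = []
        with no_grad():
            for start in range(0, len(images), batch_size):
                batch = images[start:start + batch_size]
                x = np.transpose(batch, (0, 3, 1, 2))
                pyr = self.forward(Tensor(x))
                outs.append(pyr.full_res.data[:, 0])
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(model: GANet, path) -> None:
    """Save parameters, buffers and config to an .npz checkpoint."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    cfg = model.cfg
    np.savez_compressed(
        path, __depth=cfg.depth, __base_channels=cfg.base_channels,
        __attention_dim=-1 if cfg.attention_dim is None else cfg.attention_dim,
        __gamma_init=cfg.gamma_init,
        __sigmoid=int(cfg.sigmoid_on_predictions), __seed=model.seed,
        **state)


def load_checkpoint(path) -> GANet:
    with np.load(Path(path)) as data:
        attn = int(data["__attention_dim"])
        cfg = GANetConfig(
            depth=int(data["__depth"]),
            base_channels=int(data["__base_channels"]),
            attention_dim=None if attn < 0 else attn,
            gamma_init=float(data["__gamma_init"]),
            sigmoid_on_predictions=bool(data["__sigmoid"]))
        model = GANet(cfg, seed=int(data["__seed"]))
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    model.load_state_dict(state)
    return model
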