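"""Synthetic multi-domain endoscopy-style benchmark.

Real polyp collections (CVC-ClinicDB, CVC-ColonDB, Kvasir, hospital-private
sets) differ systematically in colour cast, illumination, texture and
specular artefacts; a private set may additionally contain coloured bright
spots absent from the public ones.  This module emulates that situation at
desk scale: ``k`` labeled "source" domains, each with its own deterministic
:class:`DomainStyle`, plus one unlabeled "target" domain whose style is a
perturbed convex mixture of the source styles with one known dominant
source.  The dominant source index is recorded in the dataset metadata and
serves as ground truth for distribution-weight selectivity checks.

Every generator is a pure function of its seed: regenerating with the same
arguments is bit-exact.
"""

from __future__ import annotations

import colorsys
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import read_image, read_mask, write_image, write_mask

#: Minimum separation between two distinct domain styles: either the hue gap
#: or the illumination-gain gap must exceed these margins.
HUE_MARGIN_DEG = 10.0
GAIN_MARGIN = 0.2

_HUE_STEP = 45.0       # hue classes (id-1) % 8 are >=45 deg apart
_GAIN_STEP = 0.25      # same hue class -> gains 0.25 apart
_HUE_JITTER = 4.0      # jitter stays well inside the margins
_GAIN_JITTER = 0.02


@dataclass(frozen=True)
class DomainStyle:
    """Colour/illumination/texture statistics of one imaging domain."""

    domain_id: int
    base_hue: float                      # degrees in [0, 360)
    illumination_gain: float             # multiplicative brightness, > 0
    texture_frequency: float             # cycles per image
    specular_spot_color: tuple[float, float, float]
    specular_spot_rate: float            # expected spots per image
    noise_sd: float

    def __post_init__(self):
        if self.domain_id < 1:
            raise ValueError("domain_id must be >= 1")
        if not 0.0 <= self.base_hue < 360.0:
            raise ValueError("base_hue must lie in [0, 360)")
        if self.illumination_gain <= 0:
            raise ValueError("illumination_gain must be positive")
        if any(not 0.0 <= c <= 1.0 for c in self.specular_spot_color):
            raise ValueError("specular_spot_color must lie in [0,1]^3")
        if self.specular_spot_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise_sd must be nonnegative")


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray    # H x W x 3 float32 in [0, 1]
    mask: np.ndarray     # H x W uint8 in {0, 1}
    domain_id: int
    seed: int


@dataclass
class DomainDataset:
    """Images (and masks when labeled) for one domain.

    For the unlabeled target domain, ground-truth masks exist but are held
    out for final evaluation only; every read goes through
    :meth:`heldout_masks` and is recorded in :attr:`mask_access_log`, so a
    test can assert that no training stage touched them.
    """

    domain_id: int
    name: str
    style: DomainStyle
    images: np.ndarray                     # N x H x W x 3 float32
    masks: np.ndarray | None               # N x H x W uint8, labeled only
    labeled: bool
    sample_seeds: list[int]
    nearest_source: int | None = None      # target only: dominant source id
    _heldout_masks: np.ndarray | None = None
    mask_access_log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)

    def heldout_masks(self, purpose: str) -> np.ndarray:
        """Return the held-out evaluation masks, logging the access."""
        if self._heldout_masks is None:
            raise ValueError(f"domain {self.name!r} has no held-out masks")
        self.mask_access_log.append(purpose)
        return self._heldout_masks


def make_domain_style(domain_id: int, rng_seed: int) -> DomainStyle:
    """Deterministic style for a domain id.

    Hue is assigned on a 45-degree grid (offset by a seed-dependent global
    rotation) and illumination gain on a 0.25 grid, so any two distinct ids
    under the same seed differ by >= 10 degrees of hue or >= 0.2 of gain.
    """
    if domain_id < 1:
        raise ValueError("domain_id must be >= 1")
    offset = float(np.random.default_rng(rng_seed).uniform(0.0, 360.0))
    rng = np.random.default_rng([rng_seed, domain_id])
    hue_class = (domain_id - 1) % 8
    gain_class = (domain_id - 1) // 8
    hue = (offset + hue_class * _HUE_STEP
           + rng.uniform(-_HUE_JITTER, _HUE_JITTER)) % 360.0
    gain = (0.85 + gain_class * _GAIN_STEP
            + rng.uniform(-_GAIN_JITTER, _GAIN_JITTER))
    spot_hue = rng.uniform(0.0, 360.0)
    spot_rgb = colorsys.hsv_to_rgb(spot_hue / 360.0, 0.6, 1.0)
    return DomainStyle(
        domain_id=domain_id,
        base_hue=hue,
        illumination_gain=float(gain),
        texture_frequency=float(rng.uniform(3.0, 8.0)),
        specular_spot_color=tuple(float(np.clip(c, 0, 1)) for c in spot_rgb),
        specular_spot_rate=float(rng.uniform(0.5, 3.0)),
        noise_sd=float(rng.uniform(0.005, 0.03)),
    )


def styles_separated(a: DomainStyle, b: DomainStyle) -> bool:
    """True when two styles satisfy the documented separation margin."""
    dh = abs(a.base_hue - b.base_hue)
    dh = min(dh, 360.0 - dh)
    return dh >= HUE_MARGIN_DEG or \
        abs(a.illumination_gain - b.illumination_gain) >= GAIN_MARGIN


def _hsv_image(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorised HSV (h in degrees) -> RGB."""
    h = (np.asarray(h) % 360.0) / 60.0
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    v = np.clip(v, 0.0, 1.0)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    out = np.empty(h.shape + (3,), dtype=np.float32)
    for idx, (r, g, b) in enumerate([(v, t, p), (q, v, p), (p, v, t),
                                     (p, q, v), (t, p, v), (v, p, q)]):
        m = i == idx
        out[m, 0], out[m, 1], out[m, 2] = r[m], g[m], b[m]
    return out


def _style_rng(style: DomainStyle, seed: int) -> np.random.Generator:
    key = [int(seed), style.domain_id, int(style.base_hue * 64.0),
           int(style.illumination_gain * 1024.0)]
    return np.random.default_rng(key)


def render_polyp_image(style: DomainStyle, height: int, width: int,
                       seed: int) -> SyntheticSample:
    """Render one mucosa-like image with a single blobby polyp.

    The polyp is a random ellipse whose boundary radius is perturbed by
    low-frequency sinusoids (star-shaped, hence one 4-connected component);
    its area fraction always lies in [0.02, 0.40].  The background carries
    the style's hue, an illumination gradient and sinusoidal texture;
    Poisson-many specular spots of the style's colour and Gaussian pixel
    noise are added on top.
    """
    if height < 32 or width < 32:
        raise ValueError("image size must be at least 32 x 32")
    rng = _style_rng(style, seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float32)

    # background: tinted mucosa with illumination gradient and texture
    gdir = rng.uniform(0, 2 * np.pi)
    gradient = 0.12 * ((xx / width) * np.cos(gdir)
                       + (yy / height) * np.sin(gdir))
    f = style.texture_frequency
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    texture = (0.03 * np.sin(2 * np.pi * f * xx / width + phase1)
               + 0.03 * np.sin(2 * np.pi * f * yy / height + phase2))
    value = np.clip(0.55 * style.illumination_gain + gradient + texture,
                    0.05, 1.0)
    sat = np.full_like(value, 0.45)
    hue = np.full_like(value, style.base_hue)

    # polyp geometry: deformed ellipse, kept inside the frame
    cy = rng.uniform(0.35, 0.65) * height
    cx = rng.uniform(0.35, 0.65) * width
    scale = min(height, width)
    a = rng.uniform(0.14, 0.26) * scale
    b = rng.uniform(0.14, 0.26) * scale
    theta0 = rng.uniform(0, np.pi)
    amps = rng.uniform(0.02, 0.12, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    dy, dx = yy - cy, xx - cx
    ang = np.arctan2(dy, dx)
    ca, sa = np.cos(theta0), np.sin(theta0)
    u = (dx * ca + dy * sa) / a
    v = (-dx * sa + dy * ca) / b
    rho = np.sqrt(u * u + v * v)
    wobble = 1.0 + sum(amp * np.sin((m + 2) * ang + ph)
                       for m, (amp, ph) in enumerate(zip(amps, phases)))
    mask = (rho <= wobble).astype(np.uint8)
    frac = mask.mean()
    # deterministic rescue for the rare out-of-band draw
    tries = 0
    while not 0.02 <= frac <= 0.40 and tries < 8:
        factor = 1.25 if frac < 0.02 else 0.8
        a *= factor
        b *= factor
        u = (dx * ca + dy * sa) / a
        v = (-dx * sa + dy * ca) / b
        rho = np.sqrt(u * u + v * v)
        mask = (rho <= wobble).astype(np.uint8)
        frac = mask.mean()
        tries += 1

    # polyp appearance: hue-shifted, brighter dome with its own texture
    inside = mask.astype(bool)
    dome = np.clip(1.0 - rho, 0.0, 1.0)
    ptex = 0.04 * np.sin(2 * np.pi * 2.0 * f * xx / width + phase2) \
        * np.sin(2 * np.pi * 2.0 * f * yy / height + phase1)
    hue[inside] = (style.base_hue + 18.0) % 360.0
    value[inside] = np.clip(value[inside] + 0.18 * dome[inside]
                            + ptex[inside], 0.05, 1.0)
    sat[inside] = 0.55

    image = _hsv_image(hue, sat, value)

    # specular spots (small bright Gaussian blobs of the style's colour)
    n_spots = rng.poisson(style.specular_spot_rate)
    color = np.asarray(style.specular_spot_color, dtype=np.float32)
    for _ in range(int(n_spots)):
        sy = rng.uniform(0, height)
        sx = rng.uniform(0, width)
        radius = rng.uniform(1.5, 3.5)
        blob = np.exp(-(((yy - sy) ** 2 + (xx - sx) ** 2)
                        / (2 * radius ** 2)))
        image = image + blob[..., None] * color[None, None, :]

    if style.noise_sd > 0:
        image = image + rng.normal(0.0, style.noise_sd,
                                   size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SyntheticSample(image=image, mask=mask, domain_id=style.domain_id,
                           seed=seed)


def _circular_mean_deg(hues: np.ndarray, weights: np.ndarray) -> float:
    rad = np.deg2rad(hues)
    s = float(np.sum(weights * np.sin(rad)))
    c = float(np.sum(weights * np.cos(rad)))
    return float(np.rad2deg(np.arctan2(s, c)) % 360.0)


#: Mixture weight of the dominant source in the target style.  High enough
#: that the dominant source is unambiguously the nearest style even after
#: the perturbations below (the construction must guarantee the recorded
#: nearest-source label is correct).
TARGET_DOMINANT_WEIGHT = 0.8


def make_target_style(source_styles: list[DomainStyle],
                      master_seed: int) -> tuple[DomainStyle, int]:
    """Perturbed convex mixture of source styles with one dominant source.

    Returns the style (domain_id = k+1) and the dominant source's domain_id,
    which is by construction the nearest source in style space.  The target
    additionally carries a cold (green/blue) specular-spot colour and a
    raised spot rate — the kind of bright artefact a private endoscopy rig
    can add that public sets lack.
    """
    k = len(source_styles)
    rng = np.random.default_rng([master_seed, 7919])
    dominant = int(rng.integers(0, k))
    w = np.full(k, (1.0 - TARGET_DOMINANT_WEIGHT) / max(k - 1, 1))
    w[dominant] = TARGET_DOMINANT_WEIGHT if k > 1 else 1.0
    hues = np.array([s.base_hue for s in source_styles])
    gains = np.array([s.illumination_gain for s in source_styles])
    freqs = np.array([s.texture_frequency for s in source_styles])
    rates = np.array([s.specular_spot_rate for s in source_styles])
    sds = np.array([s.noise_sd for s in source_styles])
    hue = (_circular_mean_deg(hues, w) + rng.normal(0.0, 2.0)) % 360.0
    # spot colour: mixture of the source spot colours, nudged toward a cold
    # (green/blue) tone so the target carries its own bright-spot signature
    # without drifting nearer to a non-dominant source
    spot_hue = rng.uniform(120.0, 260.0)
    cold = np.asarray(colorsys.hsv_to_rgb(spot_hue / 360.0, 0.7, 1.0))
    spots = np.array([s.specular_spot_color for s in source_styles])
    spot_rgb = np.clip(0.7 * (w @ spots) + 0.3 * cold, 0.0, 1.0)
    style = DomainStyle(
        domain_id=k + 1,
        base_hue=hue,
        illumination_gain=float(np.dot(w, gains) + rng.normal(0.0, 0.02)),
        texture_frequency=float(np.dot(w, freqs)),
        specular_spot_color=tuple(float(c) for c in spot_rgb),
        specular_spot_rate=float(np.dot(w, rates) + 0.5),
        noise_sd=float(np.dot(w, sds)),
    )
    return style, source_styles[dominant].domain_id


def _render_domain(style: DomainStyle, n: int, height: int, width: int,
                   master_seed: int) -> tuple[np.ndarray, np.ndarray, list]:
    seeds = np.random.default_rng(
        [master_seed, style.domain_id, 104729]).integers(
            0, 2 ** 31 - 1, size=n)
    images = np.empty((n, height, width, 3), dtype=np.float32)
    masks = np.empty((n, height, width), dtype=np.uint8)
    for j, s in enumerate(seeds):
        sample = render_polyp_image(style, height, width, int(s))
        images[j] = sample.image
        masks[j] = sample.mask
    return images, masks, [int(s) for s in seeds]


def generate_benchmark(k: int, n_per_domain: int, height: int = 64,
                       width: int = 64,
                       master_seed: int = 0) -> list[DomainDataset]:
    """Generate ``k`` labeled source domains plus one unlabeled target.

    The returned list holds the k sources first, then the target.  Target
    masks are generated but stored held-out; training code must never read
    them (see :meth:`DomainDataset.heldout_masks`).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_per_domain < 4:
        raise ValueError("n_per_domain must be >= 4")
    datasets: list[DomainDataset] = []
    source_styles = [make_domain_style(i, master_seed)
                     for i in range(1, k + 1)]
    for style in source_styles:
        images, masks, seeds = _render_domain(style, n_per_domain, height,
                                              width, master_seed)
        datasets.append(DomainDataset(
            domain_id=style.domain_id, name=f"source_{style.domain_id}",
            style=style, images=images, masks=masks, labeled=True,
            sample_seeds=seeds))
    target_style, nearest = make_target_style(source_styles, master_seed)
    images, masks, seeds = _render_domain(target_style, n_per_domain, height,
                                          width, master_seed)
    datasets.append(DomainDataset(
        domain_id=target_style.domain_id, name="target", style=target_style,
        images=images, masks=None, labeled=False, sample_seeds=seeds,
        nearest_source=nearest, _heldout_masks=masks))
    return datasets


# -- on-disk layout -----------------------------------------------------------

def save_benchmark(datasets: list[DomainDataset], root) -> None:
    """Write ``<root>/<name>/images|masks/*.png`` plus ``metadata.yaml``."""
    root = Path(root)
    meta = {"domains": []}
    for ds in datasets:
        ddir = root / ds.name
        (ddir / "images").mkdir(parents=True, exist_ok=True)
        (ddir / "masks").mkdir(parents=True, exist_ok=True)
        masks = ds.masks if ds.labeled else ds._heldout_masks
        for j in range(len(ds)):
            write_image(ds.images[j], ddir / "images" / f"{j:04d}.png")
            if masks is not None:
                write_mask(masks[j], ddir / "masks" / f"{j:04d}.png")
        meta["domains"].append({
            "name": ds.name,
            "domain_id": ds.domain_id,
            "labeled": ds.labeled,
            "masks_held_out": not ds.labeled,
            "nearest_source": ds.nearest_source,
            "sample_seeds": ds.sample_seeds,
            "style": dataclasses.asdict(ds.style),
        })
    with open(root / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_benchmark(root) -> list[DomainDataset]:
    root = Path(root)
    with open(root / "metadata.yaml") as fh:
        meta = yaml.safe_load(fh)
    datasets = []
    for dom in meta["domains"]:
        ddir = root / dom["name"]
        img_paths = sorted((ddir / "images").glob("*.png"))
        images = np.stack([read_image(p) for p in img_paths])
        mask_paths = sorted((ddir / "masks").glob("*.png"))
        masks = np.stack([read_mask(p) for p in mask_paths]) \
            if mask_paths else None
        sdict = dict(dom["style"])
        sdict["specular_spot_color"] = tuple(sdict["specular_spot_color"])
        style = DomainStyle(**sdict)
        labeled = dom["labeled"]
        datasets.append(DomainDataset(
            domain_id=dom["domain_id"], name=dom["name"], style=style,
            images=images, masks=masks if labeled else None, labeled=labeled,
            sample_seeds=list(dom["sample_seeds"]),
            nearest_source=dom.get("nearest_source"),
            _heldout_masks=None if labeled else masks))
    return datasets
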