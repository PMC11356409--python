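"""PNG readers/writers shared by all stages.

Images are float32 RGB in [0, 1]; binary masks are written as 0/255 8-bit
PNG and binarized at >127 on read; soft pseudo-labels are stored as 16-bit
grayscale PNG (values scaled to [0, 65535]) so fusion weights survive the
round trip to within 1/65535.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def _open(path) -> Image.Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        return Image.open(path)
    except Exception as exc:  # undecodable
        raise OSError(f"cannot decode image file {path}: {exc}") from exc


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG as H x W x 3 float32 RGB in [0, 1]."""
    with _open(path) as img:
        arr = np.asarray(img.convert("RGB"), dtype=np.float32)
    return arr / 255.0


def write_image(image: np.ndarray, path) -> None:
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(Path(path))


def read_mask(path, threshold: int = 127) -> np.ndarray:
    """Read a mask PNG, binarizing at > threshold; returns uint8 {0, 1}."""
    with _open(path) as img:
        arr = np.asarray(img.convert("L"))
    return (arr > threshold).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a {0,1} (or boolean) mask as a 0/255 8-bit PNG."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr).save(Path(path))


def write_soft_label(label: np.ndarray, path) -> None:
    """Write a [0, 1] soft mask as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(label, dtype=np.float64), 0.0, 1.0)
    arr16 = np.round(arr * 65535.0).astype(np.uint16)
    Image.fromarray(arr16).save(Path(path))


def read_soft_label(path) -> np.ndarray:
    """Read a 16-bit grayscale PNG back to float32 in [0, 1]."""
    with _open(path) as img:
        arr = np.asarray(img, dtype=np.float32)
    return arr / 65535.0
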