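"""Image and mask I/O.

Images are 8-bit RGB PNG/TIFF/JPEG.  Label masks are stored as
indexed-color PNG: the pixel values are the class labels themselves and
the embedded palette only colors them for viewing, so labels survive a
write/read round trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]


def read_image(path) -> np.ndarray:
    """Load an image file as 8-bit RGB (H, W, 3)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_image(path, img: np.ndarray) -> None:
    img = np.asarray(img, dtype=np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img, mode="RGB").save(path)


def read_mask(path) -> np.ndarray:
    """Load an indexed-color mask; returns the integer label grid."""
    with Image.open(path) as im:
        if im.mode != "P":
            im = im.convert("L")
        return np.asarray(im, dtype=np.int64)


def write_mask(path, mask: np.ndarray, palette) -> None:
    """Write labels as indexed PNG with the given [(r,g,b), ...] palette."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= len(palette):
        raise ValueError(f"mask labels outside palette of {len(palette)} entries")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    flat = []
    for rgb in palette:
        flat.extend(rgb)
    im.putpalette(flat)
    im.save(path)
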