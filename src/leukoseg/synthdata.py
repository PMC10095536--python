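"""Synthetic stained blood-smear generator with pixel-perfect masks.

Emulates the structure of Romanowsky-stained smear photographs: a pale,
unevenly lit background, red-blood-cell distractors whose colour is close
to leukocyte cytoplasm, and five leukocyte phenotypes told apart by
nucleus geometry and cytoplasm texture:

* neutrophil — 2-5 nuclear lobes joined by thin filaments;
* eosinophil — two lobes with coarse reddish granules dispersed through
  (and slightly beyond) the cytoplasm;
* basophil — nucleus largely obscured by dense dark granules;
* monocyte — kidney / horseshoe nucleus;
* lymphocyte — large round nucleus with a thin cytoplasm rim.

Geometry is a deliberate caricature: the generator exists to exercise the
enhancement/training/evaluation pipeline with exact ground truth, not to
match real staining statistics.  Cells are drawn anti-aliased on a 2x
supersampled canvas; the label mask is the per-block majority label, so
every cell pixel carries its cell's class and background/RBC pixels are 0.

Single-cell tiles can be stitched into 2x2 / 3x3 / 4x4 grids on a
512 x 512 canvas, mirroring how multi-cell evaluation images are composed
from single-cell datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import color as skcolor
from skimage.transform import resize

from . import io

__all__ = [
    "DEFAULT_PALETTE",
    "CLASS_NAMES",
    "CellPhenotype",
    "PHENOTYPES",
    "SyntheticSmearSpec",
    "generate_smear",
    "stitch_tiles",
    "write_dataset",
    "sample_classes",
    "make_easy_task",
]

#: label -> display colour for indexed masks (0 = background)
DEFAULT_PALETTE = (
    (0, 0, 0),        # background
    (228, 26, 28),    # neutrophil
    (255, 127, 0),    # eosinophil
    (152, 78, 163),   # basophil
    (55, 126, 184),   # monocyte
    (77, 175, 74),    # lymphocyte
)

CLASS_NAMES = ("background", "neutrophil", "eosinophil", "basophil",
               "monocyte", "lymphocyte")


@dataclass
class CellPhenotype:
    """Drawing parameters of one leukocyte class."""

    class_id: int
    nucleus_shape: str            # lobed | bilobed | obscured | kidney | round
    granular: bool
    size_range: tuple             # cell radius range, px on a 256 canvas
    cytoplasm_color: tuple
    nucleus_color: tuple
    granule_color: tuple | None = None


PHENOTYPES = {
    1: CellPhenotype(1, "lobed", False, (30, 42), (238, 210, 218), (92, 58, 132)),
    2: CellPhenotype(2, "bilobed", True, (30, 42), (242, 205, 195), (102, 62, 128),
                     (205, 75, 70)),
    3: CellPhenotype(3, "obscured", True, (28, 40), (222, 202, 232), (70, 48, 108),
                     (66, 44, 104)),
    4: CellPhenotype(4, "kidney", False, (32, 44), (204, 208, 228), (110, 78, 150)),
    5: CellPhenotype(5, "round", False, (24, 34), (178, 196, 232), (78, 48, 122)),
}


@dataclass
class SyntheticSmearSpec:
    """Scene description; every random choice derives from ``seed``."""

    canvas_size: tuple = (256, 256)
    n_cells: int = 1
    class_mix: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    background_hue_range: tuple = (0.88, 0.99)
    background_brightness_range: tuple = (195, 240)
    rbc_density: float = 2.0e-4
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if len(self.class_mix) != 5 or abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must be 5 probabilities summing to 1")


def sample_classes(n: int, class_mix, rng: np.random.Generator) -> np.ndarray:
    """Draw n leukocyte class ids (1..5) from the mix."""
    return rng.choice(np.arange(1, 6), size=n, p=np.asarray(class_mix))


# -- drawing primitives (supersampled float canvas) ------------------------

_SS = 2  # supersampling factor


def _local_grid(h, w, cy, cx, r):
    """Clipped bounding-box coordinate grids around (cy, cx)."""
    pad = int(np.ceil(r * 1.6)) + 2
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return (slice(y0, y1), slice(x0, x1)), yy.astype(float), xx.astype(float)


def _blob(yy, xx, cy, cx, r, rng, wobble=0.12, n_harm=3):
    """Boolean mask of a smoothly perturbed disk."""
    theta = np.arctan2(yy - cy, xx - cx)
    rad = np.full_like(theta, float(r))
    for k in range(2, 2 + n_harm):
        rad += r * wobble / n_harm * rng.uniform(0.3, 1.0) * np.sin(
            k * theta + rng.uniform(0, 2 * np.pi))
    dist = np.hypot(yy - cy, xx - cx)
    return dist < rad


def _disk(yy, xx, cy, cx, r):
    return np.hypot(yy - cy, xx - cx) < r


def _segment(yy, xx, p0, p1, thickness):
    """Pixels within ``thickness`` of the segment p0-p1."""
    v = np.array(p1) - np.array(p0)
    L2 = float(v @ v) + 1e-12
    t = np.clip(((yy - p0[0]) * v[0] + (xx - p0[1]) * v[1]) / L2, 0.0, 1.0)
    dy = yy - (p0[0] + t * v[0])
    dx = xx - (p0[1] + t * v[1])
    return np.hypot(dy, dx) < thickness


def _nucleus_mask(shape, yy, xx, cy, cx, r, rng):
    """Nucleus footprint for one phenotype; connected by construction
    (lobes are joined by filaments) except that the eosinophil's granules
    are drawn separately in the image layer only."""
    if shape == "round":
        return _blob(yy, xx, cy, cx, 0.62 * r, rng, wobble=0.08)
    if shape == "obscured":
        return _blob(yy, xx, cy, cx, 0.58 * r, rng, wobble=0.10)
    if shape == "kidney":
        body = _blob(yy, xx, cy, cx, 0.56 * r, rng, wobble=0.06)
        ang = rng.uniform(0, 2 * np.pi)
        bite = _disk(yy, xx, cy + 0.45 * r * np.sin(ang), cx + 0.45 * r * np.cos(ang),
                     0.38 * r)
        return body & ~bite
    # lobed (2-5) and bilobed (exactly 2)
    n_lobes = 2 if shape == "bilobed" else int(rng.integers(2, 6))
    base = rng.uniform(0, 2 * np.pi)
    centers = []
    for i in range(n_lobes):
        ang = base + 2 * np.pi * i / n_lobes + rng.uniform(-0.3, 0.3)
        rad = 0.34 * r * rng.uniform(0.8, 1.1)
        centers.append((cy + rad * np.sin(ang), cx + rad * np.cos(ang)))
    mask = np.zeros(yy.shape, dtype=bool)
    for (ly, lx) in centers:
        mask |= _blob(yy, xx, ly, lx, 0.26 * r, rng, wobble=0.10)
    for (a, b) in zip(centers, centers[1:]):
        mask |= _segment(yy, xx, a, b, 0.07 * r)
    return mask


def _jitter(rgb, rng, amount=10.0):
    return np.clip(np.asarray(rgb, float) + rng.normal(0, amount, 3), 0, 255)


def _paint(img, box, where, rgb):
    img[box][where] = rgb


def _draw_cell(img, mask_sup, cls: int, cy, cx, r, rng):
    pheno = PHENOTYPES[cls]
    h, w = mask_sup.shape
    box, yy, xx = _local_grid(h, w, cy, cx, r)
    cyto = _blob(yy, xx, cy, cx, r, rng, wobble=0.14)
    _paint(img, box, cyto, _jitter(pheno.cytoplasm_color, rng))
    nucleus = _nucleus_mask(pheno.nucleus_shape, yy, xx, cy, cx, r, rng) & cyto
    _paint(img, box, nucleus, _jitter(pheno.nucleus_color, rng))
    cell = cyto.copy()
    if pheno.granular:
        # granule dots; eosinophil granules may scatter slightly outside
        spread = 1.15 if pheno.nucleus_shape == "bilobed" else 0.92
        n_gran = int(r * r * 0.10)
        ang = rng.uniform(0, 2 * np.pi, n_gran)
        rad = r * spread * np.sqrt(rng.uniform(0, 1, n_gran))
        for gy, gx in zip(cy + rad * np.sin(ang), cx + rad * np.cos(ang)):
            dot = _disk(yy, xx, gy, gx, rng.uniform(1.2, 2.6))
            _paint(img, box, dot, _jitter(pheno.granule_color, rng, 14))
            cell |= dot
    mask_sup[box][cell] = cls


def _draw_rbc(img, h, w, cy, cx, r, rng):
    box, yy, xx = _local_grid(h, w, cy, cx, r)
    body = _blob(yy, xx, cy, cx, r, rng, wobble=0.07)
    rim = _jitter((232, 158, 152), rng, 8)
    _paint(img, box, body, rim)
    center = _disk(yy, xx, cy, cx, 0.5 * r)
    _paint(img, box, body & center, np.clip(rim + 22, 0, 255))  # pale biconcave middle


def _background(hh, ww, spec, rng):
    hue = rng.uniform(*spec.background_hue_range) % 1.0
    sat = rng.uniform(0.05, 0.14)
    base_v = rng.uniform(*spec.background_brightness_range) / 255.0
    # smooth illumination gradient — backgrounds are not uniformly lit
    ang = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:hh, 0:ww]
    ramp = (yy * np.sin(ang) + xx * np.cos(ang)) / max(hh, ww)
    v = np.clip(base_v + rng.uniform(0.03, 0.10) * (ramp - ramp.mean()) * 2, 0.05, 1.0)
    hsv = np.stack([np.full((hh, ww), hue), np.full((hh, ww), sat), v], axis=2)
    return skcolor.hsv2rgb(hsv) * 255.0


def generate_smear(spec: SyntheticSmearSpec):
    """Render one smear; returns (rgb uint8 (H,W,3), mask int (H,W)).

    Leukocytes never overlap one another (bounded retries, then an error
    suggesting fewer cells); RBC distractors may crowd freely and are
    drawn underneath.  Bit-identical for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas_size
    hh, ww = h * _SS, w * _SS
    img = _background(hh, ww, spec, rng)
    mask_sup = np.zeros((hh, ww), dtype=np.int64)

    n_rbc = rng.poisson(spec.rbc_density * h * w)
    for _ in range(n_rbc):
        r = _SS * rng.uniform(9, 14) * (h / 256.0)
        _draw_rbc(img, hh, ww, rng.uniform(0, hh), rng.uniform(0, ww), r, rng)

    classes = sample_classes(spec.n_cells, spec.class_mix, rng)
    placed = []  # (cy, cx, r)
    for cls in classes:
        lo, hi = PHENOTYPES[int(cls)].size_range
        r = _SS * rng.uniform(lo, hi) * (h / 256.0)
        for attempt in range(200):
            cy = rng.uniform(1.2 * r, hh - 1.2 * r)
            cx = rng.uniform(1.2 * r, ww - 1.2 * r)
            if all(np.hypot(cy - py, cx - px) > 1.15 * (r + pr)
                   for py, px, pr in placed):
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells on a "
                f"{spec.canvas_size} canvas; try fewer cells or a larger canvas")
        placed.append((cy, cx, r))
        _draw_cell(img, mask_sup, int(cls), cy, cx, r, rng)

    # downsample: block-mean image (anti-aliased), block-majority mask
    img = img.reshape(h, _SS, w, _SS, 3).mean(axis=(1, 3))
    img = img + rng.normal(0, spec.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    mask = _majority_downsample(mask_sup, _SS)
    return img, mask


def _majority_downsample(mask_sup: np.ndarray, ss: int) -> np.ndarray:
    h, w = mask_sup.shape[0] // ss, mask_sup.shape[1] // ss
    blocks = mask_sup.reshape(h, ss, w, ss)
    n_cls = int(mask_sup.max()) + 1
    counts = np.stack([(blocks == c).sum(axis=(1, 3)) for c in range(n_cls)], axis=0)
    return counts.argmax(axis=0).astype(np.int64)


def stitch_tiles(tiles, grid: int):
    """Compose grid x grid single-cell tiles into one 512 x 512 scene.

    Tiles are (image, mask) pairs; each is resized to its cell of the
    512-pixel canvas (nearest-neighbour for masks so labels stay exact)
    and arranged row-major.
    """
    if grid not in (2, 3, 4):
        raise ValueError("grid must be 2, 3 or 4")
    if len(tiles) != grid * grid:
        raise ValueError(f"expected {grid * grid} tiles for a {grid}x{grid} grid, "
                         f"got {len(tiles)}")
    edges = [round(i * 512 / grid) for i in range(grid + 1)]
    out_img = np.zeros((512, 512, 3), dtype=np.uint8)
    out_mask = np.zeros((512, 512), dtype=np.int64)
    for idx, (img, mask) in enumerate(tiles):
        gy, gx = divmod(idx, grid)
        hy, wx = edges[gy + 1] - edges[gy], edges[gx + 1] - edges[gx]
        rimg = resize(np.asarray(img, float), (hy, wx, 3), order=1,
                      preserve_range=True, anti_aliasing=True)
        rmask = resize(np.asarray(mask), (hy, wx), order=0,
                       preserve_range=True, anti_aliasing=False).astype(np.int64)
        out_img[edges[gy]:edges[gy + 1], edges[gx]:edges[gx + 1]] = \
            np.clip(np.rint(rimg), 0, 255).astype(np.uint8)
        out_mask[edges[gy]:edges[gy + 1], edges[gx]:edges[gx + 1]] = rmask
    return out_img, out_mask


def write_dataset(specs, out_dir, palette=DEFAULT_PALETTE) -> dict:
    """Render all specs to ``out_dir`` as PNG pairs plus a JSON manifest."""
    out_dir = Path(out_dir)
    entries = []
    for i, spec in enumerate(specs):
        img, mask = generate_smear(spec)
        img_rel, mask_rel = f"images/smear_{i:04d}.png", f"masks/smear_{i:04d}.png"
        io.write_image(out_dir / img_rel, img)
        io.write_mask(out_dir / mask_rel, mask, palette)
        labels, counts = np.unique(mask, return_counts=True)
        entries.append({
            "image": img_rel,
            "mask": mask_rel,
            "seed": spec.seed,
            "class_counts": {int(l): int(c) for l, c in zip(labels, counts)},
        })
    manifest = {"n_pairs": len(entries), "palette": [list(p) for p in palette],
                "class_names": list(CLASS_NAMES), "pairs": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# -- easy blob task for CPU-scale learning checks --------------------------

_EASY_COLORS = {1: (205, 60, 60), 2: (60, 90, 205), 3: (60, 185, 85)}


def make_easy_task(n_images: int, size: int = 64, seed: int = 0,
                   cells_range=(2, 4), noise_sigma: float = 4.0):
    """Colour-separable blob scenes with 4 classes (background + 3).

    A deliberately easy segmentation task — each foreground class has a
    distinct hue on a pale background — used to verify that the network
    and training loop actually learn within a CPU-scale step budget.
    Returns a list of (image uint8 (size,size,3), mask (size,size)) pairs.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_images):
        img = np.full((size, size, 3), 0.0) + rng.uniform(215, 235, 3)
        mask = np.zeros((size, size), dtype=np.int64)
        placed = []
        n_cells = int(rng.integers(cells_range[0], cells_range[1] + 1))
        for _c in range(n_cells):
            cls = int(rng.integers(1, 4))
            r = rng.uniform(size * 0.12, size * 0.2)
            for _try in range(100):
                cy, cx = rng.uniform(r, size - r, 2)
                if all(np.hypot(cy - py, cx - px) > r + pr for py, px, pr in placed):
                    break
            else:
                continue
            placed.append((cy, cx, r))
            yy, xx = np.mgrid[0:size, 0:size].astype(float)
            blob = _blob(yy, xx, cy, cx, r, rng, wobble=0.10)
            img[blob] = _jitter(_EASY_COLORS[cls], rng, 6)
            mask[blob] = cls
        img = np.clip(np.rint(img + rng.normal(0, noise_sigma, img.shape)),
                      0, 255).astype(np.uint8)
        pairs.append((img, mask))
    return pairs
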