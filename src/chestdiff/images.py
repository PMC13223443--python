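"""Image containers, pixel-domain conversion, NPZ/PNG I/O, and synthetic
chest phantoms.

The phantom generator produces 28x28 grayscale pseudo-radiographs: a bright
elliptical thorax on a dark background, two darker lung fields, a brighter
mediastinal column and faint rib bands.  Per-image variability knobs mirror
the axes along which real chest X-rays vary: overall body scale (BMI / body
shape), rotation (posture), lung-field area (lung volume), global brightness
(gray value), and translation jitter (field of view).  The phantoms are
intentionally crude: they provide a learnable, low-entropy image distribution
for desk-scale experiments and are not radiologically plausible.

Coordinate convention: row-major, origin top-left, 0-based pixel indices.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "Domain",
    "ImageBatch",
    "PhantomParams",
    "normalize",
    "denormalize",
    "generate_phantoms",
    "read_medmnist_npz",
    "write_medmnist_npz",
    "write_image_grid",
    "read_image_grid",
]


class Domain(enum.Enum):
    """Pixel value domain tag."""

    UINT8 = "uint8"        # integers in [0, 255]
    NORMALIZED = "normalized"  # reals in [-1, 1]


@dataclass
class ImageBatch:
    """A stack of grayscale images: (batch, channel=1, height, width)."""

    pixels: np.ndarray
    domain: Domain

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4 or self.pixels.shape[1] != 1:
            raise ValueError(
                f"pixels must be rank-4 (B, 1, H, W), got shape {self.pixels.shape}"
            )
        if self.domain is Domain.UINT8:
            if self.pixels.dtype != np.uint8:
                raise ValueError(f"UINT8 batch must be uint8, got {self.pixels.dtype}")
        else:
            # Clean images live in [-1, 1]; diffusion latents x_t are Gaussian-
            # corrupted and legitimately exceed it, so only finiteness is enforced.
            if not np.issubdtype(self.pixels.dtype, np.floating):
                raise ValueError("NORMALIZED batch must be floating point")
            if not np.all(np.isfinite(self.pixels)):
                raise ValueError("NORMALIZED batch contains non-finite values")

    def __len__(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


def normalize(x: ImageBatch) -> ImageBatch:
    """Affine map [0, 255] -> [-1, 1]."""
    if x.domain is not Domain.UINT8:
        raise ValueError("normalize expects a UINT8 batch; input is already normalized")
    return ImageBatch(x.pixels.astype(np.float32) / 127.5 - 1.0, Domain.NORMALIZED)


def denormalize(x: ImageBatch) -> ImageBatch:
    """Affine map [-1, 1] -> [0, 255]: clamp, rescale, round half away from zero."""
    if x.domain is not Domain.NORMALIZED:
        raise ValueError("denormalize expects a NORMALIZED batch")
    v = np.clip(x.pixels.astype(np.float64), -1.0, 1.0)
    v = (v + 1.0) * 127.5
    out = np.floor(v + 0.5).astype(np.uint8)  # round half away from zero (values >= 0)
    return ImageBatch(out, Domain.UINT8)


# ---------------------------------------------------------------------------
# Synthetic chest phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomParams:
    """Configuration of the phantom population.

    Ranges are sampled uniformly per image.  Defaults give a population with
    visible but moderate variability across every axis.
    """

    n: int = 16
    seed: int = 0
    size: int = 28
    body_scale_range: tuple[float, float] = (0.85, 1.10)
    rotation_range_deg: tuple[float, float] = (-8.0, 8.0)
    lung_area_range: tuple[float, float] = (0.22, 0.38)
    brightness_range: tuple[float, float] = (0.75, 1.05)
    crop_jitter_px: int = 1

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("body_scale_range", "rotation_range_deg", "lung_area_range",
                     "brightness_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"{name} is an empty interval: ({lo}, {hi})")
        if self.body_scale_range[0] <= 0 or self.lung_area_range[0] <= 0:
            raise ValueError("scale and lung-area ranges must be positive")
        if self.brightness_range[0] <= 0:
            raise ValueError("brightness range must be positive")
        if self.crop_jitter_px < 0:
            raise ValueError("crop_jitter_px must be >= 0")


def _smoothstep(d: np.ndarray, width: float) -> np.ndarray:
    """1 inside (d <= 0), 0 outside, smooth ramp of the given width."""
    t = np.clip(1.0 - d / width, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def phantom_lung_mask(params: "PhantomParams", index_draws: dict) -> np.ndarray:
    """Boolean mask of the lung fields for one image's sampled draws."""
    return index_draws["lung_mask"]


def generate_phantoms(params: PhantomParams, return_masks: bool = False):
    """Generate ``params.n`` seeded synthetic chest phantoms.

    Returns an ``ImageBatch`` in the UINT8 domain (and optionally the boolean
    lung/thorax masks used during rendering, for population statistics).
    Identical parameters produce bitwise-identical batches.
    """
    rng = np.random.default_rng(params.seed)
    size = params.size
    half = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    ux = (xx - half) / half  # [-1, 1], columns
    uy = (yy - half) / half  # [-1, 1], rows

    images = np.empty((params.n, 1, size, size), dtype=np.uint8)
    lung_masks = np.empty((params.n, size, size), dtype=bool)
    thorax_masks = np.empty((params.n, size, size), dtype=bool)

    for i in range(params.n):
        scale = rng.uniform(*params.body_scale_range)
        theta = np.deg2rad(rng.uniform(*params.rotation_range_deg))
        lung_area = rng.uniform(*params.lung_area_range)
        brightness = rng.uniform(*params.brightness_range)
        jx = rng.integers(-params.crop_jitter_px, params.crop_jitter_px + 1)
        jy = rng.integers(-params.crop_jitter_px, params.crop_jitter_px + 1)

        # shift (field of view), then rotate (posture)
        px = ux - jx / half
        py = uy - jy / half
        c, s = np.cos(theta), np.sin(theta)
        rx = c * px + s * py
        ry = -s * px + c * py

        # thorax: soft-edged ellipse
        ax_t, ay_t = 0.80 * scale, 0.94 * scale
        d_thorax = np.sqrt((rx / ax_t) ** 2 + (ry / ay_t) ** 2) - 1.0
        thorax = _smoothstep(d_thorax, 0.12)

        # lung fields: two darker ellipses; area knob scales both axes
        la = np.sqrt(lung_area / 0.30)
        ax_l, ay_l = 0.26 * scale * la, 0.52 * scale * la
        cx = 0.36 * scale
        d_left = np.sqrt(((rx + cx) / ax_l) ** 2 + ((ry + 0.05) / ay_l) ** 2) - 1.0
        d_right = np.sqrt(((rx - cx) / ax_l) ** 2 + ((ry + 0.05) / ay_l) ** 2) - 1.0
        lungs = np.maximum(_smoothstep(d_left, 0.10), _smoothstep(d_right, 0.10))

        # mediastinum: brighter central column inside the thorax
        medi = _smoothstep(np.abs(rx) / (0.14 * scale) - 1.0, 0.3) * thorax

        # faint rib bands modulating the lung fields
        ribs = 0.5 * (1.0 + np.sin(ry * 9.0 * np.pi / scale))

        img = 25.0 + 175.0 * thorax
        img -= 80.0 * lungs * (1.0 - 0.25 * ribs)
        img += 35.0 * medi
        img *= brightness
        img += rng.normal(0.0, 2.0, size=(size, size))

        images[i, 0] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        lung_masks[i] = (np.minimum(d_left, d_right) < -0.15) & (d_thorax < -0.05)
        thorax_masks[i] = (d_thorax < -0.05) & ~lung_masks[i]

    batch = ImageBatch(images, Domain.UINT8)
    if return_masks:
        return batch, lung_masks, thorax_masks
    return batch


# ---------------------------------------------------------------------------
# MedMNIST-layout NPZ archives
# ---------------------------------------------------------------------------

_SPLITS = ("train", "val", "test")


def read_medmnist_npz(path, split: str = "train") -> tuple[ImageBatch, np.ndarray]:
    """Read one split of a MedMNIST-layout NPZ archive.

    The archive stores ``<split>_images`` (N x H x W uint8) and
    ``<split>_labels``.  Images are promoted to (N, 1, H, W); labels are
    returned untouched (they are not consumed by training).  Non-28x28 images
    are accepted with a warning to allow higher-resolution archives.
    """
    if split not in _SPLITS:
        raise ValueError(f"split must be one of {_SPLITS}, got {split!r}")
    with np.load(path) as archive:
        img_key, lab_key = f"{split}_images", f"{split}_labels"
        if img_key not in archive or lab_key not in archive:
            raise KeyError(
                f"archive {path} lacks keys {img_key!r}/{lab_key!r}; expected the "
                f"MedMNIST layout with keys <split>_images and <split>_labels for "
                f"splits {_SPLITS}"
            )
        images = archive[img_key]
        labels = archive[lab_key]
    if images.ndim == 3:
        images = images[:, None, :, :]
    if images.shape[-2:] != (28, 28):
        import warnings

        warnings.warn(
            f"archive images are {images.shape[-2]}x{images.shape[-1]}, not 28x28; "
            "accepted as-is",
            stacklevel=2,
        )
    return ImageBatch(images.astype(np.uint8), Domain.UINT8), labels


def write_medmnist_npz(path, splits: dict[str, tuple[ImageBatch, np.ndarray]]) -> Path:
    """Write ImageBatches into the MedMNIST NPZ key layout (uncompressed)."""
    arrays = {}
    for split, (batch, labels) in splits.items():
        if split not in _SPLITS:
            raise ValueError(f"unknown split {split!r}")
        if batch.domain is not Domain.UINT8:
            raise ValueError("archives store UINT8 images; denormalize first")
        arrays[f"{split}_images"] = batch.pixels[:, 0]
        arrays[f"{split}_labels"] = np.asarray(labels)
    path = Path(path)
    np.savez(path, **arrays)
    return path


# ---------------------------------------------------------------------------
# PNG grids
# ---------------------------------------------------------------------------


def write_image_grid(x: ImageBatch, path, columns: int = 8) -> Path:
    """Tile a batch row-major into one lossless 8-bit grayscale PNG."""
    if len(x) == 0:
        raise ValueError("cannot write an empty batch")
    if columns < 1:
        raise ValueError("columns must be >= 1")
    pix = x.pixels if x.domain is Domain.UINT8 else denormalize(x).pixels
    n, _, h, w = pix.shape
    rows = -(-n // columns)
    canvas = np.zeros((rows * h, columns * w), dtype=np.uint8)
    for i in range(n):
        r, c = divmod(i, columns)
        canvas[r * h : (r + 1) * h, c * w : (c + 1) * w] = pix[i, 0]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(canvas, mode="L").save(path, format="PNG")
    return path


def read_image_grid(path, image_size: int = 28, n: int | None = None) -> ImageBatch:
    """De-tile a PNG grid written by :func:`write_image_grid`."""
    canvas = np.asarray(Image.open(path).convert("L"))
    rows, cols = canvas.shape[0] // image_size, canvas.shape[1] // image_size
    tiles = []
    for r in range(rows):
        for c in range(cols):
            tiles.append(
                canvas[
                    r * image_size : (r + 1) * image_size,
                    c * image_size : (c + 1) * image_size,
                ]
            )
    pix = np.stack(tiles)[:, None]
    if n is not None:
        pix = pix[:n]
    return ImageBatch(pix.astype(np.uint8), Domain.UINT8)
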