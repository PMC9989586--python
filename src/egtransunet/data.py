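"""Dataset I/O, resizing, augmentation, splitting, and a synthetic
lesion-image generator.

Samples are (image, mask) pairs: the image is a ``(C, H, W)`` float array
in [0, 1], the mask a strictly binary ``(H, W)`` array.  Every stage of
the pipeline preserves image/mask spatial alignment and mask binarity,
and all randomness flows from explicit seeds.

The synthetic generator emulates the kind of data this network targets:
one or more bright, textured, irregularly shaped blobs with blurred
boundaries on a cluttered background — e.g. polyps in endoscopy frames or
nuclei in microscopy.  The mask is the exact pre-blur blob support, so
ground truth is unambiguous even where the image boundary is soft.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform


@dataclass
class SegmentationSample:
    """An image with its per-pixel binary annotation."""

    image: np.ndarray  # (C, H, W) float in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    id: str

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3:
            raise ValueError("image must be (C, H, W)")
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[1:]} and mask {self.mask.shape} sizes differ"
            )
        uniq = np.unique(self.mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask must be binary, found values {uniq[:8]}")
        self.mask = self.mask.astype(np.uint8)


@dataclass
class SyntheticParams:
    """Knobs of the synthetic lesion generator (sizes in pixels)."""

    image_size: Tuple[int, int] = (64, 64)
    n_blobs: Tuple[int, int] = (1, 3)        # inclusive range per image
    radius: Tuple[float, float] = (6.0, 12.0)
    contrast: float = 0.45                   # blob vs background intensity gap
    boundary_blur_sigma: float = 1.5
    noise_sigma: float = 0.05
    texture_strength: float = 0.15
    deform: float = 0.25                     # radial deformation cap (fraction of radius)
    seed: int = 0

    def __post_init__(self):
        if self.radius[0] < 2:
            raise ValueError("minimum radius must be >= 2 px")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        h, w = self.image_size
        if self.radius[1] * (1 + self.deform) * 2 >= min(h, w):
            raise ValueError("largest blob cannot fit within the canvas")


@dataclass
class SplitSpec:
    ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be nonnegative")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(self.ratios)}")


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_IMAGE_EXTS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


def _scan(directory) -> dict:
    files = {}
    for p in sorted(Path(directory).iterdir()):
        if p.suffix.lower() in _IMAGE_EXTS:
            files[p.stem] = p
    return files


def load_pairs(image_dir, mask_dir) -> List[SegmentationSample]:
    """Load image/mask pairs matched one-to-one by filename stem.

    Images are decoded to [0, 1] float (grayscale replicated to 3
    channels); masks are binarized at half their dtype range.  Samples
    are sorted by id.  Unpaired files raise with the offending stems.
    """
    import imageio.v3 as iio

    images, masks = _scan(image_dir), _scan(mask_dir)
    missing_masks = sorted(set(images) - set(masks))
    missing_images = sorted(set(masks) - set(images))
    if missing_masks or missing_images:
        raise ValueError(
            f"unpaired files: images without masks {missing_masks}, "
            f"masks without images {missing_images}"
        )
    samples = []
    for stem in sorted(images):
        img = np.asarray(iio.imread(images[stem])).astype(np.float64)
        if np.issubdtype(iio.imread(images[stem]).dtype, np.integer):
            img /= 255.0
        if img.ndim == 2:
            img = np.stack([img] * 3)
        else:
            img = img[..., :3].transpose(2, 0, 1)  # HWC -> CHW, drop alpha
        msk = np.asarray(iio.imread(masks[stem]))
        if msk.ndim == 3:
            msk = msk[..., 0]
        scale = 255.0 if msk.dtype != np.bool_ and msk.max() > 1 else 1.0
        samples.append(
            SegmentationSample(np.clip(img, 0, 1), (msk >= 0.5 * scale).astype(np.uint8), stem)
        )
    return samples


def save_dataset(samples: Sequence[SegmentationSample], out_dir) -> None:
    """Write samples as images/ + masks/ PNG pairs with a manifest CSV."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"])
        for s in samples:
            img = (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8).transpose(1, 2, 0)
            iio.imwrite(out / "images" / f"{s.id}.png", img)
            iio.imwrite(out / "masks" / f"{s.id}.png", (s.mask * 255).astype(np.uint8))
            writer.writerow([s.id])


# --------------------------------------------------------------------------
# Resizing
# --------------------------------------------------------------------------


def resize(sample: SegmentationSample, size: Tuple[int, int] = (320, 320)) -> SegmentationSample:
    """Resize: image bilinearly, mask by nearest neighbour (stays binary)."""
    h, w = size
    if sample.image.shape[1:] == (h, w):
        return SegmentationSample(sample.image.copy(), sample.mask.copy(), sample.id)
    image = np.stack(
        [
            sktransform.resize(ch, (h, w), order=1, anti_aliasing=True, preserve_range=True)
            for ch in sample.image
        ]
    )
    mask = sktransform.resize(
        sample.mask.astype(float), (h, w), order=0, anti_aliasing=False, preserve_range=True
    )
    return SegmentationSample(np.clip(image, 0, 1), (mask >= 0.5).astype(np.uint8), sample.id)


# --------------------------------------------------------------------------
# Augmentation
# --------------------------------------------------------------------------


@dataclass
class AugmentConfig:
    hflip: bool = True
    vflip: bool = True
    rotate: bool = True
    max_rotation_deg: float = 30.0
    crop: bool = True
    crop_scale: Tuple[float, float] = (0.8, 1.0)
    grid_distortion: bool = True
    grid_cells: int = 5
    grid_jitter: float = 0.1


def flip_horizontal(sample: SegmentationSample) -> SegmentationSample:
    return SegmentationSample(sample.image[:, :, ::-1].copy(), sample.mask[:, ::-1].copy(), sample.id)


def flip_vertical(sample: SegmentationSample) -> SegmentationSample:
    return SegmentationSample(sample.image[:, ::-1, :].copy(), sample.mask[::-1, :].copy(), sample.id)


def rotate90(sample: SegmentationSample, k: int = 1) -> SegmentationSample:
    return SegmentationSample(
        np.rot90(sample.image, k, axes=(1, 2)).copy(),
        np.rot90(sample.mask, k).copy(),
        sample.id,
    )


def _warp_pair(image, mask, coords):
    """Apply one coordinate map to both streams (image order 1, mask order 0)."""
    warped_img = np.stack(
        [ndimage.map_coordinates(ch, coords, order=1, mode="reflect") for ch in image]
    )
    warped_mask = ndimage.map_coordinates(mask.astype(float), coords, order=0, mode="reflect")
    return np.clip(warped_img, 0, 1), (warped_mask >= 0.5).astype(np.uint8)


def _grid_distortion(image, mask, rng, cells: int, jitter: float):
    h, w = mask.shape
    # jittered control-point offsets, interpolated to a dense displacement field
    ctrl = rng.uniform(-jitter, jitter, size=(2, cells + 1, cells + 1))
    ctrl[:, 0, :] = ctrl[:, -1, :] = ctrl[:, :, 0] = ctrl[:, :, -1] = 0.0  # pin the border
    dy = sktransform.resize(ctrl[0], (h, w), order=1, preserve_range=True) * (h / cells)
    dx = sktransform.resize(ctrl[1], (h, w), order=1, preserve_range=True) * (w / cells)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coords = np.stack([yy + dy, xx + dx])
    return _warp_pair(image, mask, coords)


def augment(
    sample: SegmentationSample,
    seed: int,
    config: Optional[AugmentConfig] = None,
) -> SegmentationSample:
    """Random geometric augmentation, identical on image and mask.

    Flips (p=0.5 each), rotation uniform in ±max_rotation_deg, random
    crop (scale in crop_scale, resized back to the working resolution)
    and grid distortion.  Fully deterministic given ``seed``.
    """
    config = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    image, mask = sample.image.copy(), sample.mask.copy()
    h, w = mask.shape

    if config.hflip and rng.random() < 0.5:
        image, mask = image[:, :, ::-1], mask[:, ::-1]
    if config.vflip and rng.random() < 0.5:
        image, mask = image[:, ::-1, :], mask[::-1, :]
    if config.rotate:
        angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
        image = np.stack(
            [
                sktransform.rotate(ch, angle, order=1, mode="reflect", preserve_range=True)
                for ch in image
            ]
        )
        mask = sktransform.rotate(
            mask.astype(float), angle, order=0, mode="reflect", preserve_range=True
        ) >= 0.5
        mask = mask.astype(np.uint8)
    if config.crop:
        scale = rng.uniform(*config.crop_scale)
        ch_, cw_ = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
        top = rng.integers(0, h - ch_ + 1)
        left = rng.integers(0, w - cw_ + 1)
        cropped = SegmentationSample(
            image[:, top : top + ch_, left : left + cw_].copy(),
            mask[top : top + ch_, left : left + cw_].copy(),
            sample.id,
        )
        resized = resize(cropped, (h, w))
        image, mask = resized.image, resized.mask
    if config.grid_distortion:
        image, mask = _grid_distortion(
            image, mask, rng, config.grid_cells, config.grid_jitter
        )
    return SegmentationSample(np.clip(np.ascontiguousarray(image), 0, 1),
                              np.ascontiguousarray(mask), sample.id)


# --------------------------------------------------------------------------
# Splitting
# --------------------------------------------------------------------------


def split(
    samples: Sequence[SegmentationSample], spec: SplitSpec
) -> Tuple[list, list, list]:
    """Deterministic random split into disjoint, exhaustive train/val/test."""
    n = len(samples)
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(round(spec.ratios[0] * n))
    n_val = int(round(spec.ratios[1] * n))
    n_val = min(n_val, n - n_train)
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    pick = lambda idx: [samples[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)


# --------------------------------------------------------------------------
# Synthetic generator
# --------------------------------------------------------------------------


def _blob_mask(h, w, cy, cx, r, aspect, theta, deform_amp, deform_phase, n_lobes=3):
    """Support of a deformed ellipse: r(phi) = r * (1 + amp*cos(n*phi+phase))."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    y, x = yy - cy, xx - cx
    # rotate into the ellipse frame, squeeze one axis
    yr = (y * np.cos(theta) - x * np.sin(theta)) / aspect
    xr = y * np.sin(theta) + x * np.cos(theta)
    rho = np.hypot(yr, xr)
    phi = np.arctan2(yr, xr)
    boundary = r * (1.0 + deform_amp * np.cos(n_lobes * phi + deform_phase))
    return rho <= boundary


def _smooth_noise(rng, h, w, sigma):
    base = rng.normal(size=(h, w))
    sm = ndimage.gaussian_filter(base, sigma)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_synthetic(n: int, params: Optional[SyntheticParams] = None) -> List[SegmentationSample]:
    """Generate ``n`` synthetic lesion images with exact binary masks.

    Each image holds ``n_blobs`` deformed elliptical blobs (mask = exact
    pre-blur support) brightened by ``contrast`` over a cluttered
    background; the image-side boundary is softened with a Gaussian blur
    of ``boundary_blur_sigma`` and corrupted with multiplicative texture
    and additive Gaussian noise.  Fully reproducible from ``params.seed``.
    """
    params = params or SyntheticParams()
    h, w = params.image_size
    samples = []
    for i in range(n):
        rng = np.random.default_rng([params.seed, i])
        n_blobs = int(rng.integers(params.n_blobs[0], params.n_blobs[1] + 1))
        mask = np.zeros((h, w), dtype=bool)
        for _ in range(n_blobs):
            placed = False
            for _attempt in range(50):
                r = rng.uniform(*params.radius)
                margin = r * (1 + params.deform) + 1
                if 2 * margin >= min(h, w):
                    continue
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                blob = _blob_mask(
                    h, w, cy, cx, r,
                    aspect=rng.uniform(0.7, 1.3),
                    theta=rng.uniform(0, np.pi),
                    deform_amp=rng.uniform(0, params.deform),
                    deform_phase=rng.uniform(0, 2 * np.pi),
                )
                if blob.any():
                    mask |= blob
                    placed = True
                    break
            if not placed:
                raise RuntimeError("could not place a blob within the canvas")

        background = 0.35 + 0.12 * _smooth_noise(rng, h, w, sigma=6.0)  # cluttered base
        blob_layer = ndimage.gaussian_filter(
            mask.astype(float), params.boundary_blur_sigma
        )
        intensity = background + params.contrast * blob_layer
        texture = 1.0 + params.texture_strength * _smooth_noise(rng, h, w, sigma=1.5)
        intensity = intensity * texture
        image = np.stack([intensity] * 3)
        image = image + rng.normal(0, params.noise_sigma, size=image.shape)
        samples.append(
            SegmentationSample(np.clip(image, 0, 1), mask.astype(np.uint8), f"synth_{i:04d}")
        )
    return samples
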