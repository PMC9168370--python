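"""CT image standardization: raw volume + mask -> model-ready tumor crops.

The chain (fixed order) is: intensity resegmentation of the mask to the
(-1000, 400) HU window -> adaptive windowing from in-mask statistics ->
Gaussian denoising -> 0-255 rescale with 256-bin histogram equalization ->
selection of the consecutive axial slices with maximal tumor area ->
bounding-box-centred square crop.  Intensity operations run on the whole
volume before slice selection so all selected slices share one transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._utils import logger


@dataclass(frozen=True)
class PreprocessConfig:
    hu_range: tuple[float, float] = (-1000.0, 400.0)
    out_range: tuple[float, float] = (0.0, 255.0)
    denoise_sigma: float = 0.5      # voxels
    n_slices: int = 3
    crop_size: int = 224

    def validate(self) -> None:
        if self.hu_range[0] >= self.hu_range[1]:
            raise ValueError("hu_range low must be < high")
        if self.n_slices < 1 or self.n_slices % 2 == 0:
            raise ValueError("n_slices must be odd and >= 1")
        if self.crop_size <= 0:
            raise ValueError("crop_size must be positive")


@dataclass
class RoiStack:
    """A subject's processed tumor region: ``n_slices`` square intensity
    tiles with matching binary masks, plus provenance (source z positions,
    the applied intensity window, and the voxel spacing in mm)."""

    slices: np.ndarray          # (n_slices, crop, crop) float, in [0, 255]
    masks: np.ndarray           # same shape, bool
    slice_indices: np.ndarray   # source z positions (may repeat at borders)
    window: tuple[float, float]  # (center, width)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x) mm


def resegment(volume: np.ndarray, mask: np.ndarray,
              hu_range: tuple[float, float] = (-1000.0, 400.0)) -> np.ndarray:
    """Keep only mask voxels whose HU lies inside ``hu_range``."""
    if volume.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    out = mask.astype(bool) & (volume >= hu_range[0]) & (volume <= hu_range[1])
    if not out.any():
        raise ValueError("ROI eliminated by resegmentation")
    return out


def adaptive_window(volume: np.ndarray, mask: np.ndarray) -> tuple[
        np.ndarray, tuple[float, float]]:
    """Window the volume using in-mask statistics.

    Center = mean HU inside the mask; width = max(2 * (p99 - p1), 1).
    Returns the clipped volume and the applied (center, width).
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = volume[mask]
    center = float(vals.mean())
    p1, p99 = np.percentile(vals, [1, 99])
    width = max(2.0 * float(p99 - p1), 1.0)
    lo, hi = center - width / 2.0, center + width / 2.0
    return np.clip(volume, lo, hi), (center, width)


def denoise(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian filter with reflecting boundary; sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")


def normalize_and_equalize(image: np.ndarray) -> np.ndarray:
    """Linear min->0 / max->255 rescale followed by 256-bin histogram
    equalization.  A constant image maps to all zeros."""
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image, dtype=float)
    scaled = (image - lo) / (hi - lo) * 255.0
    levels = np.clip(np.round(scaled).astype(int), 0, 255)
    hist = np.bincount(levels.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    denom = cdf[-1] - cdf_min
    if denom == 0:
        return np.zeros_like(image, dtype=float)
    lut = np.round((cdf - cdf_min) / denom * 255.0)
    return lut[levels].astype(float)


def select_informative_slices(volume: np.ndarray, mask: np.ndarray,
                              n_slices: int = 3) -> np.ndarray:
    """Indices of the consecutive axial window of length ``n_slices``
    maximizing total in-mask area; ties break toward the smaller index.

    If the mask spans fewer slices than ``n_slices``, the window is centred
    on the mask and border indices are duplicated (logged).
    """
    mask = mask.astype(bool)
    areas = mask.sum(axis=(1, 2))
    nz = np.nonzero(areas)[0]
    if nz.size == 0:
        raise ValueError("empty mask")
    n_z = volume.shape[0]
    if nz.size < n_slices or n_z < n_slices:
        center = int(nz[len(nz) // 2])
        half = n_slices // 2
        idx = np.arange(center - half, center + half + 1)
        idx = np.clip(idx, 0, n_z - 1)
        logger.warning("mask spans %d slice(s) < %d; padded by duplicating "
                       "boundary slices", nz.size, n_slices)
        return idx
    sums = np.convolve(areas, np.ones(n_slices, dtype=int), mode="valid")
    start = int(np.argmax(sums))  # argmax takes the first maximum
    return np.arange(start, start + n_slices)


def crop_to_bbox(slice_2d: np.ndarray, mask_2d: np.ndarray, crop_size: int,
                 center: tuple[int, int] | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Square crop centred on the mask bounding-box centre (or an explicit
    ``center``), zero-padded at image borders.  Tumors wider than
    ``crop_size`` get a centre crop (logged)."""
    mask_2d = mask_2d.astype(bool)
    if center is None:
        rows, cols = np.nonzero(mask_2d)
        if rows.size == 0:
            center = (slice_2d.shape[0] // 2, slice_2d.shape[1] // 2)
        else:
            center = ((int(rows.min()) + int(rows.max())) // 2,
                      (int(cols.min()) + int(cols.max())) // 2)
            if (rows.max() - rows.min() >= crop_size
                    or cols.max() - cols.min() >= crop_size):
                logger.warning("tumor exceeds crop size %d; centre-cropping",
                               crop_size)
    half = crop_size // 2
    tile = np.zeros((crop_size, crop_size), dtype=float)
    mtile = np.zeros((crop_size, crop_size), dtype=bool)
    r0, c0 = center[0] - half, center[1] - half
    src_r = slice(max(r0, 0), min(r0 + crop_size, slice_2d.shape[0]))
    src_c = slice(max(c0, 0), min(c0 + crop_size, slice_2d.shape[1]))
    dst_r = slice(src_r.start - r0, src_r.stop - r0)
    dst_c = slice(src_c.start - c0, src_c.stop - c0)
    tile[dst_r, dst_c] = slice_2d[src_r, src_c]
    mtile[dst_r, dst_c] = mask_2d[src_r, src_c]
    return tile, mtile


def preprocess_subject(volume: np.ndarray, mask: np.ndarray,
                       config: PreprocessConfig | None = None,
                       spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       ) -> RoiStack:
    """Run the full standardization chain on one subject."""
    cfg = config or PreprocessConfig()
    cfg.validate()
    mask = resegment(volume, mask, cfg.hu_range)
    vol, window = adaptive_window(volume, mask)
    vol = denoise(vol, cfg.denoise_sigma)
    vol = normalize_and_equalize(vol)
    idx = select_informative_slices(vol, mask, cfg.n_slices)

    # one crop origin shared by all selected slices, from the union mask
    union = mask[idx].any(axis=0)
    rows, cols = np.nonzero(union)
    center = ((int(rows.min()) + int(rows.max())) // 2,
              (int(cols.min()) + int(cols.max())) // 2)
    tiles, mtiles = [], []
    for z in idx:
        t, m = crop_to_bbox(vol[z], mask[z], cfg.crop_size, center=center)
        tiles.append(t)
        mtiles.append(m)
    return RoiStack(slices=np.stack(tiles), masks=np.stack(mtiles),
                    slice_indices=np.asarray(idx), window=window,
                    spacing=spacing)
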