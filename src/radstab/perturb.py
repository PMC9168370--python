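"""Controlled image/mask perturbations for feature-robustness analysis.

Three perturbation kinds are applied per subject:

* ``S`` (slice thickness): z-axis slab averaging to 1, 2, 3 and 5 mm —
  applied to the raw volume/mask before preprocessing.
* ``R`` (in-plane rotation): rotation of the processed tumor tiles by
  -30, -15, +15 and +30 degrees — applied after slice selection, in 2-D.
* ``Seg`` (segmentation): morphological expansion/shrinkage of the mask to
  an area ratio of 1.2 / 0.8 — applied to the raw mask before preprocessing.

All perturbations are deterministic, so every subject contributes a
balanced rater panel (original + one replicate per level) to the ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._utils import logger
from .preprocess import PreprocessConfig, RoiStack, preprocess_subject

THICKNESS_LEVELS_MM = (1.0, 2.0, 3.0, 5.0)
ROTATION_LEVELS_DEG = (-30.0, -15.0, 15.0, 30.0)
SEGMENTATION_LEVELS = (0.8, 1.2)


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str                       # "S" | "R" | "Seg"
    levels: tuple[float, ...]

    def validate(self) -> None:
        if self.kind not in {"S", "R", "Seg"}:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not self.levels:
            raise ValueError("levels must be nonempty")
        if self.kind == "Seg" and min(self.levels) <= 0:
            raise ValueError("Seg factors must be positive")


DEFAULT_SPECS = (
    PerturbationSpec("S", THICKNESS_LEVELS_MM),
    PerturbationSpec("R", ROTATION_LEVELS_DEG),
    PerturbationSpec("Seg", SEGMENTATION_LEVELS),
)


def perturb_thickness(volume: np.ndarray, mask: np.ndarray, t_mm: float,
                      base_mm: float = 1.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct at slab thickness ``t_mm`` by z-axis slab averaging
    (mean for the volume, majority vote for the mask)."""
    step = t_mm / base_mm
    if abs(step - round(step)) > 1e-9 or step < 1:
        raise ValueError("t_mm must be a positive multiple of base spacing")
    step = int(round(step))
    if step == 1:
        return volume.copy(), mask.astype(bool).copy()
    n_out = volume.shape[0] // step
    if n_out < 1:
        raise ValueError("slab averaging leaves no slices")
    trimmed_v = volume[: n_out * step].reshape(n_out, step, *volume.shape[1:])
    trimmed_m = mask[: n_out * step].astype(float).reshape(
        n_out, step, *mask.shape[1:])
    return trimmed_v.mean(axis=1), trimmed_m.mean(axis=1) >= 0.5


def perturb_rotation(slice_2d: np.ndarray, mask_2d: np.ndarray,
                     theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a tile and its mask about the tile centre (bilinear for the
    image, nearest-neighbour for the mask; canvas size preserved)."""
    if theta_deg == 0:
        return slice_2d.copy(), mask_2d.astype(bool).copy()
    img = ndimage.rotate(slice_2d, theta_deg, reshape=False, order=1,
                         mode="constant", cval=0.0)
    msk = ndimage.rotate(mask_2d.astype(np.uint8), theta_deg, reshape=False,
                         order=0, mode="constant", cval=0)
    msk = msk.astype(bool)
    if not msk.any():
        raise ValueError("rotated mask is empty")
    return img, msk


def rotate_stack(stack: RoiStack, theta_deg: float) -> RoiStack:
    """Apply the rotation perturbation to every slice of a processed stack."""
    tiles, masks = [], []
    for img, msk in zip(stack.slices, stack.masks):
        t, m = perturb_rotation(img, msk, theta_deg)
        tiles.append(t)
        masks.append(m)
    return RoiStack(slices=np.stack(tiles), masks=np.stack(masks),
                    slice_indices=stack.slice_indices.copy(),
                    window=stack.window, spacing=stack.spacing)


def perturb_segmentation(mask: np.ndarray, factor: float
                         ) -> tuple[np.ndarray, float]:
    """Expand (factor > 1) or shrink (factor < 1) the mask by iterative
    unit-ball dilation/erosion, stopping at the iterate whose volume ratio
    to the original is closest to ``factor``.

    Returns (mask', achieved ratio).  If erosion would empty the mask the
    last nonempty iterate is returned with a warning.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    mask = mask.astype(bool)
    n0 = int(mask.sum())
    if n0 == 0:
        raise ValueError("empty mask")
    if factor == 1.0:
        return mask.copy(), 1.0
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    op = ndimage.binary_dilation if factor > 1 else ndimage.binary_erosion
    best, best_ratio = mask.copy(), 1.0
    current = mask.copy()
    for _ in range(200):
        nxt = op(current, structure=structure)
        n = int(nxt.sum())
        if n == 0:
            logger.warning("erosion emptied mask before reaching factor "
                           "%.2f; returning ratio %.3f", factor, best_ratio)
            return best, best_ratio
        ratio = n / n0
        if abs(ratio - factor) < abs(best_ratio - factor):
            best, best_ratio = nxt, ratio
        # once we have passed the target, further steps only move away
        if (factor > 1 and ratio >= factor) or (factor < 1 and ratio <= factor):
            break
        current = nxt
    if best_ratio == 1.0 and factor != 1.0:
        logger.warning("segmentation perturbation could not move mask "
                       "toward factor %.2f (degenerate mask)", factor)
    return best, best_ratio


@dataclass
class Replicate:
    kind: str           # "original" | "S" | "R" | "Seg"
    level: float        # 0 for original
    stack: RoiStack
    achieved_ratio: float | None = None


def make_replicates(volume: np.ndarray, mask: np.ndarray,
                    pre_config: PreprocessConfig | None = None,
                    specs: tuple[PerturbationSpec, ...] = DEFAULT_SPECS,
                    base_mm: float = 1.0) -> list[Replicate]:
    """Produce the original plus every perturbed replicate as processed
    ``RoiStack`` objects, all run through the identical preprocess chain.

    Thickness and segmentation perturb the raw volume/mask before
    preprocessing; rotation applies to the processed 2-D tiles.
    """
    cfg = pre_config or PreprocessConfig()
    original = preprocess_subject(volume, mask, cfg,
                                  spacing=(base_mm, 1.0, 1.0))
    out = [Replicate("original", 0.0, original)]
    for spec in specs:
        spec.validate()
        for level in spec.levels:
            if spec.kind == "S":
                v, m = perturb_thickness(volume, mask, level, base_mm)
                stack = preprocess_subject(v, m, cfg,
                                           spacing=(level, 1.0, 1.0))
                out.append(Replicate("S", level, stack))
            elif spec.kind == "R":
                out.append(Replicate("R", level, rotate_stack(original,
                                                              level)))
            else:  # Seg
                m, ratio = perturb_segmentation(mask, level)
                stack = preprocess_subject(volume, m, cfg,
                                           spacing=(base_mm, 1.0, 1.0))
                out.append(Replicate("Seg", level, stack,
                                     achieved_ratio=ratio))
    return out
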