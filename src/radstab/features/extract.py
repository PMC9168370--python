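"""Assemble the full 851-feature handcrafted vector per subject."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._utils import logger
from ..preprocess import RoiStack
from .catalogue import CATALOGUE, NON_SHAPE_FAMILIES, SHAPE, WAVELET_BANDS
from .firstorder import first_order_features
from .shape import shape_features
from .texture import texture_features_stack
from .wavelet import wavelet_subbands


def _image_features(slices: np.ndarray, masks: np.ndarray,
                    voxel_volume: float, n_bins: int) -> dict[str, float]:
    """The 93 non-shape features of one (possibly filtered) stack."""
    out: dict[str, float] = {}
    fo = first_order_features(slices[masks], voxel_volume, n_bins)
    out.update({f"firstorder_{k}": v for k, v in fo.items()})
    tex = texture_features_stack(slices, masks, n_bins)
    for fam, feats in tex.items():
        out.update({f"{fam}_{k}": v for k, v in feats.items()})
    return out


def extract_all(stack: RoiStack, n_bins: int = 32,
                wavelet: str = "coif1") -> pd.Series:
    """851 named features of one processed stack, in catalogue order.

    Raises if any value comes out non-finite, naming the feature.
    """
    masks = stack.masks.astype(bool)
    if not masks.any():
        raise ValueError("empty mask stack")
    voxel_volume = float(np.prod(stack.spacing))

    values: dict[str, float] = {}
    img = _image_features(stack.slices, masks, voxel_volume, n_bins)
    values.update({f"original_{k}": v for k, v in img.items()})
    shp = shape_features(masks, stack.spacing)
    values.update({f"original_shape_{k}": v for k, v in shp.items()})

    for band, sub in wavelet_subbands(stack.slices, wavelet).items():
        img = _image_features(sub, masks, voxel_volume, n_bins)
        values.update({f"wavelet-{band}_{k}": v for k, v in img.items()})

    row = pd.Series(values).reindex(CATALOGUE)
    bad = row.index[~np.isfinite(row.to_numpy())]
    if len(bad):
        raise ValueError(f"non-finite feature value(s): {list(bad[:5])}")
    return row


def extract_table(stacks: dict[str, RoiStack], n_bins: int = 32,
                  wavelet: str = "coif1", provenance: str = "original"
                  ) -> pd.DataFrame:
    """Extract the catalogue for a set of subjects into a subjects x 851
    table (index = subject id); ``provenance`` is stored in ``df.attrs``."""
    rows = {sid: extract_all(stk, n_bins, wavelet)
            for sid, stk in stacks.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")[list(CATALOGUE)]
    df.attrs["extractor"] = "radiomics"
    df.attrs["perturbation"] = provenance
    logger.debug("extracted %d x %d feature table (%s)", *df.shape,
                 provenance)
    return df
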