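"""Single-level 3-D wavelet filtration of a slice stack.

Implemented as an undecimated (stationary) separable transform: the
decomposition low/high-pass filter pair is applied along each of the three
axes in every L/H combination, yielding 8 sub-bands (LLL ... HHH, letters
in z-y-x axis order) that keep the original raster geometry, so the
original mask remains valid on every band.  Default basis is Coiflet-1;
stacks thinner than the filter along any axis fall back to Haar (logged).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .._utils import logger
from .catalogue import WAVELET_BANDS


def wavelet_subbands(stack: np.ndarray, wavelet: str = "coif1"
                     ) -> dict[str, np.ndarray]:
    """Return {band name: filtered stack} for the 8 L/H axis combinations."""
    stack = np.asarray(stack, dtype=float)
    wav = pywt.Wavelet(wavelet)
    if min(stack.shape) < len(wav.dec_lo):
        if wavelet != "haar":
            logger.info("stack shape %s too thin for %s; using Haar",
                        stack.shape, wavelet)
        wav = pywt.Wavelet("haar")
    lo = np.asarray(wav.dec_lo)
    hi = np.asarray(wav.dec_hi)

    out: dict[str, np.ndarray] = {}
    for band in WAVELET_BANDS:
        img = stack
        for axis, letter in enumerate(band):
            taps = lo if letter == "L" else hi
            img = ndimage.correlate1d(img, taps, axis=axis, mode="reflect")
        out[band] = img
    return out
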