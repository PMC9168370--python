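"""Second-order texture features from gray-level matrices.

All five matrix families (GLCM, GLRLM, GLSZM, GLDM, NGTDM) are computed in
2-D per slice on gray levels discretized to equal-width bins over the
pooled in-mask intensity range of the stack.  GLCM and GLRLM use the four
in-plane directions at distance 1 (symmetric GLCM); features are computed
per direction, averaged over directions, then averaged over slices.
GLSZM/GLDM/NGTDM use 8-connectivity and are averaged over slices.

Degenerate conventions (single gray level in the ROI): entropy-type
features are 0 and correlation-type features 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .._utils import logger

_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))
_STRUCT8 = np.ones((3, 3), dtype=bool)
_EPS = np.finfo(float).eps


def discretize(values: np.ndarray, mask: np.ndarray, n_bins: int = 32,
               rng: tuple[float, float] | None = None) -> np.ndarray:
    """Equal-width discretization of in-mask intensities to levels 1..n_bins
    (0 outside the mask).  ``rng`` overrides the in-mask min-max range so a
    whole stack can share one set of bin edges."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = mask.astype(bool)
    out = np.zeros(values.shape, dtype=np.int64)
    if not mask.any():
        return out
    vals = values[mask]
    lo, hi = rng if rng is not None else (float(vals.min()), float(vals.max()))
    if hi <= lo:
        out[mask] = 1
        return out
    edges = np.linspace(lo, hi, n_bins + 1)
    lev = np.digitize(values[mask], edges[1:-1], right=False) + 1
    out[mask] = np.clip(lev, 1, n_bins)
    return out


def _xlog2x(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return p * np.log2(p, out=np.zeros_like(p), where=p > 0)


# --------------------------------------------------------------------- GLCM

def glcm_matrix(disc: np.ndarray, offset: tuple[int, int],
                n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset (both pixels in-mask)."""
    dz, dx = offset
    h, w = disc.shape
    r0 = slice(max(0, -dz), min(h, h - dz))
    c0 = slice(max(0, -dx), min(w, w - dx))
    r1 = slice(max(0, dz), min(h, h + dz))
    c1 = slice(max(0, dx), min(w, w + dx))
    a, b = disc[r0, c0].ravel(), disc[r1, c1].ravel()
    ok = (a > 0) & (b > 0)
    a, b = a[ok] - 1, b[ok] - 1
    m = np.zeros((n_levels, n_levels))
    np.add.at(m, (a, b), 1.0)
    return m + m.T


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """Features of one normalized symmetric GLCM ``p`` (levels 1..Ng)."""
    ng = p.shape[0]
    total = p.sum()
    if total <= 0:
        raise ValueError("empty co-occurrence matrix")
    p = p / total
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((px * i).sum())              # == mu_x == mu_y by symmetry
    sigma2 = float((px * (i - mu) ** 2).sum())
    sigma = np.sqrt(sigma2)

    k_diff = np.arange(ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())

    da = float((k_diff * p_diff).sum())
    corr = 1.0 if sigma2 <= 0 else float(
        ((ii * jj * p).sum() - mu * mu) / sigma2)

    hx = float(-_xlog2x(px).sum())
    hxy = float(-_xlog2x(p).sum())
    pxpy = np.outer(px, px)
    log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-_xlog2x(pxpy).sum())
    imc1 = 0.0 if hx == 0 else (hxy - hxy1) / hx
    imc2 = 0.0 if hxy2 < hxy else float(np.sqrt(1 - np.exp(-2 * (hxy2 - hxy))))

    # MCC: second-largest eigenvalue of Q over levels actually present
    present = px > 0
    if present.sum() < 2:
        mcc = 1.0
    else:
        pp = p[np.ix_(present, present)]
        pxp = px[present]
        q = (pp / pxp[:, None]) @ (pp / pxp[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(ev[-2], 0.0))) if ev.size >= 2 else 1.0

    off = ii != jj
    inv_var = float((p[off] / (ii - jj)[off].astype(float) ** 2).sum())

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((((ii + jj) - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float((((ii + jj) - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float((((ii + jj) - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-_xlog2x(p_diff).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-_xlog2x(p_sum).sum()),
        "SumSquares": float((px * (i - mu) ** 2).sum()),
    }


# -------------------------------------------------------------------- GLRLM

def _lines(disc: np.ndarray, direction: tuple[int, int]) -> np.ndarray:
    """Concatenate all scan lines of one direction, 0-separated."""
    h, w = disc.shape
    if direction == (0, 1):
        chunks = list(disc)
    elif direction == (1, 0):
        chunks = list(disc.T)
    elif direction == (1, 1):
        chunks = [np.diagonal(disc, o) for o in range(-(h - 1), w)]
    elif direction == (1, -1):
        f = disc[:, ::-1]
        chunks = [np.diagonal(f, o) for o in range(-(h - 1), w)]
    else:
        raise ValueError(f"unsupported direction {direction}")
    sep = np.zeros(1, dtype=disc.dtype)
    parts: list[np.ndarray] = []
    for c in chunks:
        parts.append(np.asarray(c))
        parts.append(sep)
    return np.concatenate(parts)


def glrlm_matrix(disc: np.ndarray, direction: tuple[int, int],
                 n_levels: int) -> np.ndarray:
    """Run-length counts P[level-1, length-1]; runs break at mask gaps."""
    line = _lines(disc, direction)
    change = np.nonzero(np.diff(line))[0]
    starts = np.concatenate([[0], change + 1])
    lengths = np.diff(np.concatenate([starts, [len(line)]]))
    values = line[starts]
    keep = values > 0
    values, lengths = values[keep], lengths[keep]
    max_len = max(disc.shape)
    m = np.zeros((n_levels, max_len))
    np.add.at(m, (values - 1, lengths - 1), 1.0)
    return m


def _size_matrix_features(m: np.ndarray, n_pixels: int, kind: str
                          ) -> dict[str, float]:
    """Shared formulas for GLRLM/GLSZM (i = gray level, j = length/size)."""
    nr = m.sum()
    if nr <= 0:
        raise ValueError("empty matrix")
    i = np.arange(1, m.shape[0] + 1, dtype=float)
    j = np.arange(1, m.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = m / nr
    gi = m.sum(axis=1)      # per gray level
    gj = m.sum(axis=0)      # per length/size
    mu_i = float((p.sum(axis=1) * i).sum())
    mu_j = float((p.sum(axis=0) * j).sum())
    names = {
        "glrlm": ("ShortRunEmphasis", "LongRunEmphasis",
                  "RunLengthNonUniformity", "RunLengthNonUniformityNormalized",
                  "RunPercentage", "RunVariance", "RunEntropy",
                  "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
                  "ShortRunLowGrayLevelEmphasis",
                  "ShortRunHighGrayLevelEmphasis",
                  "LongRunLowGrayLevelEmphasis",
                  "LongRunHighGrayLevelEmphasis"),
        "glszm": ("SmallAreaEmphasis", "LargeAreaEmphasis",
                  "SizeZoneNonUniformity", "SizeZoneNonUniformityNormalized",
                  "ZonePercentage", "ZoneVariance", "ZoneEntropy",
                  "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
                  "SmallAreaLowGrayLevelEmphasis",
                  "SmallAreaHighGrayLevelEmphasis",
                  "LargeAreaLowGrayLevelEmphasis",
                  "LargeAreaHighGrayLevelEmphasis"),
    }[kind]
    (small, large, len_nu, len_nun, pct, var_j, entr, lgl, hgl,
     s_lgl, s_hgl, l_lgl, l_hgl) = names
    return {
        small: float((m / jj ** 2).sum() / nr),
        large: float((m * jj ** 2).sum() / nr),
        "GrayLevelNonUniformity": float((gi ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((gi ** 2).sum() / nr ** 2),
        len_nu: float((gj ** 2).sum() / nr),
        len_nun: float((gj ** 2).sum() / nr ** 2),
        pct: float(nr / n_pixels),
        "GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        var_j: float((p * (jj - mu_j) ** 2).sum()),
        entr: float(-_xlog2x(p).sum()),
        lgl: float((m / ii ** 2).sum() / nr),
        hgl: float((m * ii ** 2).sum() / nr),
        s_lgl: float((m / (ii ** 2 * jj ** 2)).sum() / nr),
        s_hgl: float((m * ii ** 2 / jj ** 2).sum() / nr),
        l_lgl: float((m * jj ** 2 / ii ** 2).sum() / nr),
        l_hgl: float((m * ii ** 2 * jj ** 2).sum() / nr),
    }


def glrlm_features(m: np.ndarray, n_pixels: int) -> dict[str, float]:
    return _size_matrix_features(m, n_pixels, "glrlm")


# -------------------------------------------------------------------- GLSZM

def glszm_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts P[level-1, size-1] with 8-connected zones."""
    n_pixels = int((disc > 0).sum())
    m = np.zeros((n_levels, max(n_pixels, 1)))
    for level in np.unique(disc[disc > 0]):
        lab, n_zones = ndimage.label(disc == level, structure=_STRUCT8)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(m, (np.full(n_zones, level - 1), sizes - 1), 1.0)
    last = np.nonzero(m.sum(axis=0))[0]
    return m[:, : last[-1] + 1] if last.size else m[:, :1]


def glszm_features(m: np.ndarray, n_pixels: int) -> dict[str, float]:
    return _size_matrix_features(m, n_pixels, "glszm")


# --------------------------------------------------------------------- GLDM

def gldm_matrix(disc: np.ndarray, n_levels: int, alpha: float = 0.0
                ) -> np.ndarray:
    """Dependence counts P[level-1, d-1]; the dependence of a pixel is 1 +
    the number of in-mask 8-neighbours whose level differs by <= alpha."""
    mask = disc > 0
    dep = np.ones(disc.shape, dtype=np.int64)
    h, w = disc.shape
    for dz, dx in ((0, 1), (1, 1), (1, 0), (1, -1),
                   (0, -1), (-1, -1), (-1, 0), (-1, 1)):
        r0 = slice(max(0, -dz), min(h, h - dz))
        c0 = slice(max(0, -dx), min(w, w - dx))
        r1 = slice(max(0, dz), min(h, h + dz))
        c1 = slice(max(0, dx), min(w, w + dx))
        ok = (mask[r0, c0] & mask[r1, c1]
              & (np.abs(disc[r0, c0] - disc[r1, c1]) <= alpha))
        dep[r0, c0] += ok
    m = np.zeros((n_levels, 9))
    np.add.at(m, (disc[mask] - 1, dep[mask] - 1), 1.0)
    return m


def gldm_features(m: np.ndarray) -> dict[str, float]:
    nz = m.sum()
    if nz <= 0:
        raise ValueError("empty dependence matrix")
    i = np.arange(1, m.shape[0] + 1, dtype=float)
    j = np.arange(1, m.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = m / nz
    gi, gj = m.sum(axis=1), m.sum(axis=0)
    mu_i = float((p.sum(axis=1) * i).sum())
    mu_j = float((p.sum(axis=0) * j).sum())
    return {
        "SmallDependenceEmphasis": float((m / jj ** 2).sum() / nz),
        "LargeDependenceEmphasis": float((m * jj ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((gi ** 2).sum() / nz),
        "DependenceNonUniformity": float((gj ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((gj ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (jj - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-_xlog2x(p).sum()),
        "LowGrayLevelEmphasis": float((m / ii ** 2).sum() / nz),
        "HighGrayLevelEmphasis": float((m * ii ** 2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis":
            float((m / (ii ** 2 * jj ** 2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis":
            float((m * ii ** 2 / jj ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis":
            float((m * jj ** 2 / ii ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis":
            float((m * ii ** 2 * jj ** 2).sum() / nz),
    }


# -------------------------------------------------------------------- NGTDM

def ngtdm_table(disc: np.ndarray, n_levels: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): pixel counts and summed |level - neighbourhood
    mean| over in-mask pixels that have at least one in-mask 8-neighbour."""
    mask = disc > 0
    vals = disc.astype(float)
    h, w = disc.shape
    nb_sum = np.zeros(disc.shape)
    nb_cnt = np.zeros(disc.shape)
    for dz, dx in ((0, 1), (1, 1), (1, 0), (1, -1),
                   (0, -1), (-1, -1), (-1, 0), (-1, 1)):
        r0 = slice(max(0, -dz), min(h, h - dz))
        c0 = slice(max(0, -dx), min(w, w - dx))
        r1 = slice(max(0, dz), min(h, h + dz))
        c1 = slice(max(0, dx), min(w, w + dx))
        ok = mask[r1, c1]
        nb_sum[r0, c0] += np.where(ok, vals[r1, c1], 0.0)
        nb_cnt[r0, c0] += ok
    valid = mask & (nb_cnt > 0)
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    lev = disc[valid] - 1
    diff = np.abs(vals[valid] - nb_sum[valid] / nb_cnt[valid])
    np.add.at(n, lev, 1.0)
    np.add.at(s, lev, diff)
    return n, s


def ngtdm_features(n: np.ndarray, s: np.ndarray) -> dict[str, float]:
    nvp = n.sum()
    if nvp <= 0:
        raise ValueError("no valid NGTDM pixels")
    p = n / nvp
    i = np.arange(1, len(n) + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p[present], s[present]

    coarse_den = float((pp * sp).sum())
    coarseness = 1e6 if coarse_den == 0 else 1.0 / coarse_den

    if ngp <= 1:
        contrast = 0.0
    else:
        di2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = (float((pp[:, None] * pp[None, :] * di2).sum())
                    / (ngp * (ngp - 1)) * float(s.sum()) / nvp)

    ipi = ip * pp
    busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = 0.0 if busy_den == 0 else float((pp * sp).sum()) / busy_den

    absdiff = np.abs(ip[:, None] - ip[None, :])
    psum = pp[:, None] + pp[None, :]
    complexity = float((absdiff * (pp[:, None] * sp[None, :]
                                   + pp[None, :] * sp[:, None]) / psum).sum()
                       ) / nvp

    s_sum = float(sp.sum())
    strength = 0.0 if s_sum == 0 else float(
        (psum * (ip[:, None] - ip[None, :]) ** 2).sum()) / s_sum

    return {"Coarseness": float(coarseness), "Contrast": float(contrast),
            "Busyness": float(busyness), "Complexity": complexity,
            "Strength": strength}


# ----------------------------------------------------------- stack wrapper

def texture_features_stack(slices: np.ndarray, masks: np.ndarray,
                           n_bins: int = 32) -> dict[str, dict[str, float]]:
    """All five texture families of a slice stack, averaged per the
    direction-first-then-slice scheme.  Returns {family: {feature: value}}.
    """
    masks = masks.astype(bool)
    pooled = slices[masks]
    if pooled.size == 0:
        raise ValueError("empty mask stack")
    rng = (float(pooled.min()), float(pooled.max()))
    if rng[0] == rng[1]:
        logger.debug("single gray level in ROI; degenerate texture "
                     "conventions apply")

    per_slice: dict[str, list[dict[str, float]]] = {
        f: [] for f in ("glcm", "glrlm", "glszm", "gldm", "ngtdm")}
    for img, msk in zip(slices, masks):
        if not msk.any():
            continue
        disc = discretize(img, msk, n_bins, rng=rng)
        n_levels = int(disc.max())
        n_pixels = int(msk.sum())

        dir_feats: list[dict[str, float]] = []
        for d in _DIRECTIONS:
            m = glcm_matrix(disc, d, n_levels)
            if m.sum() > 0:
                dir_feats.append(glcm_features(m))
        if dir_feats:
            per_slice["glcm"].append(_avg(dir_feats))

        dir_feats = [glrlm_features(glrlm_matrix(disc, d, n_levels), n_pixels)
                     for d in _DIRECTIONS]
        per_slice["glrlm"].append(_avg(dir_feats))

        per_slice["glszm"].append(
            glszm_features(glszm_matrix(disc, n_levels), n_pixels))
        per_slice["gldm"].append(gldm_features(gldm_matrix(disc, n_levels)))
        n, s = ngtdm_table(disc, n_levels)
        if n.sum() > 0:
            per_slice["ngtdm"].append(ngtdm_features(n, s))

    out = {}
    for fam, feats in per_slice.items():
        if not feats:
            raise ValueError(f"no valid slices for {fam}")
        out[fam] = _avg(feats)
    return out


def _avg(dicts: list[dict[str, float]]) -> dict[str, float]:
    keys = dicts[0].keys()
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}
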