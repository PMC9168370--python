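"""Texture matrices vs brute-force enumeration oracles.

The oracles below count co-occurrences, runs, zones, dependences and
neighbourhood differences with plain Python loops (written before the
vectorized implementations were tested against them) on tiny toy images,
so any indexing or normalization slip in the fast path shows up exactly.
"""

import numpy as np
import pytest

from radstab.features.texture import (discretize, glcm_features, glcm_matrix,
                                      gldm_features, gldm_matrix,
                                      glrlm_matrix, glszm_matrix,
                                      ngtdm_table, texture_features_stack)

DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


# ------------------------------------------------------------- oracles

def oracle_glcm(disc, offset, n_levels):
    m = np.zeros((n_levels, n_levels))
    h, w = disc.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + offset[0], c + offset[1]
            if 0 <= r2 < h and 0 <= c2 < w and disc[r, c] > 0 \
                    and disc[r2, c2] > 0:
                m[disc[r, c] - 1, disc[r2, c2] - 1] += 1
                m[disc[r2, c2] - 1, disc[r, c] - 1] += 1
    return m


def _oracle_lines(disc, direction):
    h, w = disc.shape
    lines = []
    if direction == (0, 1):
        lines = [disc[r, :] for r in range(h)]
    elif direction == (1, 0):
        lines = [disc[:, c] for c in range(w)]
    else:
        dr, dc = direction
        starts = [(0, c) for c in range(w)]
        starts += [(r, 0 if dc == 1 else w - 1) for r in range(1, h)]
        for r0, c0 in starts:
            line, r, c = [], r0, c0
            while 0 <= r < h and 0 <= c < w:
                line.append(disc[r, c])
                r, c = r + dr, c + dc
            lines.append(np.array(line))
    return lines


def oracle_glrlm(disc, direction, n_levels):
    m = np.zeros((n_levels, max(disc.shape)))
    for line in _oracle_lines(disc, direction):
        run_val, run_len = 0, 0
        for v in list(line) + [0]:
            if v == run_val:
                run_len += 1
            else:
                if run_val > 0:
                    m[run_val - 1, run_len - 1] += 1
                run_val, run_len = v, 1
    return m


def oracle_glszm(disc, n_levels):
    h, w = disc.shape
    seen = np.zeros((h, w), bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if disc[r, c] > 0 and not seen[r, c]:
                level, size = disc[r, c], 0
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (0 <= r2 < h and 0 <= c2 < w
                                    and not seen[r2, c2]
                                    and disc[r2, c2] == level):
                                seen[r2, c2] = True
                                stack.append((r2, c2))
                zones.append((level, size))
    m = np.zeros((n_levels, max(s for _, s in zones)))
    for level, size in zones:
        m[level - 1, size - 1] += 1
    return m


def oracle_gldm(disc, n_levels, alpha=0):
    h, w = disc.shape
    m = np.zeros((n_levels, 9))
    for r in range(h):
        for c in range(w):
            if disc[r, c] == 0:
                continue
            dep = 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if (0 <= r2 < h and 0 <= c2 < w and disc[r2, c2] > 0
                            and abs(int(disc[r, c])
                                    - int(disc[r2, c2])) <= alpha):
                        dep += 1
            m[disc[r, c] - 1, dep - 1] += 1
    return m


def oracle_ngtdm(disc, n_levels):
    h, w = disc.shape
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    for r in range(h):
        for c in range(w):
            if disc[r, c] == 0:
                continue
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and disc[r2, c2] > 0:
                        nb.append(disc[r2, c2])
            if nb:
                n[disc[r, c] - 1] += 1
                s[disc[r, c] - 1] += abs(disc[r, c] - np.mean(nb))
    return n, s


def random_toys(n_toys=8):
    rng = np.random.default_rng(11)
    toys = []
    for i in range(n_toys):
        h, w = rng.integers(3, 7, size=2)
        disc = rng.integers(1, 5, size=(h, w))
        disc[rng.random((h, w)) < 0.25] = 0  # carve out-of-mask holes
        if (disc > 0).sum() >= 3:
            toys.append(disc)
    return toys


# ---------------------------------------------------------- matrix parity

@pytest.mark.parametrize("toy_idx", range(len(random_toys())))
def test_matrices_equal_oracles_on_toys(toy_idx):
    disc = random_toys()[toy_idx]
    n_levels = int(disc.max())
    for d in DIRECTIONS:
        assert np.array_equal(glcm_matrix(disc, d, n_levels),
                              oracle_glcm(disc, d, n_levels))
        got = glrlm_matrix(disc, d, n_levels)
        want = oracle_glrlm(disc, d, n_levels)
        assert np.array_equal(got[:, :want.shape[1]], want)
        assert got[:, want.shape[1]:].sum() == 0
    got = glszm_matrix(disc, n_levels)
    want = oracle_glszm(disc, n_levels)
    assert np.array_equal(got[:, :want.shape[1]], want)
    assert np.array_equal(gldm_matrix(disc, n_levels),
                          oracle_gldm(disc, n_levels))
    n_got, s_got = ngtdm_table(disc, n_levels)
    n_want, s_want = oracle_ngtdm(disc, n_levels)
    assert np.array_equal(n_got, n_want)
    assert np.allclose(s_got, s_want)


# ---------------------------------------------------------- hand examples

def test_checkerboard_glcm_hand_enumeration():
    # 2x2 checkerboard of levels {1,2}: horizontally every pair is (1,2) or
    # (2,1), so the symmetric normalized GLCM is 0.5 off-diagonal and the
    # contrast sum_ij (i-j)^2 p(i,j) = 1
    disc = np.array([[1, 2], [2, 1]])
    m = glcm_matrix(disc, (0, 1), 2)
    p = m / m.sum()
    assert p[0, 1] == 0.5 and p[1, 0] == 0.5 and p[0, 0] == 0
    feats = glcm_features(m)
    assert feats["Contrast"] == pytest.approx(1.0)
    assert feats["JointEntropy"] == pytest.approx(1.0)  # two 0.5 cells


def test_run_length_hand_enumeration():
    # [1,1,2,2] horizontally: two runs of length 2; run-length
    # non-uniformity = (sum over lengths of counts^2)/Nr = 2^2/2 = 2
    disc = np.array([[1, 1, 2, 2]])
    m = glrlm_matrix(disc, (0, 1), 2)
    assert m[0, 1] == 1 and m[1, 1] == 1 and m.sum() == 2
    from radstab.features.texture import glrlm_features
    feats = glrlm_features(m, n_pixels=4)
    assert feats["RunLengthNonUniformity"] == pytest.approx(2.0)
    assert feats["RunPercentage"] == pytest.approx(0.5)
    assert feats["ShortRunEmphasis"] == pytest.approx(0.25)


def test_constant_roi_degenerate_conventions():
    slices = np.full((3, 8, 8), 42.0)
    masks = np.ones_like(slices, bool)
    feats = texture_features_stack(slices, masks)
    assert feats["glcm"]["Contrast"] == 0.0
    assert feats["glcm"]["JointEntropy"] == 0.0
    assert feats["glcm"]["Correlation"] == 1.0


def test_glcm_features_from_first_principles():
    # independent naive sums over the normalized matrix
    disc = random_toys()[0]
    n_levels = int(disc.max())
    m = oracle_glcm(disc, (1, 0), n_levels)
    p = m / m.sum()
    contrast = sum((i - j) ** 2 * p[i - 1, j - 1]
                   for i in range(1, n_levels + 1)
                   for j in range(1, n_levels + 1))
    entropy = -sum(p[i, j] * np.log2(p[i, j])
                   for i in range(n_levels) for j in range(n_levels)
                   if p[i, j] > 0)
    feats = glcm_features(m)
    assert feats["Contrast"] == pytest.approx(contrast, abs=1e-12)
    assert feats["JointEntropy"] == pytest.approx(entropy, abs=1e-12)


def test_gldm_features_from_first_principles():
    disc = random_toys()[1]
    n_levels = int(disc.max())
    m = oracle_gldm(disc, n_levels)
    nz = m.sum()
    sde = sum(m[i, j] / (j + 1) ** 2 for i in range(m.shape[0])
              for j in range(m.shape[1])) / nz
    assert gldm_features(m)["SmallDependenceEmphasis"] == \
        pytest.approx(sde, abs=1e-12)


# ------------------------------------------------------------- invariants

def test_rotation_90_invariance_of_direction_averaged_glcm():
    rng = np.random.default_rng(3)
    img = rng.normal(size=(12, 12))
    masks = np.ones((1, 12, 12), bool)
    a = texture_features_stack(img[None], masks)["glcm"]
    b = texture_features_stack(np.rot90(img)[None].copy(), masks)["glcm"]
    for k in a:
        assert a[k] == pytest.approx(b[k], rel=1e-9), k


def test_intensity_shift_invariance():
    rng = np.random.default_rng(4)
    slices = rng.normal(100, 20, size=(3, 10, 10))
    masks = np.ones_like(slices, bool)
    a = texture_features_stack(slices, masks)
    b = texture_features_stack(slices + 57.0, masks)
    for fam in a:
        for k in a[fam]:
            assert a[fam][k] == pytest.approx(b[fam][k], rel=1e-9), (fam, k)


def test_discretize_bins_and_mask():
    vals = np.array([[0.0, 1.0], [2.0, 3.0]])
    mask = np.array([[True, True], [True, False]])
    disc = discretize(vals, mask, n_bins=2)
    assert disc[1, 1] == 0                      # outside the mask
    assert disc[0, 0] == 1 and disc[1, 0] == 2  # equal-width over [0, 2]
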