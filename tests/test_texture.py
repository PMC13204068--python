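"""Texture matrices and features against brute-force enumeration oracles.

Every oracle here is an independent, loop-based re-derivation from the matrix
definitions, evaluated on arrays small enough to verify by hand.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pnetrad.radiomics import ExtractionConfig, preprocess, texture_features, texture_matrices
from pnetrad.radiomics.texture import (
    ANGLES_13,
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _sample_from_bins(bins):
    """Wrap an integer gray-level array as a preprocessed sample."""
    vol = bins.astype(float) * 25.0  # one level per 25-HU bin
    mask = bins > 0
    cfg = ExtractionConfig(resegment_range=(-1e6, 1e6), bin_width=25.0)
    return preprocess(vol, mask, cfg)


def _in(shape, v):
    return all(0 <= c < s for c, s in zip(v, shape))


# ---------------------------------------------------------------------------
# oracles


def oracle_glcm(bins, offset):
    ng = bins.max()
    P = np.zeros((ng, ng))
    for idx in np.ndindex(bins.shape):
        if bins[idx] == 0:
            continue
        nb = tuple(np.add(idx, offset))
        if _in(bins.shape, nb) and bins[nb] > 0:
            P[bins[idx] - 1, bins[nb] - 1] += 1
            P[bins[nb] - 1, bins[idx] - 1] += 1
    return P


def oracle_zones(bins):
    """Flood-fill zone enumeration (26-connectivity, one zone list per level)."""
    visited = np.zeros(bins.shape, bool)
    zones = []
    for idx in np.ndindex(bins.shape):
        if bins[idx] == 0 or visited[idx]:
            continue
        level = bins[idx]
        stack, size = [idx], 0
        visited[idx] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in ALL_26:
                nb = tuple(np.add(cur, off))
                if _in(bins.shape, nb) and not visited[nb] and bins[nb] == level:
                    visited[nb] = True
                    stack.append(nb)
        zones.append((int(level), size))
    return zones


def oracle_ngtdm(bins):
    ng = int(bins.max())
    n = np.zeros(ng)
    s = np.zeros(ng)
    for idx in np.ndindex(bins.shape):
        g = bins[idx]
        if g == 0:
            continue
        vals = []
        for off in ALL_26:
            nb = tuple(np.add(idx, off))
            if _in(bins.shape, nb) and bins[nb] > 0:
                vals.append(bins[nb])
        n[g - 1] += 1
        if vals:
            s[g - 1] += abs(g - np.mean(vals))
    p = n / n.sum()
    return n, p, s


def oracle_busyness(bins):
    n, p, s = oracle_ngtdm(bins)
    num = float((p * s).sum())
    levels = np.arange(1, len(p) + 1)
    den = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            if p[i] > 0 and p[j] > 0:
                den += abs(levels[i] * p[i] - levels[j] * p[j])
    return num / den if den > 0 else 0.0


def oracle_gldm(bins):
    ng = int(bins.max())
    P = np.zeros((ng, 27))
    for idx in np.ndindex(bins.shape):
        g = bins[idx]
        if g == 0:
            continue
        k = 0
        for off in ALL_26:
            nb = tuple(np.add(idx, off))
            if _in(bins.shape, nb) and bins[nb] == g:
                k += 1
        P[g - 1, k] += 1
    return P


def _random_bins(seed, shape=(4, 4, 4), levels=3, p_roi=0.8):
    gen = np.random.default_rng(seed)
    bins = gen.integers(1, levels + 1, size=shape)
    bins[gen.random(shape) > p_roi] = 0
    if bins.max() == 0:
        bins[0, 0, 0] = 1
    return bins


# ---------------------------------------------------------------------------
# tests


class TestGLCM:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matrices_match_pair_enumeration(self, seed):
        bins = _random_bins(seed)
        mats = glcm_matrices(bins, bins.max())
        for k, off in enumerate(ANGLES_13):
            np.testing.assert_array_equal(mats[k], oracle_glcm(bins, off))

    def test_constant_roi_diagonal_and_idmn_one(self):
        s = _sample_from_bins(np.ones((3, 3, 3), dtype=int))
        feats = texture_features(texture_matrices(s))
        assert feats["glcm_Idmn"] == pytest.approx(1.0)
        assert feats["glcm_Contrast"] == pytest.approx(0.0)

    def test_idmn_matches_definition_on_small_roi(self):
        bins = _random_bins(5)
        s = _sample_from_bins(bins)
        feats = texture_features(texture_matrices(s))
        vals = []
        for off in ANGLES_13:
            P = oracle_glcm(bins, off)
            if P.sum() == 0:
                vals.append(0.0)
                continue
            p = P / P.sum()
            ng = p.shape[0]
            i, j = np.meshgrid(np.arange(1, ng + 1), np.arange(1, ng + 1), indexing="ij")
            vals.append((p / (1 + (i - j) ** 2 / ng**2)).sum())
        assert feats["glcm_Idmn"] == pytest.approx(np.mean(vals), abs=1e-12)


class TestGLSZM:
    def test_two_zone_plane(self):
        bins = np.array([[[1], [1]], [[1], [2]]])  # 2x2x1: three 1s, one 2
        Z = glszm_matrix(bins, 2)
        zones = oracle_zones(bins)
        assert sorted(zones) == [(1, 3), (2, 1)]
        assert Z[0, 2] == 1  # level 1, size 3
        assert Z[1, 0] == 1  # level 2, size 1
        assert Z.sum() == 2

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_size_zone_nonuniformity_matches_flood_fill(self, seed):
        bins = _random_bins(seed)
        s = _sample_from_bins(bins)
        feats = texture_features(texture_matrices(s))
        zones = oracle_zones(bins)
        sizes = np.array([z[1] for z in zones])
        szn = sum((sizes == k).sum() ** 2 for k in np.unique(sizes)) / len(zones)
        assert feats["glszm_SizeZoneNonUniformity"] == pytest.approx(szn, abs=1e-12)

    def test_small_area_high_gray_matches_enumeration(self):
        bins = _random_bins(9)
        Z = glszm_matrix(bins, bins.max())
        zones = oracle_zones(bins)
        expected = sum(lvl**2 / size**2 for lvl, size in zones) / len(zones)
        feats = texture_features({"glcm": glcm_matrices(bins, bins.max()),
                                  "glrlm": glrlm_matrices(bins, bins.max()),
                                  "glszm": Z, "gldm": gldm_matrix(bins, bins.max()),
                                  "ngtdm": ngtdm_table(bins, bins.max())})
        assert feats["glszm_SmallAreaHighGrayLevelEmphasis"] == pytest.approx(expected)


class TestGLDM:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_matrix_matches_neighbour_counting(self, seed):
        bins = _random_bins(seed)
        np.testing.assert_array_equal(gldm_matrix(bins, bins.max()), oracle_gldm(bins))

    def test_dependence_nonuniformity_matches_oracle(self):
        bins = _random_bins(11)
        P = oracle_gldm(bins)
        expected = (P.sum(axis=0) ** 2).sum() / P.sum()
        s = _sample_from_bins(bins)
        feats = texture_features(texture_matrices(s))
        assert feats["gldm_DependenceNonUniformity"] == pytest.approx(expected, abs=1e-12)


class TestNGTDM:
    def test_single_voxel_zero_neighbourhood_sum(self):
        bins = np.zeros((3, 3, 3), int)
        bins[1, 1, 1] = 1
        T = ngtdm_table(bins, 1)
        assert T[0, 0] == 1
        assert T[0, 2] == 0.0

    def test_constant_roi_busyness_zero_by_convention(self):
        s = _sample_from_bins(np.ones((3, 3, 3), int))
        assert texture_features(texture_matrices(s))["ngtdm_Busyness"] == 0.0

    def test_checkerboard_busyness_matches_hand_formula(self):
        x, y = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
        bins = (1 + (x + y) % 2)[:, :, None]  # 3x3x1 checkerboard of levels 1/2
        s = _sample_from_bins(bins)
        feats = texture_features(texture_matrices(s))
        assert feats["ngtdm_Busyness"] == pytest.approx(oracle_busyness(bins), abs=1e-12)

    @pytest.mark.parametrize("seed", [13, 14, 15])
    def test_busyness_matches_oracle_on_random_rois(self, seed):
        bins = _random_bins(seed)
        s = _sample_from_bins(bins)
        feats = texture_features(texture_matrices(s))
        assert feats["ngtdm_Busyness"] == pytest.approx(oracle_busyness(bins), abs=1e-12)


class TestGLRLM:
    def test_runs_on_a_line(self):
        bins = np.zeros((5, 1, 1), int)
        bins[:, 0, 0] = [1, 1, 2, 2, 2]
        mats = glrlm_matrices(bins, 2)
        x_dir = ANGLES_13.index((1, 0, 0))
        R = mats[x_dir]
        assert R[0, 1] == 1  # one run of level 1, length 2
        assert R[1, 2] == 1  # one run of level 2, length 3
        assert R.sum() == 2
        # along y every voxel is its own run
        y_dir = ANGLES_13.index((0, 1, 0))
        assert mats[y_dir].sum() == 5
        assert mats[y_dir][:, 0].sum() == 5

    def test_run_voxel_conservation(self):
        bins = _random_bins(21)
        n_vox = (bins > 0).sum()
        for R in glrlm_matrices(bins, bins.max()):
            lengths = np.arange(1, R.shape[1] + 1)
            assert (R.sum(axis=0) * lengths).sum() == n_vox


class TestInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=1, max_value=4))
    def test_rotation_invariance_of_direction_averaged_features(self, seed, axis_pair):
        bins = _random_bins(seed, shape=(4, 4, 4))
        axes = [(0, 1), (0, 2), (1, 2), (0, 1)][axis_pair - 1]
        rotated = np.rot90(bins, k=1, axes=axes)
        f1 = texture_features(texture_matrices(_sample_from_bins(bins)))
        f2 = texture_features(texture_matrices(_sample_from_bins(rotated)))
        for key in ("glcm_Idmn", "glcm_Contrast", "glszm_SizeZoneNonUniformity",
                    "ngtdm_Busyness", "gldm_DependenceNonUniformity",
                    "glrlm_RunLengthNonUniformity"):
            assert f1[key] == pytest.approx(f2[key], abs=1e-10), key

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=-50.0, max_value=50.0))
    def test_intensity_shift_leaves_texture_unchanged(self, seed, c):
        gen = np.random.default_rng(seed)
        vol = gen.uniform(0, 150, size=(4, 4, 4))
        mask = gen.random((4, 4, 4)) > 0.3
        mask[1, 1, 1] = True
        cfg = ExtractionConfig(resegment_range=(-1e9, 1e9), bin_width=25.0)
        f1 = texture_features(texture_matrices(preprocess(vol, mask, cfg)))
        f2 = texture_features(texture_matrices(preprocess(vol + c, mask, cfg)))
        for key, v in f1.items():
            assert v == pytest.approx(f2[key], abs=1e-9), key
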