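"""3D texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM) and their features.

All matrices operate on the discretized gray-level array produced by
``preprocess`` (0 outside the ROI, levels >= 1 inside), use distance-1
26-connected neighbourhoods (13 unique directions for GLCM/GLRLM), and
directional features are aggregated by averaging over directions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .preprocess import RoiSample

__all__ = ["ANGLES_13", "texture_matrices", "texture_features"]

#: the 13 unique distance-1 direction offsets in 3D (the other 13 are negations)
ANGLES_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, -1),
    (0, 1, 0),
    (0, 1, 1),
    (1, -1, -1),
    (1, -1, 0),
    (1, -1, 1),
    (1, 0, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, -1),
    (1, 1, 0),
    (1, 1, 1),
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _shifted_views(a: np.ndarray, offset):
    """Return aligned views (base, shifted) of ``a`` under the offset."""
    slices_a, slices_b = [], []
    for d, size in zip(offset, a.shape):
        if d == 0:
            slices_a.append(slice(None))
            slices_b.append(slice(None))
        elif d > 0:
            slices_a.append(slice(0, size - d))
            slices_b.append(slice(d, size))
        else:
            slices_a.append(slice(-d, size))
            slices_b.append(slice(0, size + d))
    return a[tuple(slices_a)], a[tuple(slices_b)]


# ---------------------------------------------------------------------------
# matrix builders


def glcm_matrices(bins: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts, one (Ng x Ng) matrix per direction."""
    out = np.zeros((len(ANGLES_13), n_levels, n_levels))
    for k, off in enumerate(ANGLES_13):
        a, b = _shifted_views(bins, off)
        valid = (a > 0) & (b > 0)
        i, j = a[valid] - 1, b[valid] - 1
        np.add.at(out[k], (i, j), 1)
        np.add.at(out[k], (j, i), 1)
    return out


def glrlm_matrices(bins: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Run-length counts per direction: rows = gray level, cols = run length."""
    matrices = []
    for off in ANGLES_13:
        runs: dict[tuple[int, int], int] = {}
        # a run start is an in-ROI voxel whose predecessor along -off differs
        prev_arr = np.zeros_like(bins)
        bins_base, _ = _shifted_views(bins, off)
        _, prev_shift = _shifted_views(prev_arr, off)
        prev_shift[...] = bins_base  # prev_arr[v] = bins[v - off]
        starts = np.argwhere((bins > 0) & (prev_arr != bins))
        d = np.array(off)
        shape = np.array(bins.shape)
        for s in starts:
            level = bins[tuple(s)]
            length = 1
            nxt = s + d
            while np.all(nxt >= 0) and np.all(nxt < shape) and bins[tuple(nxt)] == level:
                length += 1
                nxt = nxt + d
            key = (int(level), length)
            runs[key] = runs.get(key, 0) + 1
        max_len = max((l for (_, l) in runs), default=1)
        m = np.zeros((n_levels, max_len))
        for (level, length), c in runs.items():
            m[level - 1, length - 1] = c
        matrices.append(m)
    return matrices


def glszm_matrix(bins: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts: rows = gray level, cols = zone size (26-connected)."""
    zones: list[tuple[int, int]] = []
    for level in range(1, n_levels + 1):
        labeled, nz = ndimage.label(bins == level, structure=_STRUCT26)
        if nz:
            sizes = np.bincount(labeled.ravel())[1:]
            zones.extend((level, int(s)) for s in sizes)
    if not zones:
        return np.zeros((n_levels, 1))
    max_size = max(s for _, s in zones)
    m = np.zeros((n_levels, max_size))
    for level, s in zones:
        m[level - 1, s - 1] += 1
    return m


def gldm_matrix(bins: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts: rows = gray level, cols = number of dependent neighbours.

    A 26-neighbour j is dependent on centre i when |level_i - level_j| <= alpha;
    column k holds the count of in-ROI voxels with exactly k dependent
    neighbours (k = 0..26).
    """
    dep = np.zeros(bins.shape, dtype=np.int64)
    in_roi = bins > 0
    for off in ANGLES_13:
        a, b = _shifted_views(bins, off)
        match = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        da, db = _shifted_views(dep, off)
        da += match
        db += match
    m = np.zeros((n_levels, 27))
    np.add.at(m, (bins[in_roi] - 1, dep[in_roi]), 1)
    return m


def ngtdm_table(bins: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-level (n_i, p_i, s_i): counts, probabilities, and summed absolute
    differences from the mean of the valid 26-neighbourhood (centre excluded).
    Voxels with no in-ROI neighbour contribute 0 to s_i."""
    in_roi = bins > 0
    nsum = np.zeros(bins.shape)
    ncnt = np.zeros(bins.shape)
    for off in ANGLES_13:
        a, b = _shifted_views(bins, off)
        both = (a > 0) & (b > 0)
        sa, sb = _shifted_views(nsum, off)
        ca, cb = _shifted_views(ncnt, off)
        sa += np.where(both, b, 0)
        sb += np.where(both, a, 0)
        ca += both
        cb += both
    n_total = int(in_roi.sum())
    table = np.zeros((n_levels, 3))
    levels = bins[in_roi]
    has_nb = ncnt[in_roi] > 0
    avg = np.where(has_nb, nsum[in_roi] / np.maximum(ncnt[in_roi], 1), 0.0)
    diff = np.where(has_nb, np.abs(levels - avg), 0.0)
    np.add.at(table[:, 0], levels - 1, 1)
    np.add.at(table[:, 2], levels - 1, diff)
    table[:, 1] = table[:, 0] / n_total
    return table


def texture_matrices(sample: RoiSample) -> dict[str, object]:
    """Build all five texture-matrix families for one preprocessed ROI."""
    bins, ng = sample.bins, sample.n_levels
    return {
        "glcm": glcm_matrices(bins, ng),
        "glrlm": glrlm_matrices(bins, ng),
        "glszm": glszm_matrix(bins, ng),
        "gldm": gldm_matrix(bins, ng),
        "ngtdm": ngtdm_table(bins, ng),
    }


# ---------------------------------------------------------------------------
# features


def _glcm_features_one(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    if total == 0:
        return {k: 0.0 for k in ("Contrast", "JointEntropy", "Idm", "Idn", "Idmn", "Correlation")}
    p = P / total
    ng = p.shape[0]
    i, j = np.meshgrid(np.arange(1, ng + 1), np.arange(1, ng + 1), indexing="ij")
    px = p.sum(axis=1)
    mu = (np.arange(1, ng + 1) * px).sum()
    sigma2 = (((np.arange(1, ng + 1) - mu) ** 2) * px).sum()
    nz = p > 0
    contrast = float(((i - j) ** 2 * p).sum())
    joint_entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    idn = float((p / (1.0 + np.abs(i - j) / ng)).sum())
    idmn = float((p / (1.0 + (i - j) ** 2 / ng**2)).sum())
    if sigma2 > 0:
        corr = float((((i - mu) * (j - mu) * p).sum()) / sigma2)
    else:
        corr = 1.0  # single gray level: perfectly correlated by convention
    return {
        "Contrast": contrast,
        "JointEntropy": joint_entropy,
        "Idm": idm,
        "Idn": idn,
        "Idmn": idmn,
        "Correlation": corr,
    }


def _glrlm_features_one(R: np.ndarray) -> dict[str, float]:
    nr = R.sum()
    if nr == 0:
        return {k: 0.0 for k in (
            "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
            "RunLengthNonUniformity", "RunPercentage")}
    lengths = np.arange(1, R.shape[1] + 1)
    row = R.sum(axis=1)
    col = R.sum(axis=0)
    n_vox = (col * lengths).sum()
    return {
        "ShortRunEmphasis": float((col / lengths**2).sum() / nr),
        "LongRunEmphasis": float((col * lengths**2).sum() / nr),
        "GrayLevelNonUniformity": float((row**2).sum() / nr),
        "RunLengthNonUniformity": float((col**2).sum() / nr),
        "RunPercentage": float(nr / n_vox),
    }


def _glszm_features(Z: np.ndarray) -> dict[str, float]:
    nz = Z.sum()
    names = (
        "SmallAreaEmphasis", "LargeAreaEmphasis", "SizeZoneNonUniformity",
        "GrayLevelNonUniformity", "LowGrayLevelZoneEmphasis",
        "HighGrayLevelZoneEmphasis", "SmallAreaHighGrayLevelEmphasis",
        "ZonePercentage", "ZoneEntropy",
    )
    if nz == 0:
        return {k: 0.0 for k in names}
    sizes = np.arange(1, Z.shape[1] + 1)
    levels = np.arange(1, Z.shape[0] + 1)
    row = Z.sum(axis=1)  # per gray level
    col = Z.sum(axis=0)  # per zone size
    n_vox = (col * sizes).sum()
    p = Z / nz
    pnz = p[p > 0]
    lv, sz = np.meshgrid(levels, sizes, indexing="ij")
    return {
        "SmallAreaEmphasis": float((col / sizes**2).sum() / nz),
        "LargeAreaEmphasis": float((col * sizes**2).sum() / nz),
        "SizeZoneNonUniformity": float((col**2).sum() / nz),
        "GrayLevelNonUniformity": float((row**2).sum() / nz),
        "LowGrayLevelZoneEmphasis": float((row / levels**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((row * levels**2).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((Z * lv**2 / sz**2).sum() / nz),
        "ZonePercentage": float(nz / n_vox),
        "ZoneEntropy": float(-(pnz * np.log2(pnz)).sum()),
    }


def _gldm_features(D: np.ndarray) -> dict[str, float]:
    nd = D.sum()
    names = (
        "SmallDependenceEmphasis", "LargeDependenceEmphasis",
        "DependenceNonUniformity", "GrayLevelNonUniformity", "DependenceEntropy",
    )
    if nd == 0:
        return {k: 0.0 for k in names}
    # dependence size j = number of dependent neighbours + 1 (the centre voxel)
    j = np.arange(1, D.shape[1] + 1)
    row = D.sum(axis=1)
    col = D.sum(axis=0)
    p = D / nd
    pnz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((col / j**2).sum() / nd),
        "LargeDependenceEmphasis": float((col * j**2).sum() / nd),
        "DependenceNonUniformity": float((col**2).sum() / nd),
        "GrayLevelNonUniformity": float((row**2).sum() / nd),
        "DependenceEntropy": float(-(pnz * np.log2(pnz)).sum()),
    }


def _ngtdm_features(T: np.ndarray) -> dict[str, float]:
    n_i, p_i, s_i = T[:, 0], T[:, 1], T[:, 2]
    present = p_i > 0
    levels = np.arange(1, T.shape[0] + 1, dtype=float)
    n_total = n_i.sum()
    ngp = int(present.sum())
    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    # Busyness: denominator over pairs of *present* levels; 0 by convention
    # when only one gray level exists (denominator vanishes).
    ip = levels[present] * p_i[present]
    busy_den = float(np.abs(ip[:, None] - ip[None, :]).sum())
    busyness = coarse_den / busy_den if busy_den > 0 else 0.0

    if ngp > 1 and n_total > 0:
        li = levels[present]
        pi = p_i[present]
        diff2 = (li[:, None] - li[None, :]) ** 2
        contrast = float((pi[:, None] * pi[None, :] * diff2).sum() / (ngp * (ngp - 1))) * float(
            s_i.sum() / n_total
        )
    else:
        contrast = 0.0

    s_sum = float(s_i.sum())
    if s_sum > 0 and ngp > 1:
        li = levels[present]
        pi = p_i[present]
        diff2 = (li[:, None] - li[None, :]) ** 2
        strength = float(((pi[:, None] + pi[None, :]) * diff2).sum() / s_sum)
    else:
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Busyness": busyness,
        "Contrast": contrast,
        "Strength": strength,
    }


def texture_features(matrices: dict[str, object]) -> dict[str, float]:
    """Direction-averaged feature map over all five matrix families,
    with keys prefixed by the matrix class (e.g. ``glcm_Idmn``)."""
    out: dict[str, float] = {}
    glcm_per_dir = [_glcm_features_one(P) for P in matrices["glcm"]]
    for key in glcm_per_dir[0]:
        out[f"glcm_{key}"] = float(np.mean([d[key] for d in glcm_per_dir]))
    glrlm_per_dir = [_glrlm_features_one(R) for R in matrices["glrlm"]]
    for key in glrlm_per_dir[0]:
        out[f"glrlm_{key}"] = float(np.mean([d[key] for d in glrlm_per_dir]))
    for key, val in _glszm_features(matrices["glszm"]).items():
        out[f"glszm_{key}"] = val
    for key, val in _gldm_features(matrices["gldm"]).items():
        out[f"gldm_{key}"] = val
    for key, val in _ngtdm_features(matrices["ngtdm"]).items():
        out[f"ngtdm_{key}"] = val
    return out
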