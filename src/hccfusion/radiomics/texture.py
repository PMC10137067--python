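"""Gray-level texture-matrix features: GLCM, GLRLM, GLSZM, GLDM (68 features).

All matrices are built in 3D on the discretized gray levels (1..Ng, 0
outside the VOI):

* GLCM — symmetric co-occurrence at distance 1 over the 13 unique 3D
  direction offsets; the 22 features are evaluated per direction and then
  averaged (feature-then-average).
* GLRLM — maximal same-level runs per direction, 13 directions, likewise
  feature-then-average (16 features).
* GLSZM — 26-connected constant-level zones, one matrix per VOI
  (16 features).
* GLDM — dependence counts: a voxel's dependence is 1 plus the number of
  its 26-neighbours inside the VOI with exactly the same level (alpha = 0);
  one matrix per VOI (14 features).

Degenerate VOIs (a single gray level) produce the limit value of each
feature rather than NaN; such events are logged at debug level.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: the 13 unique direction offsets of the 26-neighbourhood (z, y, x)
OFFSETS_13 = tuple(
    o
    for o in itertools.product((-1, 0, 1), repeat=3)
    if o != (0, 0, 0)
    and (o[0] > 0 or (o[0] == 0 and (o[1] > 0 or (o[1] == 0 and o[2] > 0))))
)

OFFSETS_26 = tuple(
    o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)
)

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

TEXTURE_CLASSES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
}


def _pair_slices(shape, offset):
    """(src, dst) slice tuples such that dst = src + offset, both in bounds."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        src.append(slice(max(0, -o), n - max(0, o)))
        dst.append(slice(max(0, o), n - max(0, -o)))
    return tuple(src), tuple(dst)


def _shift(arr: np.ndarray, offset, fill=0) -> np.ndarray:
    """Array with ``out[v] = arr[v + offset]`` (``fill`` beyond the border)."""
    out = np.full_like(arr, fill)
    src, dst = _pair_slices(arr.shape, offset)
    out[src] = arr[dst]
    return out


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def glcm_matrices(levels: np.ndarray, ng: int) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrices, one per direction.

    ``levels`` holds 1..Ng inside the VOI and 0 outside.  Directions with
    no valid voxel pair are omitted.
    """
    matrices = []
    for offset in OFFSETS_13:
        src, dst = _pair_slices(levels.shape, offset)
        a, b = levels[src].ravel(), levels[dst].ravel()
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        counts = np.bincount(
            (a[valid] - 1) * ng + (b[valid] - 1), minlength=ng * ng
        ).reshape(ng, ng)
        matrices.append(counts + counts.T)
    return matrices


def glrlm_matrices(levels: np.ndarray, ng: int) -> list[np.ndarray]:
    """Run-length count matrices P(g, r), one per direction."""
    valid = levels > 0
    max_run = max(levels.shape)
    matrices = []
    for offset in OFFSETS_13:
        # cont[v]: voxel v and v+offset form a same-level in-VOI pair
        nxt = _shift(levels, offset, fill=0)
        cont = valid & (nxt == levels) & (nxt > 0)
        # run length by backward dynamic programming: L = 1 + cont * L(v+o)
        runlen = np.ones(levels.shape, dtype=np.int64)
        for _ in range(max_run - 1):
            new = 1 + cont * _shift(runlen, offset, fill=0)
            if np.array_equal(new, runlen):
                break
            runlen = new
        # a run starts where the predecessor does not continue into v
        prev_cont = _shift(cont, tuple(-o for o in offset), fill=False)
        starts = valid & ~prev_cont
        g = levels[starts] - 1
        r = runlen[starts] - 1
        mat = np.zeros((ng, int(r.max()) + 1 if r.size else 1), dtype=np.int64)
        np.add.at(mat, (g, r), 1)
        matrices.append(mat)
    return matrices


def glszm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone count matrix P(g, s) from 26-connected constant-level zones."""
    structure = np.ones((3, 3, 3), dtype=bool)
    sizes_per_level = []
    max_size = 1
    for g in range(1, ng + 1):
        labeled, n_zones = ndimage.label(levels == g, structure=structure)
        if n_zones == 0:
            sizes_per_level.append(np.array([], dtype=np.int64))
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        sizes_per_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((ng, max_size), dtype=np.int64)
    for g, sizes in enumerate(sizes_per_level):
        for s in sizes:
            mat[g, s - 1] += 1
    return mat


def gldm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    """Dependence count matrix P(g, d); d = 1 + #equal-level 26-neighbours."""
    valid = levels > 0
    dep = np.ones(levels.shape, dtype=np.int64)
    for offset in OFFSETS_26:
        nxt = _shift(levels, offset, fill=0)
        dep += (valid & (nxt == levels) & (nxt > 0)).astype(np.int64)
    g = levels[valid] - 1
    d = dep[valid] - 1
    mat = np.zeros((ng, int(d.max()) + 1 if d.size else 1), dtype=np.int64)
    np.add.at(mat, (g, d), 1)
    return mat


# ---------------------------------------------------------------------------
# feature evaluation
# ---------------------------------------------------------------------------

def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


def glcm_features_from_matrix(counts: np.ndarray) -> dict[str, float]:
    """The 22 GLCM features of one symmetric co-occurrence count matrix."""
    ng = counts.shape[0]
    p = counts / counts.sum()
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((px * i).sum())
    sigma2 = float((px * (i - mu) ** 2).sum())

    # diagonal-band marginals
    diff = np.abs(ii - jj)
    p_diff = np.array([p[diff == k].sum() for k in range(ng)])
    s = ii + jj
    p_sum = np.array([p[s == k].sum() for k in range(2, 2 * ng + 1)])
    ks_diff = np.arange(ng)

    autocorr = float((p * ii * jj).sum())
    da = float((p_diff * ks_diff).sum())
    contrast = float((p_diff * ks_diff**2).sum())

    if sigma2 > 0:
        correlation = (autocorr - mu * mu) / sigma2
    else:
        logger.debug("single gray level: GLCM Correlation set to 1")
        correlation = 1.0

    hxy = float(-_xlog2(p).sum())
    hx = float(-_xlog2(px).sum())
    outer = np.outer(px, px)
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-(p[pos] * np.log2(outer[pos])).sum())
    hxy2 = float(-_xlog2(outer).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    offdiag = diff > 0
    inv_var = float((p[offdiag] / diff[offdiag] ** 2).sum())

    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-_xlog2(p_diff).sum()),
        "DifferenceVariance": float((p_diff * (ks_diff - da) ** 2).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "Id": float((p / (1.0 + diff)).sum()),
        "Idn": float((p / (1.0 + diff / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-_xlog2(p_sum).sum()),
        "SumSquares": float((p * (ii - mu) ** 2).sum()),
    }


def _gray_size_features(mat: np.ndarray, n_voxels: int, names: dict[str, str]) -> dict:
    """Shared gray-level x size family (GLRLM runs / GLSZM zones / GLDM deps).

    ``mat[g-1, s-1]`` counts elements of gray level g and size s; ``names``
    maps generic keys to class-specific feature names.
    """
    ns = mat.sum()
    p = mat / ns
    g = np.arange(1, mat.shape[0] + 1, dtype=float)
    s = np.arange(1, mat.shape[1] + 1, dtype=float)
    gg, ss = np.meshgrid(g, s, indexing="ij")
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((pg * g).sum())
    mu_s = float((ps * s).sum())

    out = {
        names["small"]: float((p / ss**2).sum()),
        names["large"]: float((p * ss**2).sum()),
        names["gln"]: float((mat.sum(axis=1).astype(float) ** 2).sum() / ns),
        names["sn"]: float((mat.sum(axis=0).astype(float) ** 2).sum() / ns),
        names["glv"]: float((p * (gg - mu_g) ** 2).sum()),
        names["sv"]: float((p * (ss - mu_s) ** 2).sum()),
        names["entropy"]: float(-_xlog2(p).sum()),
        names["lowg"]: float((p / gg**2).sum()),
        names["highg"]: float((p * gg**2).sum()),
        names["smalllow"]: float((p / (gg**2 * ss**2)).sum()),
        names["smallhigh"]: float((p * gg**2 / ss**2).sum()),
        names["largelow"]: float((p * ss**2 / gg**2).sum()),
        names["largehigh"]: float((p * gg**2 * ss**2).sum()),
    }
    if "glnn" in names:
        out[names["glnn"]] = out[names["gln"]] / ns
    if "snn" in names:
        out[names["snn"]] = out[names["sn"]] / ns
    if "percentage" in names:
        out[names["percentage"]] = float(ns / n_voxels)
    return out


def glrlm_features_from_matrix(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    out = _gray_size_features(
        mat,
        n_voxels,
        {
            "small": "ShortRunEmphasis",
            "large": "LongRunEmphasis",
            "gln": "GrayLevelNonUniformity",
            "glnn": "GrayLevelNonUniformityNormalized",
            "sn": "RunLengthNonUniformity",
            "snn": "RunLengthNonUniformityNormalized",
            "percentage": "RunPercentage",
            "glv": "GrayLevelVariance",
            "sv": "RunVariance",
            "entropy": "RunEntropy",
            "lowg": "LowGrayLevelRunEmphasis",
            "highg": "HighGrayLevelRunEmphasis",
            "smalllow": "ShortRunLowGrayLevelEmphasis",
            "smallhigh": "ShortRunHighGrayLevelEmphasis",
            "largelow": "LongRunLowGrayLevelEmphasis",
            "largehigh": "LongRunHighGrayLevelEmphasis",
        },
    )
    return {name: out[name] for name in GLRLM_NAMES}


def glszm_features_from_matrix(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    out = _gray_size_features(
        mat,
        n_voxels,
        {
            "small": "SmallAreaEmphasis",
            "large": "LargeAreaEmphasis",
            "gln": "GrayLevelNonUniformity",
            "glnn": "GrayLevelNonUniformityNormalized",
            "sn": "SizeZoneNonUniformity",
            "snn": "SizeZoneNonUniformityNormalized",
            "percentage": "ZonePercentage",
            "glv": "GrayLevelVariance",
            "sv": "ZoneVariance",
            "entropy": "ZoneEntropy",
            "lowg": "LowGrayLevelZoneEmphasis",
            "highg": "HighGrayLevelZoneEmphasis",
            "smalllow": "SmallAreaLowGrayLevelEmphasis",
            "smallhigh": "SmallAreaHighGrayLevelEmphasis",
            "largelow": "LargeAreaLowGrayLevelEmphasis",
            "largehigh": "LargeAreaHighGrayLevelEmphasis",
        },
    )
    return {name: out[name] for name in GLSZM_NAMES}


def gldm_features_from_matrix(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    out = _gray_size_features(
        mat,
        n_voxels,
        {
            "small": "SmallDependenceEmphasis",
            "large": "LargeDependenceEmphasis",
            "gln": "GrayLevelNonUniformity",
            "sn": "DependenceNonUniformity",
            "snn": "DependenceNonUniformityNormalized",
            "glv": "GrayLevelVariance",
            "sv": "DependenceVariance",
            "entropy": "DependenceEntropy",
            "lowg": "LowGrayLevelEmphasis",
            "highg": "HighGrayLevelEmphasis",
            "smalllow": "SmallDependenceLowGrayLevelEmphasis",
            "smallhigh": "SmallDependenceHighGrayLevelEmphasis",
            "largelow": "LargeDependenceLowGrayLevelEmphasis",
            "largehigh": "LargeDependenceHighGrayLevelEmphasis",
        },
    )
    return {name: out[name] for name in GLDM_NAMES}


def texture_features(levels: np.ndarray, mask: np.ndarray | None = None) -> dict[str, dict[str, float]]:
    """All 68 texture features of a discretized VOI.

    Parameters
    ----------
    levels : integer array, 1..Ng inside the VOI, 0 outside.
    mask : optional boolean array; defaults to ``levels > 0``.

    Returns
    -------
    dict mapping class name ('glcm', 'glrlm', 'glszm', 'gldm') to its
    feature dict.
    """
    levels = np.asarray(levels)
    if mask is not None:
        levels = np.where(np.asarray(mask, dtype=bool), levels, 0)
    if (levels < 0).any():
        raise ValueError("levels must be non-negative integers")
    n_voxels = int((levels > 0).sum())
    if n_voxels == 0:
        raise ValueError("empty mask: no voxels to extract texture from")
    ng = int(levels.max())

    glcm_per_dir = [glcm_features_from_matrix(m) for m in glcm_matrices(levels, ng)]
    if not glcm_per_dir:
        # single-voxel VOI: no co-occurring pair in any direction; report the
        # degenerate single-cell matrix values
        logger.debug("no voxel pairs: GLCM evaluated on the degenerate matrix")
        glcm_per_dir = [glcm_features_from_matrix(np.array([[2]]))]
    glcm = {
        name: float(np.mean([f[name] for f in glcm_per_dir])) for name in GLCM_NAMES
    }
    glrlm_per_dir = [
        glrlm_features_from_matrix(m, n_voxels) for m in glrlm_matrices(levels, ng)
    ]
    glrlm = {
        name: float(np.mean([f[name] for f in glrlm_per_dir])) for name in GLRLM_NAMES
    }
    glszm = glszm_features_from_matrix(glszm_matrix(levels, ng), n_voxels)
    gldm = gldm_features_from_matrix(gldm_matrix(levels, ng), n_voxels)
    return {"glcm": glcm, "glrlm": glrlm, "glszm": glszm, "gldm": gldm}
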