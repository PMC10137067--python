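"""Brute-force oracles used by the tests.

Everything here is deliberately naive: explicit python loops over voxels,
pairs, runs, zones and matrix cells, written directly from the textbook
definitions, independent of the vectorized implementation under test.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def in_bounds(v, shape):
    return all(0 <= v[i] < shape[i] for i in range(3))


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------

def glcm_counts_oracle(levels, offset, ng):
    """Symmetric pair counts by exhaustive enumeration of voxel pairs."""
    C = [[0] * ng for _ in range(ng)]
    shape = levels.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                a = levels[z, y, x]
                if a == 0:
                    continue
                w = (z + offset[0], y + offset[1], x + offset[2])
                if not in_bounds(w, shape):
                    continue
                b = levels[w]
                if b == 0:
                    continue
                C[a - 1][b - 1] += 1
                C[b - 1][a - 1] += 1
    return np.array(C, dtype=float)


def glcm_features_oracle(C):
    ng = C.shape[0]
    total = C.sum()
    p = [[C[i][j] / total for j in range(ng)] for i in range(ng)]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum(px[i] * (i + 1 - mu) ** 2 for i in range(ng))

    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)  # index k-2 for k = 2..2ng
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i][j]
            p_sum[i + j] += p[i][j]

    def ent(values):
        return -sum(v * math.log2(v) for v in values if v > 0)

    autocorr = sum(
        p[i][j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)
    )
    da = sum(k * p_diff[k] for k in range(ng))
    contrast = sum(k * k * p_diff[k] for k in range(ng))
    correlation = (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 1.0
    hxy = ent(p[i][j] for i in range(ng) for j in range(ng))
    hx = ent(px)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = ent(px[i] * px[j] for i in range(ng) for j in range(ng))
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": sum(
            p[i][j] * (i + j + 2 - 2 * mu) ** 4 for i in range(ng) for j in range(ng)
        ),
        "ClusterShade": sum(
            p[i][j] * (i + j + 2 - 2 * mu) ** 3 for i in range(ng) for j in range(ng)
        ),
        "ClusterTendency": sum(
            p[i][j] * (i + j + 2 - 2 * mu) ** 2 for i in range(ng) for j in range(ng)
        ),
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": sum(
            p_diff[k] * (k - da) ** 2 for k in range(ng)
        ),
        "JointEnergy": sum(
            p[i][j] ** 2 for i in range(ng) for j in range(ng)
        ),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": sum(
            p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
        ),
        "Idmn": sum(
            p[i][j] / (1 + (i - j) ** 2 / ng**2)
            for i in range(ng)
            for j in range(ng)
        ),
        "Id": sum(
            p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
        ),
        "Idn": sum(
            p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        ),
        "InverseVariance": sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "MaximumProbability": max(
            p[i][j] for i in range(ng) for j in range(ng)
        ),
        "SumEntropy": ent(p_sum),
        "SumSquares": sum(
            p[i][j] * (i + 1 - mu) ** 2 for i in range(ng) for j in range(ng)
        ),
    }


# ---------------------------------------------------------------------------
# runs, zones, dependences
# ---------------------------------------------------------------------------

def runs_oracle(levels, offset):
    """All maximal same-level runs along ``offset`` as (gray, length) tuples."""
    shape = levels.shape
    runs = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                g = levels[z, y, x]
                if g == 0:
                    continue
                prev = (z - offset[0], y - offset[1], x - offset[2])
                if in_bounds(prev, shape) and levels[prev] == g:
                    continue  # not the start of a run
                length = 1
                cur = (z + offset[0], y + offset[1], x + offset[2])
                while in_bounds(cur, shape) and levels[cur] == g:
                    length += 1
                    cur = tuple(cur[i] + offset[i] for i in range(3))
                runs.append((int(g), length))
    return runs


def zones_oracle(levels):
    """26-connected constant-level zones as (gray, size) tuples via BFS."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    neighbors = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    zones = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                g = levels[z, y, x]
                if g == 0 or seen[z, y, x]:
                    continue
                size = 0
                queue = deque([(z, y, x)])
                seen[z, y, x] = True
                while queue:
                    v = queue.popleft()
                    size += 1
                    for d in neighbors:
                        w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                        if in_bounds(w, shape) and not seen[w] and levels[w] == g:
                            seen[w] = True
                            queue.append(w)
                zones.append((int(g), size))
    return zones


def dependences_oracle(levels):
    """(gray, 1 + #equal-level 26-neighbours) per in-mask voxel."""
    shape = levels.shape
    out = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                g = levels[z, y, x]
                if g == 0:
                    continue
                dep = 1
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            w = (z + dz, y + dy, x + dx)
                            if in_bounds(w, shape) and levels[w] == g:
                                dep += 1
                out.append((int(g), dep))
    return out


def gray_size_matrix(items, ng):
    """(gray, size) tuples -> count matrix with rows 1..ng."""
    max_s = max(s for _g, s in items)
    mat = [[0] * max_s for _ in range(ng)]
    for g, s in items:
        mat[g - 1][s - 1] += 1
    return np.array(mat, dtype=float)


def gray_size_features_oracle(mat, n_voxels):
    """Naive evaluation of the shared gray-level x size feature family.

    Returns generic keys; tests map them onto the class-specific names.
    """
    ng, ns_max = mat.shape
    total = mat.sum()
    p = [[mat[g][s] / total for s in range(ns_max)] for g in range(ng)]
    pg = [sum(p[g][s] for s in range(ns_max)) for g in range(ng)]
    ps = [sum(p[g][s] for g in range(ng)) for s in range(ns_max)]
    mu_g = sum((g + 1) * pg[g] for g in range(ng))
    mu_s = sum((s + 1) * ps[s] for s in range(ns_max))
    return {
        "small": sum(
            p[g][s] / (s + 1) ** 2 for g in range(ng) for s in range(ns_max)
        ),
        "large": sum(
            p[g][s] * (s + 1) ** 2 for g in range(ng) for s in range(ns_max)
        ),
        "gln": sum(sum(mat[g]) ** 2 for g in range(ng)) / total,
        "glnn": sum(sum(mat[g]) ** 2 for g in range(ng)) / total**2,
        "sn": sum(
            sum(mat[g][s] for g in range(ng)) ** 2 for s in range(ns_max)
        )
        / total,
        "snn": sum(
            sum(mat[g][s] for g in range(ng)) ** 2 for s in range(ns_max)
        )
        / total**2,
        "percentage": total / n_voxels,
        "glv": sum(
            p[g][s] * (g + 1 - mu_g) ** 2 for g in range(ng) for s in range(ns_max)
        ),
        "sv": sum(
            p[g][s] * (s + 1 - mu_s) ** 2 for g in range(ng) for s in range(ns_max)
        ),
        "entropy": -sum(
            p[g][s] * math.log2(p[g][s])
            for g in range(ng)
            for s in range(ns_max)
            if p[g][s] > 0
        ),
        "lowg": sum(
            p[g][s] / (g + 1) ** 2 for g in range(ng) for s in range(ns_max)
        ),
        "highg": sum(
            p[g][s] * (g + 1) ** 2 for g in range(ng) for s in range(ns_max)
        ),
        "smalllow": sum(
            p[g][s] / ((g + 1) ** 2 * (s + 1) ** 2)
            for g in range(ng)
            for s in range(ns_max)
        ),
        "smallhigh": sum(
            p[g][s] * (g + 1) ** 2 / (s + 1) ** 2
            for g in range(ng)
            for s in range(ns_max)
        ),
        "largelow": sum(
            p[g][s] * (s + 1) ** 2 / (g + 1) ** 2
            for g in range(ng)
            for s in range(ns_max)
        ),
        "largehigh": sum(
            p[g][s] * (g + 1) ** 2 * (s + 1) ** 2
            for g in range(ng)
            for s in range(ns_max)
        ),
    }


GLRLM_KEYMAP = {
    "ShortRunEmphasis": "small",
    "LongRunEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "RunLengthNonUniformity": "sn",
    "RunLengthNonUniformityNormalized": "snn",
    "RunPercentage": "percentage",
    "GrayLevelVariance": "glv",
    "RunVariance": "sv",
    "RunEntropy": "entropy",
    "LowGrayLevelRunEmphasis": "lowg",
    "HighGrayLevelRunEmphasis": "highg",
    "ShortRunLowGrayLevelEmphasis": "smalllow",
    "ShortRunHighGrayLevelEmphasis": "smallhigh",
    "LongRunLowGrayLevelEmphasis": "largelow",
    "LongRunHighGrayLevelEmphasis": "largehigh",
}

GLSZM_KEYMAP = {
    "SmallAreaEmphasis": "small",
    "LargeAreaEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "sn",
    "SizeZoneNonUniformityNormalized": "snn",
    "ZonePercentage": "percentage",
    "GrayLevelVariance": "glv",
    "ZoneVariance": "sv",
    "ZoneEntropy": "entropy",
    "LowGrayLevelZoneEmphasis": "lowg",
    "HighGrayLevelZoneEmphasis": "highg",
    "SmallAreaLowGrayLevelEmphasis": "smalllow",
    "SmallAreaHighGrayLevelEmphasis": "smallhigh",
    "LargeAreaLowGrayLevelEmphasis": "largelow",
    "LargeAreaHighGrayLevelEmphasis": "largehigh",
}

GLDM_KEYMAP = {
    "SmallDependenceEmphasis": "small",
    "LargeDependenceEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "DependenceNonUniformity": "sn",
    "DependenceNonUniformityNormalized": "snn",
    "GrayLevelVariance": "glv",
    "DependenceVariance": "sv",
    "DependenceEntropy": "entropy",
    "LowGrayLevelEmphasis": "lowg",
    "HighGrayLevelEmphasis": "highg",
    "SmallDependenceLowGrayLevelEmphasis": "smalllow",
    "SmallDependenceHighGrayLevelEmphasis": "smallhigh",
    "LargeDependenceLowGrayLevelEmphasis": "largelow",
    "LargeDependenceHighGrayLevelEmphasis": "largehigh",
}

OFFSETS_13 = [
    o
    for o in [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
    ]
    if o != (0, 0, 0)
    and (o[0] > 0 or (o[0] == 0 and (o[1] > 0 or (o[1] == 0 and o[2] > 0))))
]


def texture_features_oracle(levels):
    """All 68 texture features by brute force (feature-then-average)."""
    levels = np.asarray(levels)
    ng = int(levels.max())
    n_voxels = int((levels > 0).sum())

    glcm_feats = []
    for offset in OFFSETS_13:
        C = glcm_counts_oracle(levels, offset, ng)
        if C.sum() > 0:
            glcm_feats.append(glcm_features_oracle(C))
    glcm = {
        k: float(np.mean([f[k] for f in glcm_feats])) for k in glcm_feats[0]
    }

    glrlm_feats = []
    for offset in OFFSETS_13:
        runs = runs_oracle(levels, offset)
        mat = gray_size_matrix(runs, ng)
        generic = gray_size_features_oracle(mat, n_voxels)
        glrlm_feats.append({k: generic[v] for k, v in GLRLM_KEYMAP.items()})
    glrlm = {
        k: float(np.mean([f[k] for f in glrlm_feats])) for k in glrlm_feats[0]
    }

    zmat = gray_size_matrix(zones_oracle(levels), ng)
    zg = gray_size_features_oracle(zmat, n_voxels)
    glszm = {k: zg[v] for k, v in GLSZM_KEYMAP.items()}

    dmat = gray_size_matrix(dependences_oracle(levels), ng)
    dg = gray_size_features_oracle(dmat, n_voxels)
    gldm = {k: dg[v] for k, v in GLDM_KEYMAP.items()}

    return {"glcm": glcm, "glrlm": glrlm, "glszm": glszm, "gldm": gldm}
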