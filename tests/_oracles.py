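"""Independent brute-force oracles for texture matrices and features.

Everything here is written as plain nested loops over voxels and matrix
cells, deliberately sharing no code with the package implementation, so the
vectorized builders can be checked against exhaustive enumeration on tiny
volumes.
"""

from __future__ import annotations

import numpy as np

OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
DIRECTIONS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]


def _in_bounds(v, shape):
    return all(0 <= v[i] < shape[i] for i in range(3))


def glcm_brute(levels, mask, n_levels):
    """Ordered co-occurrence counts over all 26 neighbor offsets (equivalent
    to 13 directions with both orderings)."""
    counts = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for v in np.ndindex(shape):
        if not mask[v]:
            continue
        for d in OFFSETS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in_bounds(w, shape) and mask[w]:
                counts[levels[v] - 1, levels[w] - 1] += 1
    return counts


def glrlm_brute(levels, mask, n_levels):
    """Maximal constant-level runs per direction, summed over directions."""
    shape = levels.shape
    runs = []  # (level, length)
    for d in DIRECTIONS_13:
        for v in np.ndindex(shape):
            if not mask[v]:
                continue
            prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            if (
                _in_bounds(prev, shape)
                and mask[prev]
                and levels[prev] == levels[v]
            ):
                continue  # not a run start
            length = 1
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            while _in_bounds(w, shape) and mask[w] and levels[w] == levels[v]:
                length += 1
                w = (w[0] + d[0], w[1] + d[1], w[2] + d[2])
            runs.append((levels[v], length))
    max_run = max(l for _, l in runs)
    counts = np.zeros((n_levels, max_run))
    for lev, length in runs:
        counts[lev - 1, length - 1] += 1
    return counts


def glszm_brute(levels, mask, n_levels):
    """26-connected flood fill of constant-level zones."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []  # (level, size)
    for v in np.ndindex(shape):
        if not mask[v] or seen[v]:
            continue
        lev = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for d in OFFSETS_26:
                w = (u[0] + d[0], u[1] + d[1], u[2] + d[2])
                if (
                    _in_bounds(w, shape)
                    and mask[w]
                    and not seen[w]
                    and levels[w] == lev
                ):
                    seen[w] = True
                    stack.append(w)
        zones.append((lev, size))
    max_zone = max(s for _, s in zones)
    counts = np.zeros((n_levels, max_zone))
    for lev, size in zones:
        counts[lev - 1, size - 1] += 1
    return counts


def ngtdm_brute(levels, mask, n_levels):
    """Per-level |i - neighborhood mean| sums and level probabilities."""
    shape = levels.shape
    s = np.zeros(n_levels)
    cnt = np.zeros(n_levels)
    n_valid = 0
    for v in np.ndindex(shape):
        if not mask[v]:
            continue
        nb = []
        for d in OFFSETS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in_bounds(w, shape) and mask[w]:
                nb.append(levels[w])
        if not nb:
            continue
        n_valid += 1
        lev = levels[v]
        s[lev - 1] += abs(lev - sum(nb) / len(nb))
        cnt[lev - 1] += 1
    return s, cnt / n_valid, n_valid


# ---------------------------------------------------------------------------
# feature formulas as naive loops
# ---------------------------------------------------------------------------


def histogram_features_brute(values):
    x = [float(v) for v in values]
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    if var == 0:
        return {"Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}
    sd = var**0.5
    skew = sum(((v - mu) / sd) ** 3 for v in x) / n
    kurt = sum(((v - mu) / sd) ** 4 for v in x) / n
    return {"Variance": var, "Skewness": skew, "Kurtosis": kurt}


def glcm_features_brute(counts):
    total = counts.sum()
    n = counts.shape[0]
    p = counts / total
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    mu = sum((i + 1) * px[i] for i in range(n))
    var = sum(((i + 1) - mu) ** 2 * px[i] for i in range(n))
    sd = var**0.5
    out = {
        "Energy": 0.0,
        "Contrast": 0.0,
        "Entropy": 0.0,
        "Homogeneity": 0.0,
        "Correlation": 0.0,
        "SumAverage": 0.0,
        "VarianceGLCM": 0.0,
        "Dissimilarity": 0.0,
    }
    for i in range(n):
        for j in range(n):
            pij = p[i, j]
            out["Energy"] += pij**2
            out["Contrast"] += pij * (i - j) ** 2
            if pij > 0:
                out["Entropy"] -= pij * np.log2(pij)
            out["Homogeneity"] += pij / (1 + abs(i - j))
            out["SumAverage"] += pij * ((i + 1) + (j + 1)) / 2
            out["VarianceGLCM"] += pij * ((i + 1) - mu) ** 2
            out["Dissimilarity"] += pij * abs(i - j)
            if sd > 0:
                out["Correlation"] += pij * ((i + 1) - mu) * ((j + 1) - mu) / (sd * sd)
    return out


def _rl_features_brute(counts, n_voxels, n_dirs):
    total = counts.sum()
    nl, nr = counts.shape
    p = counts / total
    out = dict.fromkeys(
        ["short", "long", "gln", "rln", "rp", "low", "high",
         "sl", "sh", "ll", "lh", "glv", "rlv"], 0.0
    )
    for i in range(nl):
        for j in range(nr):
            pij = p[i, j]
            I, J = i + 1.0, j + 1.0
            out["short"] += pij / J**2
            out["long"] += pij * J**2
            out["low"] += pij / I**2
            out["high"] += pij * I**2
            out["sl"] += pij / (I**2 * J**2)
            out["sh"] += pij * I**2 / J**2
            out["ll"] += pij * J**2 / I**2
            out["lh"] += pij * I**2 * J**2
    out["gln"] = sum(counts[i, :].sum() ** 2 for i in range(nl)) / total
    out["rln"] = sum(counts[:, j].sum() ** 2 for j in range(nr)) / total
    out["rp"] = total / (n_voxels * n_dirs)
    mu_i = sum(p[i, j] * (i + 1) for i in range(nl) for j in range(nr))
    mu_j = sum(p[i, j] * (j + 1) for i in range(nl) for j in range(nr))
    out["glv"] = sum(
        p[i, j] * ((i + 1) - mu_i) ** 2 for i in range(nl) for j in range(nr)
    )
    out["rlv"] = sum(
        p[i, j] * ((j + 1) - mu_j) ** 2 for i in range(nl) for j in range(nr)
    )
    return out


def glrlm_features_brute(counts, n_voxels):
    o = _rl_features_brute(counts, n_voxels, 13)
    keys = ["SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
            "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV"]
    vals = [o["short"], o["long"], o["gln"], o["rln"], o["rp"], o["low"],
            o["high"], o["sl"], o["sh"], o["ll"], o["lh"], o["glv"], o["rlv"]]
    return dict(zip(keys, vals))


def glszm_features_brute(counts, n_voxels):
    o = _rl_features_brute(counts, n_voxels, 1)
    keys = ["SZE", "LZE", "GLNz", "ZSN", "ZP", "LGZE", "HGZE",
            "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLVz", "ZSV"]
    vals = [o["short"], o["long"], o["gln"], o["rln"], o["rp"], o["low"],
            o["high"], o["sl"], o["sh"], o["ll"], o["lh"], o["glv"], o["rlv"]]
    return dict(zip(keys, vals))


def ngtdm_features_brute(s, p, n_valid, eps=1e-6):
    occ = [i for i in range(len(p)) if p[i] > 0]
    ng = len(occ)
    coarseness = 1.0 / (eps + sum(p[i] * s[i] for i in occ))
    contrast = 0.0
    if ng >= 2:
        pair = sum(
            p[i] * p[j] * ((i + 1) - (j + 1)) ** 2 for i in occ for j in occ
        )
        contrast = pair / (ng * (ng - 1)) * (sum(s[i] for i in occ) / n_valid)
    denom = sum(
        abs((i + 1) * p[i] - (j + 1) * p[j]) for i in occ for j in occ
    )
    num = sum(p[i] * s[i] for i in occ)
    busyness = num / denom if (ng >= 2 and denom > 0) else 0.0
    complexity = 0.0
    strength_num = 0.0
    if ng >= 2:
        complexity = sum(
            abs((i + 1) - (j + 1))
            * (p[i] * s[i] + p[j] * s[j])
            / (n_valid * (p[i] + p[j]))
            for i in occ
            for j in occ
        )
        strength_num = sum(
            (p[i] + p[j]) * ((i + 1) - (j + 1)) ** 2 for i in occ for j in occ
        )
    strength = strength_num / (eps + sum(s[i] for i in occ))
    return {
        "Coarseness": coarseness,
        "ContrastN": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def auc_brute(y, score):
    """Pairwise event-vs-nonevent comparison, ties counted half."""
    events = [s for s, yy in zip(score, y) if yy == 1]
    nons = [s for s, yy in zip(score, y) if yy == 0]
    total = 0.0
    for e in events:
        for c in nons:
            if e > c:
                total += 1.0
            elif e == c:
                total += 0.5
    return total / (len(events) * len(nons))
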