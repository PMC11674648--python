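"""Dosiomic texture features of a discretized 3D dose distribution.

Forty-two features are computed from a masked gray-level volume:

* 3 from the gray-level frequency histogram,
* 8 from the gray-level co-occurrence matrix (GLCM),
* 13 from the gray-level run-length matrix (GLRLM),
* 13 from the gray-level size zone matrix (GLSZM),
* 5 from the neighborhood gray-tone difference matrix (NGTDM).

GLCM and GLRLM aggregate the 13 unique 3D directions at voxel distance 1 by
summation into a single matrix before normalization; GLSZM zones and NGTDM
neighborhoods use 26-connectivity. Feature names are stable public
identifiers used in CSV headers and model JSON.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose import DiscretizedVolume

# The 13 unique displacement directions of a 26-neighborhood (one per
# antipodal pair), in array axis order.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

HISTOGRAM_FEATURES = ("Variance", "Skewness", "Kurtosis")
GLCM_FEATURES = (
    "Energy",
    "Contrast",
    "Entropy",
    "Homogeneity",
    "Correlation",
    "SumAverage",
    "VarianceGLCM",
    "Dissimilarity",
)
GLRLM_FEATURES = (
    "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
    "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV",
)
GLSZM_FEATURES = (
    "SZE", "LZE", "GLNz", "ZSN", "ZP", "LGZE", "HGZE",
    "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLVz", "ZSV",
)
NGTDM_FEATURES = ("Coarseness", "ContrastN", "Busyness", "Complexity", "Strength")

FEATURE_NAMES: tuple[str, ...] = (
    HISTOGRAM_FEATURES + GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES + NGTDM_FEATURES
)

FEATURE_FAMILIES = {
    "histogram": HISTOGRAM_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

_EPS = 1e-6  # Coarseness/Strength guard against division by zero


# ---------------------------------------------------------------------------
# matrix containers
# ---------------------------------------------------------------------------


@dataclass
class CooccurrenceMatrix:
    counts: np.ndarray  # (n_levels, n_levels), symmetric

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts


@dataclass
class RunLengthMatrix:
    counts: np.ndarray  # (n_levels, max_run)
    n_voxels: int
    n_directions: int = 13

    @property
    def total_runs(self) -> float:
        return float(self.counts.sum())


@dataclass
class SizeZoneMatrix:
    counts: np.ndarray  # (n_levels, max_zone)
    n_voxels: int

    @property
    def total_zones(self) -> float:
        return float(self.counts.sum())


@dataclass
class NeighborhoodGrayToneMatrix:
    s: np.ndarray  # per-level sums of |i - neighborhood mean|
    p: np.ndarray  # per-level fraction of valid voxels
    n_valid: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _crop(vol: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray]:
    """Levels and mask cropped to the mask bounding box (plus nothing else)."""
    mask = vol.mask.values
    nz = np.nonzero(mask)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)
    return vol.levels[sl], mask[sl]


def _shifted_slices(shape, d):
    """Slice pair (src at v, src at v+d) covering all in-bounds voxel pairs."""
    a, b = [], []
    for n, o in zip(shape, d):
        if o >= 0:
            a.append(slice(0, n - o))
            b.append(slice(o, n))
        else:
            a.append(slice(-o, n))
            b.append(slice(0, n + o))
    return tuple(a), tuple(b)


def _shift(arr: np.ndarray, d) -> np.ndarray:
    """out[v] = arr[v + d], padded with zeros/False outside."""
    out = np.zeros_like(arr)
    a, b = _shifted_slices(arr.shape, d)
    out[a] = arr[b]
    return out


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------


def compute_glcm(vol: DiscretizedVolume) -> CooccurrenceMatrix:
    """Co-occurrence counts over masked voxel pairs at distance 1.

    All 13 unique directions contribute, both orderings of each pair, so the
    matrix is symmetric by construction.
    """
    levels, mask = _crop(vol)
    n = vol.n_levels
    counts = np.zeros(n * n, dtype=np.float64)
    for d in DIRECTIONS_13:
        a, b = _shifted_slices(levels.shape, d)
        both = mask[a] & mask[b]
        if not both.any():
            continue
        i = levels[a][both].astype(np.int64) - 1
        j = levels[b][both].astype(np.int64) - 1
        counts += np.bincount(i * n + j, minlength=n * n)
        counts += np.bincount(j * n + i, minlength=n * n)
    return CooccurrenceMatrix(counts.reshape(n, n))


def compute_glrlm(vol: DiscretizedVolume) -> RunLengthMatrix:
    """Run-length counts summed over the 13 directions.

    A run is a maximal segment of collinear masked voxels sharing one gray
    level; mask gaps break runs.
    """
    levels, mask = _crop(vol)
    n = vol.n_levels
    max_run = int(sum(levels.shape))  # safe upper bound
    counts = np.zeros((n, max_run), dtype=np.float64)
    for d in DIRECTIONS_13:
        # cont[v]: v and v+d both masked with equal level
        nb_mask = _shift(mask, d)
        nb_lev = _shift(levels, d)
        cont = mask & nb_mask & (levels == nb_lev)
        # starts: masked voxels not continued from v-d
        back = tuple(-o for o in d)
        prev_cont = _shift(cont, back)
        starts = mask & ~prev_cont
        # consecutive continue-count from each voxel
        run_extra = np.zeros(levels.shape, dtype=np.int32)
        s = cont.copy()
        k = 1
        while s.any():
            run_extra += s
            s &= _shift(cont, tuple(k * o for o in d))
            k += 1
        lev = levels[starts].astype(np.int64) - 1
        rl = run_extra[starts].astype(np.int64)  # run length - 1
        counts += np.bincount(lev * max_run + rl, minlength=n * max_run).reshape(
            n, max_run
        )
    used = int(np.max(np.nonzero(counts.any(axis=0))[0])) + 1 if counts.any() else 1
    return RunLengthMatrix(counts[:, :used], n_voxels=int(mask.sum()))


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def compute_glszm(vol: DiscretizedVolume) -> SizeZoneMatrix:
    """Zone counts: 26-connected components of constant gray level."""
    levels, mask = _crop(vol)
    n = vol.n_levels
    sizes_by_level: dict[int, np.ndarray] = {}
    max_zone = 1
    for lev in np.unique(levels[mask]):
        lab, nlab = ndimage.label((levels == lev) & mask, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        sizes_by_level[int(lev)] = sizes
        max_zone = max(max_zone, int(sizes.max()))
    counts = np.zeros((n, max_zone), dtype=np.float64)
    for lev, sizes in sizes_by_level.items():
        counts[lev - 1] += np.bincount(sizes - 1, minlength=max_zone)
    return SizeZoneMatrix(counts, n_voxels=int(mask.sum()))


def compute_ngtdm(vol: DiscretizedVolume) -> NeighborhoodGrayToneMatrix:
    """Per-level sums of deviation from the 26-neighborhood mean gray tone."""
    levels, mask = _crop(vol)
    n = vol.n_levels
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    vals = np.where(mask, levels, 0).astype(np.float64)
    nsum = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
    ncnt = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mask & (ncnt > 0.5)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no masked voxel has a masked neighbor")
    abar = nsum[valid] / ncnt[valid]
    lv = levels[valid].astype(np.int64)
    s = np.bincount(lv - 1, weights=np.abs(lv - abar), minlength=n)
    p = np.bincount(lv - 1, minlength=n) / n_valid
    return NeighborhoodGrayToneMatrix(s=s, p=p, n_valid=n_valid)


# ---------------------------------------------------------------------------
# feature formulas
# ---------------------------------------------------------------------------


def histogram_features(vol: DiscretizedVolume) -> dict[str, float]:
    """Population variance, skewness and (non-excess) kurtosis of the masked
    gray levels. A constant volume has zero variance; its skewness and
    kurtosis are undefined and returned as 0 by convention."""
    x = vol.masked_levels.astype(np.float64)
    mu = x.mean()
    var = float(((x - mu) ** 2).mean())
    if var == 0:
        return {"Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}
    sd = np.sqrt(var)
    skew = float((((x - mu) / sd) ** 3).mean())
    kurt = float((((x - mu) / sd) ** 4).mean())
    return {"Variance": var, "Skewness": skew, "Kurtosis": kurt}


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    p = m.probabilities
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    var_x = float((((i - mu_x) ** 2) * px).sum())
    sd_x = np.sqrt(var_x)
    nz = p > 0
    energy = float((p**2).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    if sd_x == 0:
        correlation = 0.0  # single occupied level: undefined, by convention 0
    else:
        correlation = float((p * (ii - mu_x) * (jj - mu_x)).sum() / (sd_x * sd_x))
    sum_average = float((p * (ii + jj) / 2.0).sum())
    variance_glcm = float((p * (ii - mu_x) ** 2).sum())
    dissimilarity = float((p * np.abs(ii - jj)).sum())
    return {
        "Energy": energy,
        "Contrast": contrast,
        "Entropy": entropy,
        "Homogeneity": homogeneity,
        "Correlation": correlation,
        "SumAverage": sum_average,
        "VarianceGLCM": variance_glcm,
        "Dissimilarity": dissimilarity,
    }


def _rl_style_features(counts: np.ndarray, n_voxels: int, n_dirs: int | None):
    """Shared emphasis/nonuniformity/variance formulas for GLRLM (over run
    length j) and GLSZM (over zone size s)."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty matrix")
    n_lev, n_len = counts.shape
    i = np.arange(1, n_lev + 1, dtype=np.float64)[:, None]
    j = np.arange(1, n_len + 1, dtype=np.float64)[None, :]
    p = counts / total
    short = float((p / j**2).sum())
    long_ = float((p * j**2).sum())
    low = float((p / i**2).sum())
    high = float((p * i**2).sum())
    short_low = float((p / (i**2 * j**2)).sum())
    short_high = float((p * i**2 / j**2).sum())
    long_low = float((p * j**2 / i**2).sum())
    long_high = float((p * i**2 * j**2).sum())
    gln = float((counts.sum(axis=1) ** 2).sum() / total)
    rln = float((counts.sum(axis=0) ** 2).sum() / total)
    denom = n_voxels * (n_dirs if n_dirs else 1)
    rp = float(total / denom)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    glv = float((p * (i - mu_i) ** 2).sum())
    rlv = float((p * (j - mu_j) ** 2).sum())
    return short, long_, gln, rln, rp, low, high, short_low, short_high, long_low, long_high, glv, rlv


def glrlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """Run-length features of the direction-merged matrix.

    Run percentage (RP) averages the per-direction ratio N_r/n_voxels, which
    for the merged matrix equals N_r_total / (13 · n_voxels) and stays in
    (0, 1]."""
    vals = _rl_style_features(m.counts, m.n_voxels, m.n_directions)
    return dict(zip(GLRLM_FEATURES, vals))


def glszm_features(m: SizeZoneMatrix) -> dict[str, float]:
    vals = _rl_style_features(m.counts, m.n_voxels, None)
    return dict(zip(GLSZM_FEATURES, vals))


def ngtdm_features(m: NeighborhoodGrayToneMatrix) -> dict[str, float]:
    """Amadasun–King coarseness, contrast, busyness, complexity, strength.

    Sums run over occupied gray levels (p_i > 0); degenerate cases (a single
    occupied level, zero denominators) return 0 apart from Coarseness and
    Strength, whose denominators carry a 1e-6 guard."""
    occ = np.nonzero(m.p > 0)[0]
    i = (occ + 1).astype(np.float64)
    p = m.p[occ]
    s = m.s[occ]
    n = m.n_valid
    ng = len(occ)
    coarseness = 1.0 / (_EPS + float((p * s).sum()))
    if ng < 2:
        contrast = 0.0
    else:
        ii, jj = np.meshgrid(i, i, indexing="ij")
        pi, pj = np.meshgrid(p, p, indexing="ij")
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ng * (ng - 1)) * (s.sum() / n)
        )
    denom = 0.0
    if ng >= 2:
        denom = float(np.abs(i[:, None] * p[:, None] - i[None, :] * p[None, :]).sum())
    num = float((p * s).sum())
    busyness = num / denom if denom > 0 else 0.0
    if ng < 2:
        complexity = 0.0
        strength_num = 0.0
    else:
        ii, jj = np.meshgrid(i, i, indexing="ij")
        pi, pj = np.meshgrid(p, p, indexing="ij")
        si, sj = np.meshgrid(s, s, indexing="ij")
        complexity = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (n * (pi + pj))).sum()
        )
        strength_num = float(((pi + pj) * (ii - jj) ** 2).sum())
    strength = strength_num / (_EPS + float(s.sum()))
    return {
        "Coarseness": coarseness,
        "ContrastN": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def extract_all(vol: DiscretizedVolume) -> pd.Series:
    """All 42 dosiomic features of one discretized volume, in canonical order."""
    out: dict[str, float] = {}
    out.update(histogram_features(vol))
    out.update(glcm_features(compute_glcm(vol)))
    out.update(glrlm_features(compute_glrlm(vol)))
    out.update(glszm_features(compute_glszm(vol)))
    out.update(ngtdm_features(compute_ngtdm(vol)))
    return pd.Series([out[k] for k in FEATURE_NAMES], index=list(FEATURE_NAMES))


def extract_table(volumes, ids=None) -> pd.DataFrame:
    """Feature table (patients × 42) for an iterable of discretized volumes."""
    rows = [extract_all(v) for v in volumes]
    df = pd.DataFrame(rows)
    if ids is not None:
        df.index = list(ids)
    return df


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationBounds:
    """Per-feature (min, max) learned on a reference cohort."""

    minima: pd.Series
    maxima: pd.Series

    def __post_init__(self) -> None:
        if (self.maxima < self.minima).any():
            raise ValueError("max < min in normalization bounds")


def fit_normalization(table: pd.DataFrame) -> NormalizationBounds:
    if table.empty:
        raise ValueError("empty feature table")
    return NormalizationBounds(table.min(axis=0), table.max(axis=0))


def apply_normalization(table: pd.DataFrame, bounds: NormalizationBounds) -> pd.DataFrame:
    """Min-max map ``x -> (x - min) / (max - min)`` with training bounds.

    Constant reference features map to 0. Values from another cohort may fall
    outside [0, 1]; they are deliberately not clipped."""
    span = bounds.maxima - bounds.minima
    out = table.sub(bounds.minima, axis=1).div(span.replace(0.0, np.inf), axis=1)
    return out
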