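"""High-throughput radiomics features of 2-D parametric feature maps.

Per map, 350 features are extracted in a frozen canonical order:

* 16 first-order histogram statistics,
* 54 texture features from four matrix families — gray-level co-occurrence
  (GLCM, 23), gray-level run-length (GLRLM, 13), gray-level size-zone
  (GLSZM, 13) and neighborhood gray-tone difference (NGTDM, 5),
* the same 70 features recomputed on each of the four sub-images of a
  one-level 2-D discrete wavelet transform (LL, LH, HL, HH), i.e. 280
  wavelet features.

Conventions (all configurable where noted):

* Gray levels: 32 equal-width bins between the (sub-)image minimum and
  maximum, levels numbered 1..32; every sub-image is re-quantized.
* GLCM: distance 1, four directions (0, 45, 90, 135 degrees), symmetric,
  direction-averaged matrix, normalized to sum 1.
* GLRLM: four directions, the 13 descriptors averaged across directions.
* GLSZM: zones are 8-connected constant-level components.
* NGTDM: 8-neighborhood averages with edge-aware neighbor counts.
* Wavelet: Daubechies-4, symmetric signal extension.
* Entropies use log base 2; moments use population (divide-by-n) forms.

Two slots in the inventory are deliberate duplicates kept to preserve the
feature-count contract: histogram items 13-16 repeat kurtosis/mean/
variance/skewness on z-score-standardized intensities (mean and variance
are then the constants 0 and 1, and kurtosis/skewness are affine-invariant
so they equal the raw versions), and the GLCM block carries the maximal
correlation coefficient twice. Downstream selection is expected to drop
constant or duplicated columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from skimage.feature import graycomatrix

from .errors import InvalidMapError, ROITooSmallError
from .feature_maps import FeatureMap

__all__ = [
    "QuantizedImage",
    "HIST_FEATURE_NAMES",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "GLSZM_FEATURE_NAMES",
    "NGTDM_FEATURE_NAMES",
    "BASE_FEATURE_NAMES",
    "WAVELET_BANDS",
    "radiomics_feature_names",
    "quantize",
    "histogram_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "wavelet_features",
    "base_features",
    "map_features",
]

HIST_FEATURE_NAMES = (
    "hist_energy",
    "hist_entropy",
    "hist_kurtosis",
    "hist_mean",
    "hist_mad",
    "hist_median",
    "hist_range",
    "hist_uniformity",
    "hist_variance",
    "hist_rms",
    "hist_skewness",
    "hist_std",
    "hist_std_kurtosis",
    "hist_std_mean",
    "hist_std_variance",
    "hist_std_skewness",
)

GLCM_FEATURE_NAMES = (
    "glcm_energy",
    "glcm_entropy",
    "glcm_dissimilarity",
    "glcm_contrast",
    "glcm_inverse_difference",
    "glcm_correlation",
    "glcm_homogeneity",
    "glcm_autocorrelation",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_max_probability",
    "glcm_sum_of_squares",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_mcc",
    "glcm_mcc_repeat",
    "glcm_idn",
    "glcm_idmn",
)

GLRLM_FEATURE_NAMES = (
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_rln",
    "glrlm_rp",
    "glrlm_lglre",
    "glrlm_hglre",
    "glrlm_srlgle",
    "glrlm_srhgle",
    "glrlm_lrlgle",
    "glrlm_lrhgle",
    "glrlm_glv",
    "glrlm_rlv",
)

GLSZM_FEATURE_NAMES = (
    "glszm_sze",
    "glszm_lze",
    "glszm_gln",
    "glszm_zsn",
    "glszm_zp",
    "glszm_lglze",
    "glszm_hglze",
    "glszm_szlgle",
    "glszm_szhgle",
    "glszm_lzlgle",
    "glszm_lzhgle",
    "glszm_glv",
    "glszm_zsv",
)

NGTDM_FEATURE_NAMES = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
)

BASE_FEATURE_NAMES: tuple[str, ...] = (
    HIST_FEATURE_NAMES
    + GLCM_FEATURE_NAMES
    + GLRLM_FEATURE_NAMES
    + GLSZM_FEATURE_NAMES
    + NGTDM_FEATURE_NAMES
)

WAVELET_BANDS = ("LL", "LH", "HL", "HH")


def radiomics_feature_names() -> list[str]:
    """The frozen 350-name canonical order: base block then 4 wavelet blocks."""
    names = [f"orig_{n}" for n in BASE_FEATURE_NAMES]
    for band in WAVELET_BANDS:
        names.extend(f"wl_{band}_{n}" for n in BASE_FEATURE_NAMES)
    return names


@dataclass
class QuantizedImage:
    """An integer image with levels in [1, n_levels]."""

    levels: np.ndarray
    n_levels: int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not np.issubdtype(self.levels.dtype, np.integer):
            raise ValueError("levels must be integers")
        if self.levels.min() < 1 or self.levels.max() > self.n_levels:
            raise ValueError("levels out of [1, n_levels]")


def quantize(map_values: np.ndarray, n_levels: int = 32, provenance: str = "") -> QuantizedImage:
    """Equal-width quantization of a 2-D map into levels 1..n_levels.

    The maximum value maps to level ``n_levels``; a constant map maps
    entirely to level 1.
    """
    x = np.asarray(map_values, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise InvalidMapError("map contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        levels = np.ones(x.shape, dtype=np.int64)
    else:
        levels = np.floor((x - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
        np.clip(levels, 1, n_levels, out=levels)
    return QuantizedImage(levels=levels, n_levels=n_levels, provenance=provenance)


# ---------------------------------------------------------------------------
# first-order histogram features
# ---------------------------------------------------------------------------

def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def histogram_features(map_values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """The 16 first-order statistics of raw map intensities.

    Items 1-12 are computed on the raw intensities (entropy and uniformity
    from the 32-bin normalized histogram); items 13-16 repeat kurtosis,
    mean, variance and skewness on z-score-standardized intensities. On a
    zero-variance map the standardized block is set to 0 with a warning.
    """
    x = np.asarray(map_values, dtype=np.float64).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 pixels")
    if not np.all(np.isfinite(x)):
        raise InvalidMapError("map contains non-finite values")
    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    std = np.sqrt(var)
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts / counts.sum()
    out: dict[str, float] = {
        "hist_energy": float(np.sum(x**2)),
        "hist_entropy": _entropy2(p),
        "hist_mean": float(mu),
        "hist_mad": float(np.mean(np.abs(x - mu))),
        "hist_median": float(np.median(x)),
        "hist_range": float(x.max() - x.min()),
        "hist_uniformity": float(np.sum(p**2)),
        "hist_variance": float(var),
        "hist_rms": float(np.sqrt(np.mean(x**2))),
        "hist_std": float(std),
    }
    if std > 0:
        skew = float(((x - mu) ** 3).mean() / std**3)
        kurt = float(((x - mu) ** 4).mean() / std**4)
        out["hist_skewness"] = skew
        out["hist_kurtosis"] = kurt
        # z-scoring is affine, so kurtosis/skewness are unchanged and the
        # standardized mean/variance are identically 0/1; the block exists
        # to keep the 16-feature inventory intact.
        out["hist_std_kurtosis"] = kurt
        out["hist_std_mean"] = 0.0
        out["hist_std_variance"] = 1.0
        out["hist_std_skewness"] = skew
    else:
        warnings.warn("zero-variance map: standardized histogram features set to 0", stacklevel=2)
        for key in ("hist_skewness", "hist_kurtosis", "hist_std_kurtosis",
                    "hist_std_mean", "hist_std_variance", "hist_std_skewness"):
            out[key] = 0.0
    return {name: out[name] for name in HIST_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(q: QuantizedImage) -> np.ndarray:
    """Symmetric, direction-averaged, normalized co-occurrence matrix."""
    img = (q.levels - 1).astype(np.uint8 if q.n_levels <= 256 else np.uint16)
    mats = graycomatrix(
        img,
        distances=[1],
        angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=q.n_levels,
        symmetric=True,
        normed=False,
    )[:, :, 0, :].astype(np.float64)
    mat = mats.sum(axis=2)
    total = mat.sum()
    if total == 0:
        raise ValueError("image too small for any co-occurring pair")
    return mat / total


def glcm_features(q: QuantizedImage) -> dict[str, float]:
    """The 23 Haralick-family descriptors of the direction-averaged GLCM.

    On a single-level image the correlation-type descriptors (correlation,
    the two information measures and the maximal correlation coefficient)
    are set to 0 with a warning.
    """
    if q.levels.shape[0] < 2 or q.levels.shape[1] < 2:
        raise ValueError("need at least a 2x2 image")
    p = _glcm_matrix(q)
    L = q.n_levels
    i = np.arange(1, L + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    var_y = float(np.sum((i - mu_y) ** 2 * py))

    diff = np.abs(ii - jj)
    # p_{x+y}(k), k = 2..2L ; p_{x-y}(k), k = 0..L-1
    ksum = np.arange(2, 2 * L + 1, dtype=np.float64)
    p_sum = np.zeros(2 * L - 1)
    kdiff = np.arange(0, L, dtype=np.float64)
    p_diff = np.zeros(L)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    np.add.at(p_diff, diff.astype(int).ravel(), p.ravel())

    out: dict[str, float] = {}
    out["glcm_energy"] = float(np.sum(p**2))
    out["glcm_entropy"] = _entropy2(p.ravel())
    out["glcm_dissimilarity"] = float(np.sum(diff * p))
    out["glcm_contrast"] = float(np.sum((ii - jj) ** 2 * p))
    out["glcm_inverse_difference"] = float(np.sum(p / (1.0 + diff)))
    out["glcm_homogeneity"] = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    out["glcm_autocorrelation"] = float(np.sum(ii * jj * p))
    out["glcm_cluster_shade"] = float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p))
    out["glcm_cluster_prominence"] = float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p))
    out["glcm_max_probability"] = float(p.max())
    out["glcm_sum_of_squares"] = float(np.sum((ii - mu_x) ** 2 * p))
    sum_avg = float(np.sum(ksum * p_sum))
    out["glcm_sum_average"] = sum_avg
    out["glcm_sum_variance"] = float(np.sum((ksum - sum_avg) ** 2 * p_sum))
    out["glcm_sum_entropy"] = _entropy2(p_sum)
    mu_d = float(np.sum(kdiff * p_diff))
    out["glcm_difference_variance"] = float(np.sum((kdiff - mu_d) ** 2 * p_diff))
    out["glcm_difference_entropy"] = _entropy2(p_diff)
    out["glcm_idn"] = float(np.sum(p / (1.0 + diff / L)))
    out["glcm_idmn"] = float(np.sum(p / (1.0 + (ii - jj) ** 2 / L**2)))

    degenerate = var_x <= 0 or var_y <= 0
    if degenerate:
        warnings.warn("single-level image: correlation-type GLCM features set to 0", stacklevel=2)
        corr = imc1 = imc2 = mcc = 0.0
    else:
        corr = float((np.sum(ii * jj * p) - mu_x * mu_y) / np.sqrt(var_x * var_y))
        hxy = out["glcm_entropy"]
        pxpy = np.outer(px, py)
        mask = pxpy > 0
        log_pxpy = np.zeros_like(pxpy)
        np.log2(pxpy, where=mask, out=log_pxpy)
        hxy1 = float(-np.sum(p[mask] * log_pxpy[mask]))
        hxy2 = float(-np.sum(pxpy[mask] * log_pxpy[mask]))
        hx = _entropy2(px)
        hy = _entropy2(py)
        denom = max(hx, hy)
        imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
        keep = px > 0
        pk = p[np.ix_(keep, keep)]
        pxk = px[keep]
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)); px == py (symmetric p)
        Q = (pk / pxk[:, None]) @ (pk / pxk[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(0.0, eig[1]))) if eig.size > 1 else 0.0
    out["glcm_correlation"] = corr
    out["glcm_imc1"] = imc1
    out["glcm_imc2"] = imc2
    out["glcm_mcc"] = mcc
    out["glcm_mcc_repeat"] = mcc
    return {name: out[name] for name in GLCM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

_DIRECTIONS = ("horizontal", "vertical", "diagonal", "antidiagonal")


def _lines(img: np.ndarray, direction: str) -> list[np.ndarray]:
    h, w = img.shape
    if direction == "horizontal":
        return [img[r, :] for r in range(h)]
    if direction == "vertical":
        return [img[:, c] for c in range(w)]
    if direction == "diagonal":
        return [np.diagonal(img, offset=k) for k in range(-h + 1, w)]
    if direction == "antidiagonal":
        flipped = np.fliplr(img)
        return [np.diagonal(flipped, offset=k) for k in range(-h + 1, w)]
    raise ValueError(direction)


def _run_length_matrix(img: np.ndarray, n_levels: int, direction: str) -> np.ndarray:
    max_run = max(img.shape)
    mat = np.zeros((n_levels, max_run), dtype=np.float64)
    for line in _lines(img, direction):
        if line.size == 0:
            continue
        boundaries = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [line.size]))
        for s, e in zip(starts, ends):
            mat[line[s] - 1, e - s - 1] += 1
    return mat


def _rlm_descriptors(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = mat.sum()
    levels = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    runs = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    li, rj = np.meshgrid(levels, runs, indexing="ij")
    p_level = mat.sum(axis=1)
    p_run = mat.sum(axis=0)
    mu_l = float(np.sum(li * mat) / nr)
    mu_r = float(np.sum(rj * mat) / nr)
    return {
        "sre": float(np.sum(mat / rj**2) / nr),
        "lre": float(np.sum(mat * rj**2) / nr),
        "gln": float(np.sum(p_level**2) / nr),
        "rln": float(np.sum(p_run**2) / nr),
        "rp": float(nr / n_pixels),
        "lglre": float(np.sum(mat / li**2) / nr),
        "hglre": float(np.sum(mat * li**2) / nr),
        "srlgle": float(np.sum(mat / (li**2 * rj**2)) / nr),
        "srhgle": float(np.sum(mat * li**2 / rj**2) / nr),
        "lrlgle": float(np.sum(mat * rj**2 / li**2) / nr),
        "lrhgle": float(np.sum(mat * li**2 * rj**2) / nr),
        "glv": float(np.sum((li - mu_l) ** 2 * mat) / nr),
        "rlv": float(np.sum((rj - mu_r) ** 2 * mat) / nr),
    }


def glrlm_features(q: QuantizedImage) -> dict[str, float]:
    """13 run-length descriptors, averaged over the four 2-D directions."""
    img = q.levels
    if img.size < 2:
        raise ValueError("need at least 2 pixels")
    acc: dict[str, float] = {}
    for direction in _DIRECTIONS:
        mat = _run_length_matrix(img, q.n_levels, direction)
        desc = _rlm_descriptors(mat, img.size)
        for k, v in desc.items():
            acc[k] = acc.get(k, 0.0) + v / len(_DIRECTIONS)
    return {f"glrlm_{k}": acc[k] for k in
            ("sre", "lre", "gln", "rln", "rp", "lglre", "hglre",
             "srlgle", "srhgle", "lrlgle", "lrhgle", "glv", "rlv")}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=int)


def _zone_matrix(q: QuantizedImage) -> np.ndarray:
    img = q.levels
    max_zone = img.size
    mat = np.zeros((q.n_levels, max_zone), dtype=np.float64)
    for level in np.unique(img):
        labeled, n = ndimage.label(img == level, structure=_EIGHT)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for size in sizes:
            mat[level - 1, size - 1] += 1
    return mat


def glszm_features(q: QuantizedImage) -> dict[str, float]:
    """13 size-zone descriptors from 8-connected constant-level zones."""
    img = q.levels
    if img.size < 2:
        raise ValueError("need at least 2 pixels")
    mat = _zone_matrix(q)
    desc = _rlm_descriptors(mat, img.size)  # same algebra, zones for runs
    rename = {
        "sre": "sze", "lre": "lze", "gln": "gln", "rln": "zsn", "rp": "zp",
        "lglre": "lglze", "hglre": "hglze", "srlgle": "szlgle",
        "srhgle": "szhgle", "lrlgle": "lzlgle", "lrhgle": "lzhgle",
        "glv": "glv", "rlv": "zsv",
    }
    out = {f"glszm_{rename[k]}": v for k, v in desc.items()}
    return {name: out[name] for name in GLSZM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(q: QuantizedImage) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength
    (Amadasun-King) from the neighborhood gray-tone difference matrix.
    """
    img = q.levels.astype(np.float64)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("need at least a 3x3 image")
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nbr_sum = ndimage.convolve(img, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(np.ones_like(img), kernel, mode="constant", cval=0.0)
    a_bar = nbr_sum / nbr_cnt
    n_total = img.size
    levels = np.arange(1, q.n_levels + 1, dtype=np.float64)
    s = np.zeros(q.n_levels)
    n_i = np.zeros(q.n_levels)
    for idx, lvl in enumerate(levels):
        mask = q.levels == int(lvl)
        n_i[idx] = mask.sum()
        if n_i[idx]:
            s[idx] = np.abs(lvl - a_bar[mask]).sum()
    p_i = n_i / n_total
    present = p_i > 0
    n_gp = int(present.sum())

    ps = float(np.sum(p_i * s))
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if n_gp > 1:
        pi_m, pj_m = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        li_m, lj_m = np.meshgrid(levels[present], levels[present], indexing="ij")
        contrast = (
            float(np.sum(pi_m * pj_m * (li_m - lj_m) ** 2))
            / (n_gp * (n_gp - 1))
            * float(s.sum())
            / n_total
        )
        denom_busy = float(np.sum(np.abs(li_m * pi_m - lj_m * pj_m)))
        num_busy = ps
        busyness = num_busy / denom_busy if denom_busy > 0 else 0.0
        si_m, sj_m = np.meshgrid(s[present], s[present], indexing="ij")
        complexity = float(
            np.sum(np.abs(li_m - lj_m) * (pi_m * si_m + pj_m * sj_m) / (pi_m + pj_m))
        ) / n_total
        s_total = float(s.sum())
        strength = (
            float(np.sum((pi_m + pj_m) * (li_m - lj_m) ** 2)) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def base_features(map_values: np.ndarray, n_levels: int = 32, provenance: str = "") -> dict[str, float]:
    """The 70-feature base block (histogram + four texture families)."""
    q = quantize(map_values, n_levels=n_levels, provenance=provenance)
    out: dict[str, float] = {}
    out.update(histogram_features(map_values))
    out.update(glcm_features(q))
    out.update(glrlm_features(q))
    out.update(glszm_features(q))
    out.update(ngtdm_features(q))
    return out


def wavelet_features(
    map_values: np.ndarray,
    n_levels: int = 32,
    wavelet: str = "db4",
) -> dict[str, float]:
    """The 280 wavelet features: the base block on each DWT sub-image.

    A one-level 2-D discrete wavelet transform (Daubechies-4, symmetric
    padding) yields LL/LH/HL/HH coefficient sub-images; each is
    re-quantized and the full 70-feature base block is computed on it.
    """
    x = np.asarray(map_values, dtype=np.float64)
    if x.shape[0] < 8 or x.shape[1] < 8:
        raise ROITooSmallError(f"map {x.shape} too small for the wavelet transform (need >= 8x8)")
    cA, (cH, cV, cD) = pywt.dwt2(x, wavelet, mode="symmetric")
    subimages = {"LL": cA, "LH": cH, "HL": cV, "HH": cD}
    out: dict[str, float] = {}
    for band in WAVELET_BANDS:
        feats = base_features(subimages[band], n_levels=n_levels, provenance=f"wl_{band}")
        out.update({f"wl_{band}_{k}": v for k, v in feats.items()})
    return out


def map_features(fmap: FeatureMap | np.ndarray, n_levels: int = 32) -> pd.Series:
    """The full 350-feature radiomics vector of one feature map."""
    values = fmap.values if isinstance(fmap, FeatureMap) else np.asarray(fmap, dtype=np.float64)
    out: dict[str, float] = {}
    out.update({f"orig_{k}": v for k, v in base_features(values, n_levels=n_levels).items()})
    out.update(wavelet_features(values, n_levels=n_levels))
    vec = pd.Series(out, dtype=float).reindex(radiomics_feature_names())
    assert not vec.isna().any()
    return vec
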