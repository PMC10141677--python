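"""The 307-feature texture descriptor of a normalized region.

Eight families, with fixed cardinalities summing to 307:

========================  =====  ============================================
family                    count  parameters
========================  =====  ============================================
histogram                     9  mean, variance, skewness, kurtosis,
                                 percentiles 1/10/50/90/99
co-occurrence (GLCM)        220  11 Haralick-type statistics x 4 directions
                                 x distances 1..5
run-length (RLM)             20  5 Galloway statistics x 4 directions
gradient                      5  moments + nonzero fraction of a 3x3
                                 high-pass magnitude map
autoregressive (AR)           5  4 causal-neighbor weights + residual scale
Haar wavelet                 16  subband energy, 4 scales x {LL, LH, HL, HH}
Gabor                        24  mean response magnitude, 4 orientations
                                 x envelope sizes {4, 6, 8, 12, 16, 24}
HOG                           8  magnitude-weighted 8-bin orientation
                                 histogram
========================  =====  ============================================

Directions are the spatial offsets (0,d), (d,d), (d,0), (d,-d) in (row, col)
coordinates, labelled 0°, 45°, 90° and 135°.  Gray levels are uniformly
re-quantized to ``n_gray_levels`` bins of ``[0, L]`` before the co-occurrence
and run-length matrices are built.  The natural logarithm is used in all
entropies with the convention 0·log 0 = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pywt
from scipy import ndimage, signal

from .io import Region
from .normalization import NormalizedRegion, normalize_3sigma


class InsufficientExtentError(ValueError):
    """Region too small for the requested operator."""


# direction label (degrees) -> unit offset (d_row, d_col)
DIRECTION_OFFSETS: Dict[int, Tuple[int, int]] = {
    0: (0, 1),
    45: (1, 1),
    90: (1, 0),
    135: (1, -1),
}

GLCM_STAT_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
)

RLM_STAT_NAMES = ("sre", "lre", "gln", "rln", "run_percentage")

HIST_NAMES = (
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_p01",
    "hist_p10",
    "hist_p50",
    "hist_p90",
    "hist_p99",
)

GRADIENT_NAMES = (
    "grad_mean",
    "grad_variance",
    "grad_skewness",
    "grad_kurtosis",
    "grad_nonzero_fraction",
)

AR_NAMES = ("ar_theta1", "ar_theta2", "ar_theta3", "ar_theta4", "ar_sigma")

HAAR_SUBBANDS = ("ll", "lh", "hl", "hh")


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the texture descriptor.

    The defaults reproduce the 307-entry schema: G = 64 quantized gray
    levels for the matrix families, co-occurrence distances 1-5 pixels, the
    four standard directions, Gabor envelope sizes 4-24 pixels, an 8-bin
    orientation histogram and a 4-scale Haar decomposition.
    """

    n_gray_levels: int = 64
    distances: Tuple[int, ...] = (1, 2, 3, 4, 5)
    angles: Tuple[int, ...] = (0, 45, 90, 135)
    gabor_sizes: Tuple[int, ...] = (4, 6, 8, 12, 16, 24)
    hog_bins: int = 8
    haar_levels: int = 4
    normalize: bool = True
    ceiling: Optional[int] = None  # clamp ceiling for the ±3σ normalization


DEFAULT_CONFIG = FeatureConfig()


def feature_names(config: FeatureConfig = DEFAULT_CONFIG) -> List[str]:
    """The fixed, ordered schema of the descriptor."""
    names: List[str] = list(HIST_NAMES)
    for a in config.angles:
        for d in config.distances:
            names += [f"glcm_a{a}_d{d}_{s}" for s in GLCM_STAT_NAMES]
    for a in config.angles:
        names += [f"rlm_a{a}_{s}" for s in RLM_STAT_NAMES]
    names += list(GRADIENT_NAMES)
    names += list(AR_NAMES)
    for scale in range(1, config.haar_levels + 1):
        names += [f"haar_s{scale}_{b}" for b in HAAR_SUBBANDS]
    for a in config.angles:
        names += [f"gabor_a{a}_s{s}" for s in config.gabor_sizes]
    names += [f"hog_bin{b}" for b in range(config.hog_bins)]
    return names


def family_of(name: str) -> str:
    return name.split("_", 1)[0]


# ---------------------------------------------------------------------------
# quantization


def quantize(pixels: np.ndarray, gray_max: int, levels: int) -> np.ndarray:
    """Uniformly re-bin intensities in [0, gray_max] to {0, ..., levels-1}."""
    q = (np.asarray(pixels, dtype=np.int64) * levels) // (gray_max + 1)
    return np.clip(q, 0, levels - 1)


# ---------------------------------------------------------------------------
# histogram family


def _dist_moments(values: np.ndarray) -> Tuple[float, float, float, float]:
    """Mean, population variance, skewness and excess kurtosis.

    Skewness and kurtosis are defined as 0 for a degenerate (zero-variance)
    distribution.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    mean = float(v.mean())
    var = float(v.var())
    if var == 0.0:
        return mean, 0.0, 0.0, 0.0
    centred = v - mean
    sd = math.sqrt(var)
    skew = float((centred**3).mean() / sd**3)
    kurt = float((centred**4).mean() / sd**4 - 3.0)
    return mean, var, skew, kurt


def histogram_features(region: NormalizedRegion) -> Dict[str, float]:
    """First-order statistics of the intensity distribution."""
    v = region.pixels.astype(np.float64).ravel()
    mean, var, skew, kurt = _dist_moments(v)
    p01, p10, p50, p90, p99 = np.percentile(v, [1, 10, 50, 90, 99])
    return dict(
        zip(
            HIST_NAMES,
            [mean, var, skew, kurt, float(p01), float(p10), float(p50), float(p90), float(p99)],
        )
    )


# ---------------------------------------------------------------------------
# co-occurrence family


def cooccurrence_matrix(
    quantized: np.ndarray, offset: Tuple[int, int], n_levels: int
) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix for one offset."""
    q = np.asarray(quantized, dtype=np.int64)
    dr, dc = offset
    rows, cols = q.shape
    r0, r1 = max(0, -dr), rows - max(0, dr)
    c0, c1 = max(0, -dc), cols - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise InsufficientExtentError(
            f"region {rows}x{cols} has no pixel pairs at offset {offset}"
        )
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    mat = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(mat, (a, b), 1.0)
    mat = mat + mat.T
    return mat / mat.sum()


def glcm(
    region: NormalizedRegion, angle: int, distance: int, levels: int = 64
) -> np.ndarray:
    """Co-occurrence matrix of a normalized region for one (angle, distance)."""
    dr, dc = DIRECTION_OFFSETS[angle]
    q = quantize(region.pixels, region.gray_max, levels)
    return cooccurrence_matrix(q, (dr * distance, dc * distance), levels)


def glcm_features(matrix: np.ndarray) -> Dict[str, float]:
    """The 11 Haralick-type statistics of one co-occurrence matrix.

    Means/variances in `correlation` and `sum_of_squares` are taken over the
    marginal gray-level distribution; a degenerate marginal (σ = 0) yields
    correlation 0.
    """
    p = np.asarray(matrix, dtype=np.float64)
    g = p.shape[0]
    idx = np.arange(g, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((idx * px).sum())
    var_x = float(((idx - mu_x) ** 2 * px).sum())
    # symmetric matrix: x and y marginals coincide
    sd_x = math.sqrt(var_x)

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_x) / (sd_x * sd_x))
    else:
        correlation = 0.0
    sum_of_squares = var_x
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (ii + jj).astype(np.int64).ravel(), p.ravel())
    k_sum = np.arange(2 * g - 1, dtype=np.float64)
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = float(-(p_sum[p_sum > 0] * np.log(p_sum[p_sum > 0])).sum())

    entropy = float(-(p[p > 0] * np.log(p[p > 0])).sum())

    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(ii - jj).astype(np.int64).ravel(), p.ravel())
    k_diff = np.arange(g, dtype=np.float64)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = float(-(p_diff[p_diff > 0] * np.log(p_diff[p_diff > 0])).sum())

    return dict(
        zip(
            GLCM_STAT_NAMES,
            [
                asm,
                contrast,
                correlation,
                sum_of_squares,
                idm,
                sum_average,
                sum_variance,
                sum_entropy,
                entropy,
                difference_variance,
                difference_entropy,
            ],
        )
    )


# ---------------------------------------------------------------------------
# run-length family


def _direction_lines(q: np.ndarray, angle: int) -> List[np.ndarray]:
    """Decompose the grid into the 1-D lines along one direction."""
    rows, cols = q.shape
    if angle == 0:
        return [q[r, :] for r in range(rows)]
    if angle == 90:
        return [q[:, c] for c in range(cols)]
    if angle == 45:
        # down-right diagonals
        return [np.diagonal(q, offset=k) for k in range(-(rows - 1), cols)]
    if angle == 135:
        flipped = np.fliplr(q)
        return [np.diagonal(flipped, offset=k) for k in range(-(rows - 1), cols)]
    raise ValueError(f"unknown direction {angle}")


def run_length_matrix(
    quantized: np.ndarray, angle: int, n_levels: int
) -> np.ndarray:
    """Counts of maximal equal-level runs, indexed (gray level, run length - 1)."""
    q = np.asarray(quantized, dtype=np.int64)
    max_len = max(q.shape)
    mat = np.zeros((n_levels, max_len), dtype=np.int64)
    for line in _direction_lines(q, angle):
        line = np.asarray(line)
        if line.size == 0:
            continue
        boundaries = np.flatnonzero(np.diff(line))
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries, [line.size - 1]))
        lengths = ends - starts + 1
        np.add.at(mat, (line[starts], lengths - 1), 1)
    return mat


def rlm_features(
    region: NormalizedRegion, angle: int, levels: int = 64
) -> Dict[str, float]:
    """The five Galloway run-length statistics for one direction.

    Short/long-run emphasis, gray-level and run-length nonuniformity, and
    run percentage (runs per pixel).
    """
    q = quantize(region.pixels, region.gray_max, levels)
    mat = run_length_matrix(q, angle, levels).astype(np.float64)
    n_runs = mat.sum()
    lengths = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    by_length = mat.sum(axis=0)
    by_level = mat.sum(axis=1)
    sre = float((by_length / lengths**2).sum() / n_runs)
    lre = float((by_length * lengths**2).sum() / n_runs)
    gln = float((by_level**2).sum() / n_runs)
    rln = float((by_length**2).sum() / n_runs)
    run_percentage = float(n_runs / q.size)
    return dict(zip(RLM_STAT_NAMES, [sre, lre, gln, rln, run_percentage]))


# ---------------------------------------------------------------------------
# gradient family

_HIGHPASS_3X3 = np.array([[0, -1, 0], [-1, 4, -1], [0, -1, 0]], dtype=np.float64)


def gradient_features(region: NormalizedRegion) -> Dict[str, float]:
    """Moments and nonzero fraction of a 3x3 high-pass magnitude map.

    The map is the absolute response of a 3x3 Laplacian-type mask evaluated
    on the interior of the region (boundary pixels are excluded so no padding
    convention leaks into the statistics).
    """
    p = region.pixels.astype(np.float64)
    if p.shape[0] < 3 or p.shape[1] < 3:
        raise InsufficientExtentError("gradient features need at least a 3x3 region")
    response = ndimage.convolve(p, _HIGHPASS_3X3, mode="nearest")[1:-1, 1:-1]
    mag = np.abs(response)
    mean, var, skew, kurt = _dist_moments(mag)
    nonzero = float((mag > 0).mean())
    return dict(zip(GRADIENT_NAMES, [mean, var, skew, kurt, nonzero]))


# ---------------------------------------------------------------------------
# autoregressive family


def ar_features(region: NormalizedRegion) -> Dict[str, float]:
    """First-order causal autoregressive model fitted by least squares.

    Each interior pixel is predicted as a weighted sum of its left,
    upper-left, upper and upper-right neighbors; the features are the four
    weights θ1..θ4 and the population standard deviation of the residuals.
    A rank-deficient design (e.g. a constant region) takes the minimum-norm
    solution.
    """
    p = region.pixels.astype(np.float64)
    if p.shape[0] < 3 or p.shape[1] < 3:
        raise InsufficientExtentError("AR features need at least a 3x3 region")
    target = p[1:, 1:-1].ravel()
    design = np.column_stack(
        [
            p[1:, :-2].ravel(),  # left
            p[:-1, :-2].ravel(),  # upper-left
            p[:-1, 1:-1].ravel(),  # upper
            p[:-1, 2:].ravel(),  # upper-right
        ]
    )
    theta, *_ = np.linalg.lstsq(design, target, rcond=None)
    residuals = target - design @ theta
    sigma = float(np.sqrt((residuals**2).mean()))
    return dict(zip(AR_NAMES, [*map(float, theta), sigma]))


# ---------------------------------------------------------------------------
# Haar wavelet family


def haar_features(region: NormalizedRegion, n_levels: int = 4) -> Dict[str, float]:
    """Subband energies of an n-level 2-D Haar transform.

    The region is cropped (top-left anchored) to the largest size whose both
    dimensions are multiples of 2**n_levels, so the periodized transform is
    exactly orthogonal and subband energies obey Parseval.  The feature is
    the mean squared coefficient of each subband at each scale.
    """
    p = region.pixels.astype(np.float64)
    unit = 2**n_levels
    rows = (p.shape[0] // unit) * unit
    cols = (p.shape[1] // unit) * unit
    if rows == 0 or cols == 0:
        raise InsufficientExtentError(
            f"Haar features need at least {unit}x{unit} pixels for {n_levels} scales"
        )
    current = p[:rows, :cols]
    out: Dict[str, float] = {}
    for scale in range(1, n_levels + 1):
        ll, (lh, hl, hh) = pywt.dwt2(current, "haar", mode="periodization")
        for name, band in zip(HAAR_SUBBANDS, (ll, lh, hl, hh)):
            out[f"haar_s{scale}_{name}"] = float((band**2).mean())
        current = ll
    return out


# ---------------------------------------------------------------------------
# Gabor family


def _gabor_kernel(size: float, theta_deg: float) -> np.ndarray:
    """Complex Gabor kernel: wavelength = size, Gaussian σ = size / 2.

    The modulation axis follows the direction convention of the matrix
    families (0° = along columns).  The kernel is normalized by the envelope
    mass so responses are comparable across sizes.
    """
    sigma = size / 2.0
    radius = int(math.ceil(3.0 * sigma))
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(np.float64)
    theta = math.radians(theta_deg)
    xr = xx * math.cos(theta) + yy * math.sin(theta)
    yr = -xx * math.sin(theta) + yy * math.cos(theta)
    envelope = np.exp(-(xr**2 + yr**2) / (2.0 * sigma**2))
    kernel = envelope * np.exp(2j * math.pi * xr / size)
    return kernel / envelope.sum()


def gabor_features(
    region: NormalizedRegion,
    sizes: Sequence[int] = DEFAULT_CONFIG.gabor_sizes,
    angles: Sequence[int] = DEFAULT_CONFIG.angles,
) -> Dict[str, float]:
    """Mean Gabor response magnitude per (orientation, envelope size).

    The region mean is subtracted before filtering, so the filter bank is
    exactly DC-free and a constant region yields zero response everywhere.
    """
    p = region.pixels.astype(np.float64)
    largest = max(sizes)
    if min(p.shape) < largest:
        raise InsufficientExtentError(
            f"Gabor envelope {largest} exceeds region extent {p.shape}"
        )
    centred = p - p.mean()
    out: Dict[str, float] = {}
    for a in angles:
        for s in sizes:
            kernel = _gabor_kernel(s, a)
            radius = (kernel.shape[0] - 1) // 2
            # symmetric edge padding + FFT convolution == ndimage 'reflect'
            padded = np.pad(centred, radius, mode="symmetric")
            response = signal.fftconvolve(padded, kernel, mode="valid")
            out[f"gabor_a{a}_s{s}"] = float(np.abs(response).mean())
    return out


# ---------------------------------------------------------------------------
# HOG family


def hog_features(region: NormalizedRegion, n_bins: int = 8) -> Dict[str, float]:
    """Magnitude-weighted histogram of gradient orientations.

    Central-difference gradients on the interior, orientations binned into
    ``n_bins`` equal sectors of [0°, 360°), weighted by gradient magnitude
    and normalized to sum 1 (all-zero when the region has no gradient).
    """
    p = region.pixels.astype(np.float64)
    if p.shape[0] < 3 or p.shape[1] < 3:
        raise InsufficientExtentError("HOG features need at least a 3x3 region")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy).ravel()
    angle = np.mod(np.arctan2(gy, gx).ravel(), 2.0 * math.pi)
    bins = np.minimum((angle / (2.0 * math.pi / n_bins)).astype(np.int64), n_bins - 1)
    hist = np.zeros(n_bins)
    np.add.at(hist, bins, mag)
    total = hist.sum()
    if total > 0:
        hist /= total
    return {f"hog_bin{b}": float(hist[b]) for b in range(n_bins)}


# ---------------------------------------------------------------------------
# full descriptor


def extract_all(region: Region, config: FeatureConfig = DEFAULT_CONFIG) -> Dict[str, float]:
    """Compute the full named descriptor of one region.

    The ±3σ normalization is applied first (unless disabled in the config),
    then every family is evaluated.  The result is an ordered mapping whose
    key sequence equals :func:`feature_names` — 307 entries with the default
    configuration.  Family errors are re-raised with the family name
    prefixed.
    """
    if config.normalize:
        norm = normalize_3sigma(region, ceiling=config.ceiling)
    else:
        norm = NormalizedRegion(
            pixels=np.asarray(region.pixels, dtype=np.int64),
            bit_depth=region.bit_depth,
            gray_max=2**region.bit_depth - 1,
            mu=float(np.mean(region.pixels)),
            sigma=float(np.std(region.pixels)),
        )
    out: Dict[str, float] = {}

    def _family(name, fn):
        try:
            out.update(fn())
        except Exception as exc:
            raise exc.__class__(f"[{name}] {exc}") from exc

    _family("histogram", lambda: histogram_features(norm))

    def _glcm_all():
        vals: Dict[str, float] = {}
        q = quantize(norm.pixels, norm.gray_max, config.n_gray_levels)
        for a in config.angles:
            dr, dc = DIRECTION_OFFSETS[a]
            for d in config.distances:
                mat = cooccurrence_matrix(q, (dr * d, dc * d), config.n_gray_levels)
                stats = glcm_features(mat)
                vals.update({f"glcm_a{a}_d{d}_{k}": v for k, v in stats.items()})
        return vals

    _family("glcm", _glcm_all)

    def _rlm_all():
        vals: Dict[str, float] = {}
        for a in config.angles:
            stats = rlm_features(norm, a, levels=config.n_gray_levels)
            vals.update({f"rlm_a{a}_{k}": v for k, v in stats.items()})
        return vals

    _family("rlm", _rlm_all)
    _family("gradient", lambda: gradient_features(norm))
    _family("ar", lambda: ar_features(norm))
    _family("haar", lambda: haar_features(norm, n_levels=config.haar_levels))
    _family(
        "gabor", lambda: gabor_features(norm, sizes=config.gabor_sizes, angles=config.angles)
    )
    _family("hog", lambda: hog_features(norm, n_bins=config.hog_bins))

    schema = feature_names(config)
    return {name: out[name] for name in schema}
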