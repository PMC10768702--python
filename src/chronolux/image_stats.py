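"""The canonical 30-statistic vector and the airlight estimate per image.

Thirty photometric and colorimetric statistics summarize, for one image,
the luminance distribution, the chromatic distribution (CIELAB b*, chroma,
saturation, colorfulness, CCT), the photoreceptor drive (cone, rod, and
melanopic means), and the coupling between luminance and chromaticity
(pixel-wise correlations and normalized channel distances, plus the
CIEDE2000 difference between the brightest and darkest pixels).  Together
they capture the regularities of natural illumination that shift with
solar elevation — bright, contrasty, cool-white scenes at one pole and
dim, flat, warm scenes at the other.

Definitions that the literature leaves open are fixed here and documented:

* RMS contrast is the coefficient of variation (population SD / mean) of
  the linear channel.
* "Mean image CCT" is the CCT of the mean image chromaticity (mean u, v),
  not the mean of per-pixel CCTs.
* "CCT difference" is the per-pixel CCT range (max - min); the inverse CCT
  difference is the range on the mired scale (1e6 / CCT); the saturation
  difference is the per-pixel saturation range.
* Luminance-chromaticity image distances min-max normalize each channel
  within the image before averaging absolute pixel-wise differences.
* Statistics that cannot be computed (e.g. no pixel with a defined CCT)
  are NaN with a logged reason, never silently dropped.

The airlight (haze color) estimate follows the dark-channel prior: the
dark channel is the patch-wise minimum over the channel-wise minimum;
pixels in its top quantile are candidate haze; among their connected
clusters, the one ranking brightest and least saturated is averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage

from . import colorimetry as cm
from . import photoreceptor as pr
from .colorimetry import ColorMaps, EncodedImage, LinearImage
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "STATISTIC_NAMES",
    "ImageStatistics",
    "AirlightEstimate",
    "channel_descriptives",
    "rms_contrast",
    "extreme_color_difference",
    "luminance_weighted_cct",
    "luminance_chromaticity_correlation",
    "luminance_chromaticity_distance",
    "colorfulness",
    "dark_channel",
    "estimate_airlight",
    "extract_statistics",
]

#: Canonical order and names of the 30 per-image statistics.
STATISTIC_NAMES = (
    "mean_luminance",
    "var_luminance",
    "skew_luminance",
    "mean_luma",
    "mean_l_cone",
    "mean_m_cone",
    "mean_s_cone",
    "mean_rod",
    "mean_melanopic",
    "rms_contrast_luminance",
    "rms_contrast_blue",
    "mean_saturation",
    "mean_chroma",
    "min_chroma",
    "mean_bstar",
    "min_bstar",
    "sd_bstar",
    "mean_colorfulness",
    "mean_image_cct",
    "cct_difference",
    "inverse_cct_difference",
    "saturation_difference",
    "mean_luminance_weighted_cct",
    "delta_e00_extremes",
    "corr_bstar_luminance",
    "corr_saturation_luminance",
    "corr_chroma_luminance",
    "dist_bstar_luminance",
    "dist_saturation_luminance",
    "dist_chroma_luminance",
)


@dataclass(frozen=True)
class ImageStatistics:
    """The canonical named 30-vector of per-image statistics (fixed order)."""

    values: np.ndarray
    names: tuple = STATISTIC_NAMES

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.names),):
            raise ValueError(f"expected {len(self.names)} values, got {vals.shape}")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


@dataclass(frozen=True)
class AirlightEstimate:
    """Estimated airlight: linear RGB, chromaticity, CCT/Duv, support size."""

    rgb: np.ndarray
    xy: np.ndarray
    cct: float
    duv: float
    n_pixels_used: int
    defined: bool = True


class Descriptives(NamedTuple):
    max: float
    min: float
    mean: float
    variance: float
    skewness: float


# --------------------------------------------------------------------------
# Scalar statistics
# --------------------------------------------------------------------------


def channel_descriptives(channel: np.ndarray) -> Descriptives:
    """Max, min, mean, population variance, and skewness of a pixel map.

    Skewness is the moment estimator g1 = m3 / m2^1.5; a constant map has
    variance 0 and skewness defined as 0.
    """
    vals = np.asarray(channel, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite pixels")
    mean = vals.mean()
    dev = vals - mean
    m2 = np.mean(dev**2)
    if m2 <= 0.0:
        skew = 0.0
    else:
        skew = float(np.mean(dev**3) / m2**1.5)
    return Descriptives(float(vals.max()), float(vals.min()), float(mean),
                        float(m2), skew)


def rms_contrast(channel: np.ndarray) -> float:
    """RMS contrast: population standard deviation over the mean (scale-free).

    Undefined (NaN, logged) for a non-positive mean.
    """
    vals = np.asarray(channel, dtype=float).ravel()
    mean = vals.mean()
    if mean <= 0.0:
        logger.warning("rms_contrast undefined: channel mean is not positive")
        return float("nan")
    return float(vals.std() / mean)


def extreme_color_difference(lab: np.ndarray, luminance: np.ndarray) -> float:
    """CIEDE2000 between the brightest and darkest pixels' CIELAB values.

    Ties in the luminance extremes break to the first raster-scan position.
    """
    Y = np.asarray(luminance, dtype=float).ravel()
    labs = np.asarray(lab, dtype=float).reshape(-1, 3)
    return float(cm.delta_e_2000(labs[int(np.argmax(Y))], labs[int(np.argmin(Y))]))


def luminance_weighted_cct(cct: np.ndarray, luminance: np.ndarray) -> float:
    """Luminance-weighted mean CCT: sum(CCT_i * Y_i) / sum(Y_i) over defined CCTs."""
    c = np.asarray(cct, dtype=float).ravel()
    y = np.asarray(luminance, dtype=float).ravel()
    ok = np.isfinite(c) & np.isfinite(y)
    if not ok.any() or y[ok].sum() <= 0.0:
        logger.warning("luminance_weighted_cct undefined: no valid weighted pixels")
        return float("nan")
    return float(np.sum(c[ok] * y[ok]) / np.sum(y[ok]))


def luminance_chromaticity_correlation(luminance: np.ndarray, channel: np.ndarray) -> float:
    """Pearson correlation across pixels; 0 by convention if either map is constant."""
    y = np.asarray(luminance, dtype=float).ravel()
    c = np.asarray(channel, dtype=float).ravel()
    if y.size != c.size or y.size < 2:
        raise ValueError("maps must share shape with at least 2 pixels")
    if np.ptp(y) == 0.0 or np.ptp(c) == 0.0:
        return 0.0
    return float(np.corrcoef(y, c)[0, 1])


def _minmax_normalize(vals: np.ndarray) -> np.ndarray:
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.zeros_like(vals)
    return (vals - lo) / (hi - lo)


def luminance_chromaticity_distance(luminance: np.ndarray, channel: np.ndarray) -> float:
    """Mean |difference| between min-max normalized luminance and chromatic maps.

    Both channels are rescaled to [0, 1] within the image first, so the
    distance compares distributional shape, not units; a constant channel
    normalizes to all zeros.
    """
    y = _minmax_normalize(np.asarray(luminance, dtype=float).ravel())
    c = _minmax_normalize(np.asarray(channel, dtype=float).ravel())
    if y.size != c.size:
        raise ValueError("maps must share shape")
    return float(np.mean(np.abs(y - c)))


def colorfulness(img: LinearImage | np.ndarray) -> float:
    """Hasler-Suesstrunk colorfulness on the opponent channels rg and yb.

    M = sqrt(sigma_rg^2 + sigma_yb^2) + 0.3 * sqrt(mu_rg^2 + mu_yb^2),
    with rg = R - G and yb = (R + G)/2 - B on linear channels.
    """
    rgb = img.pixels if isinstance(img, LinearImage) else np.asarray(img, dtype=float)
    r, g, b = rgb[..., 0].ravel(), rgb[..., 1].ravel(), rgb[..., 2].ravel()
    rg = r - g
    yb = 0.5 * (r + g) - b
    sigma = np.sqrt(rg.std() ** 2 + yb.std() ** 2)
    mu = np.sqrt(rg.mean() ** 2 + yb.mean() ** 2)
    return float(sigma + 0.3 * mu)


# --------------------------------------------------------------------------
# Airlight (dark channel prior)
# --------------------------------------------------------------------------


def dark_channel(rgb: np.ndarray, patch: int = 15) -> np.ndarray:
    """Dark channel: minimum over a patch neighborhood of the channel minimum."""
    if patch < 1 or patch % 2 == 0:
        raise ValueError("patch must be a positive odd integer")
    per_pixel_min = np.asarray(rgb, dtype=float).min(axis=2)
    if patch == 1:
        return per_pixel_min
    return ndimage.minimum_filter(per_pixel_min, size=patch, mode="nearest")


def estimate_airlight(
    img: LinearImage,
    patch: int = 15,
    top_frac: float = 0.001,
    wp: cm.WhitePoint = cm.D65,
) -> AirlightEstimate:
    """Airlight color via the dark-channel prior with cluster refinement.

    Candidate haze pixels are those in the top ``top_frac`` quantile of the
    dark channel.  Their 8-connected clusters are ranked by mean luminance
    (ascending rank) minus mean CIELAB saturation (ascending rank); the
    best-scoring cluster — bright and achromatic, as scattered airlight
    should be — is averaged to give the airlight RGB, from which the
    chromaticity and CCT follow.  An all-black image yields an undefined
    (flagged) estimate.
    """
    if not (0.0 < top_frac <= 1.0):
        raise ValueError("top_frac must be in (0, 1]")
    rgb = img.pixels
    if rgb.max() <= 0.0:
        logger.warning("estimate_airlight undefined: image is all black")
        nan3 = np.full(3, np.nan)
        return AirlightEstimate(nan3, np.full(2, np.nan), float("nan"),
                                float("nan"), 0, defined=False)
    dark = dark_channel(rgb, patch)
    threshold = np.quantile(dark.ravel(), 1.0 - top_frac)
    mask = dark >= threshold
    labels, n_clusters = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    xyz = cm.rgb_to_xyz(rgb, wp)
    lab = cm.xyz_to_lab(xyz, wp)
    _, _, saturation = cm.lab_to_polar(lab)
    lum = xyz[..., 1]

    ids = np.arange(1, n_clusters + 1)
    mean_lum = ndimage.mean(lum, labels=labels, index=ids)
    mean_sat = ndimage.mean(saturation, labels=labels, index=ids)
    sizes = ndimage.sum_labels(np.ones_like(lum), labels=labels, index=ids)
    # rank ascending: brightest gets highest luminance rank, most saturated
    # the highest saturation rank; airlight wants high lum, low sat
    lum_rank = np.argsort(np.argsort(mean_lum))
    sat_rank = np.argsort(np.argsort(mean_sat))
    score = lum_rank.astype(float) - sat_rank.astype(float)
    order = np.lexsort((ids, -sizes, -score))  # best score, then largest, then id
    best = ids[order[0]]

    sel = labels == best
    airlight_rgb = rgb[sel].mean(axis=0)
    a_xyz = cm.rgb_to_xyz(airlight_rgb[None, None, :], wp)[0, 0]
    a_xy = cm.xyz_to_xy(a_xyz)
    uv = cm.xyz_to_uv1960(a_xyz)
    cct, duv, _ = cm.compute_cct(uv)
    return AirlightEstimate(airlight_rgb, a_xy, float(cct), float(duv),
                            int(sel.sum()), defined=True)


# --------------------------------------------------------------------------
# The 30-statistic vector
# --------------------------------------------------------------------------


def extract_statistics(
    img: EncodedImage,
    cfg: PipelineConfig | None = None,
    basis: pr.SpectralBasis | None = None,
    sens: pr.SensitivitySet | None = None,
    maps: ColorMaps | None = None,
) -> ImageStatistics:
    """Compute the canonical 30-statistic vector for one encoded image.

    Deterministic for a fixed config.  Pass precomputed ``maps`` to avoid
    recomputing the color maps when they are needed elsewhere too.
    """
    cfg = cfg or PipelineConfig()
    wp = cfg.resolved_white_point()
    linear = cm.decode_srgb(img, cfg.gamma)
    if maps is None:
        maps = cm.compute_color_maps(
            linear,
            wp,
            cct_stride=cfg.cct_stride,
            cct_pixel_cap=cfg.cct_pixel_cap,
            duv_cap=cfg.duv_cap,
            min_luminance=cfg.min_luminance,
            cct_t_min=cfg.cct_t_min,
            cct_t_max=cfg.cct_t_max,
        )
    Y = maps.luminance
    bstar = maps.lab[..., 2]
    luma = cm.compute_luma(img, cfg.luma_weights)
    receptors = pr.receptor_activations(linear, basis, sens)

    lum_desc = channel_descriptives(Y)
    b_desc = channel_descriptives(bstar)

    # Strided CCT map and matching luminance for CCT-based statistics.
    cct_map = maps.cct.ravel()
    s = maps.cct_stride
    Y_strided = Y[::s, ::s].ravel()
    cct_ok = cct_map[np.isfinite(cct_map)]

    if cct_ok.size:
        cct_diff = float(cct_ok.max() - cct_ok.min())
        mired = 1e6 / cct_ok
        inv_cct_diff = float(mired.max() - mired.min())
    else:
        logger.warning("no pixel with defined CCT; CCT range statistics are NaN")
        cct_diff = inv_cct_diff = float("nan")

    uv_flat = maps.uv.reshape(-1, 2)
    uv_ok = uv_flat[np.all(np.isfinite(uv_flat), axis=1)]
    if uv_ok.size:
        mean_cct, _, _ = cm.compute_cct(
            uv_ok.mean(axis=0), t_min=cfg.cct_t_min, t_max=cfg.cct_t_max,
            duv_cap=cfg.duv_cap,
        )
    else:
        logger.warning("no pixel with defined chromaticity; mean image CCT is NaN")
        mean_cct = float("nan")

    sat = maps.saturation
    values = {
        "mean_luminance": lum_desc.mean,
        "var_luminance": lum_desc.variance,
        "skew_luminance": lum_desc.skewness,
        "mean_luma": float(luma.mean()),
        "mean_l_cone": float(receptors.l_cone.mean()),
        "mean_m_cone": float(receptors.m_cone.mean()),
        "mean_s_cone": float(receptors.s_cone.mean()),
        "mean_rod": float(receptors.rod.mean()),
        "mean_melanopic": float(receptors.melanopic.mean()),
        "rms_contrast_luminance": rms_contrast(Y),
        "rms_contrast_blue": rms_contrast(linear.pixels[..., 2]),
        "mean_saturation": float(sat.mean()),
        "mean_chroma": float(maps.chroma.mean()),
        "min_chroma": float(maps.chroma.min()),
        "mean_bstar": b_desc.mean,
        "min_bstar": b_desc.min,
        "sd_bstar": float(np.sqrt(b_desc.variance)),
        "mean_colorfulness": colorfulness(linear),
        "mean_image_cct": float(mean_cct),
        "cct_difference": cct_diff,
        "inverse_cct_difference": inv_cct_diff,
        "saturation_difference": float(sat.max() - sat.min()),
        "mean_luminance_weighted_cct": luminance_weighted_cct(cct_map, Y_strided),
        "delta_e00_extremes": extreme_color_difference(maps.lab, Y),
        "corr_bstar_luminance": luminance_chromaticity_correlation(Y, bstar),
        "corr_saturation_luminance": luminance_chromaticity_correlation(Y, sat),
        "corr_chroma_luminance": luminance_chromaticity_correlation(Y, maps.chroma),
        "dist_bstar_luminance": luminance_chromaticity_distance(Y, bstar),
        "dist_saturation_luminance": luminance_chromaticity_distance(Y, sat),
        "dist_chroma_luminance": luminance_chromaticity_distance(Y, maps.chroma),
    }
    return ImageStatistics(np.array([values[n] for n in STATISTIC_NAMES]))
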