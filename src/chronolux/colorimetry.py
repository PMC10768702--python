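"""Color-appearance coordinates for gamma-encoded RGB images.

This module turns encoded RGB pixel values into standardized colorimetric
coordinates: linear intensities (via a pure power-law transfer function),
CIE 1931 XYZ, CIELAB and its polar form (chroma, hue, saturation),
CIE 1960 (u, v) chromaticities, and correlated color temperature (CCT)
with the signed distance from the Planckian locus (Duv).  It also provides
the CIEDE2000 color-difference formula and Rec. 709 luma.

Conventions
-----------
* The display model is a pure power law ``I = v**gamma`` with gamma 2.2
  (not the piecewise IEC sRGB curve): images are treated the way a typical
  uncalibrated display renders them.
* RGB -> XYZ uses the IEC 61966-2-1 primaries with the matrix re-normalized
  so that RGB = (1, 1, 1) maps exactly to the configured white point
  (D65 by default).  The white point is a free parameter because the
  assumed display white is an assumption, not a measurement.
* CCT is the temperature of the black-body radiator with the nearest
  chromaticity in CIE 1960 (u, v) space; Duv is the signed perpendicular
  distance, positive above the locus (toward green).

The CIE 1931 2-degree color-matching functions are evaluated from a
multi-lobe asymmetric-Gaussian analytic approximation (Wyman, Sloan &
Shirley 2013).  Its error against the tabulated observer is below about
one percent of peak, which shifts absolute CCTs by at most a few tens of
kelvin; all CCT/Duv computations in the package share these functions, so
locus searches and spectral integrations are mutually consistent.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "EncodedImage",
    "LinearImage",
    "WhitePoint",
    "ColorMaps",
    "PlanckianLocus",
    "cie1931_cmf",
    "planck_spectrum",
    "planck_uv",
    "daylight_chromaticity",
    "get_white_point",
    "decode_srgb",
    "encode_srgb",
    "rgb_to_xyz_matrix",
    "rgb_to_xyz",
    "xyz_to_rgb",
    "xyz_to_lab",
    "lab_to_xyz",
    "lab_to_polar",
    "xyz_to_uv1960",
    "xy_to_xyz",
    "xyz_to_xy",
    "uv_to_xy",
    "compute_cct",
    "compute_color_maps",
    "delta_e_2000",
    "compute_luma",
    "REC709_LUMA_WEIGHTS",
    "DEFAULT_GAMMA",
]

DEFAULT_GAMMA = 2.2

#: Rec. 709 luma weights applied to gamma-encoded R, G, B.
REC709_LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)

# IEC 61966-2-1 (sRGB) primary chromaticities.
SRGB_PRIMARIES_XY = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])

# CIELAB breakpoint constants.
_LAB_DELTA = 6.0 / 29.0
_LAB_EPS = _LAB_DELTA**3
_LAB_KAPPA = 1.0 / (3.0 * _LAB_DELTA**2)

# Second radiation constant, nm * K (CODATA, for Planck's law).
_C2_NM_K = 1.4388e7


# --------------------------------------------------------------------------
# Image containers
# --------------------------------------------------------------------------


def _validate_rgb(pixels: np.ndarray, unit_range: bool = True) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 array, got shape {pixels.shape}")
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("pixel values must be finite")
    if unit_range and (pixels.min() < 0.0 or pixels.max() > 1.0):
        raise ValueError("pixel values must lie in [0, 1]")
    return pixels


@dataclass(frozen=True)
class EncodedImage:
    """Gamma-encoded RGB raster with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pixels", _validate_rgb(self.pixels))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class LinearImage:
    """Linear-intensity RGB raster with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pixels", _validate_rgb(self.pixels))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


# --------------------------------------------------------------------------
# Color-matching functions and Planck's law
# --------------------------------------------------------------------------


def _lobe(wl, alpha, mu, sigma_lo, sigma_hi):
    sigma = np.where(wl < mu, sigma_lo, sigma_hi)
    t = (wl - mu) / sigma
    return alpha * np.exp(-0.5 * t * t)


def cie1931_cmf(wavelengths: np.ndarray) -> np.ndarray:
    """CIE 1931 2-deg color-matching functions (analytic approximation).

    Multi-lobe asymmetric-Gaussian fit (Wyman, Sloan & Shirley 2013) to the
    standard observer; returns an (N, 3) array of (xbar, ybar, zbar).
    """
    wl = np.asarray(wavelengths, dtype=float)
    xbar = (
        _lobe(wl, 1.056, 599.8, 37.9, 31.0)
        + _lobe(wl, 0.362, 442.0, 16.0, 26.7)
        + _lobe(wl, -0.065, 501.1, 20.4, 26.2)
    )
    ybar = _lobe(wl, 0.821, 568.8, 46.9, 40.5) + _lobe(wl, 0.286, 530.9, 16.3, 31.1)
    zbar = _lobe(wl, 1.217, 437.0, 11.8, 36.0) + _lobe(wl, 0.681, 459.0, 26.0, 13.8)
    return np.stack([xbar, ybar, zbar], axis=-1)


def default_wavelengths(step: float = 1.0) -> np.ndarray:
    """Visible-range wavelength grid in nm (360-830 by default step 1)."""
    return np.arange(360.0, 830.0 + step / 2, step)


def planck_spectrum(temperature, wavelengths: np.ndarray) -> np.ndarray:
    """Relative black-body spectral radiance at the given temperatures.

    Parameters are temperature(s) in kelvin (scalar or (M,) array) and a
    wavelength grid in nm; returns spectra of shape (..., N), arbitrary units.
    """
    T = np.atleast_1d(np.asarray(temperature, dtype=float))[:, None]
    wl = np.asarray(wavelengths, dtype=float)[None, :]
    with np.errstate(over="ignore"):
        rad = wl**-5.0 / np.expm1(_C2_NM_K / (wl * T))
    return rad[0] if np.ndim(temperature) == 0 else rad


def planck_uv(temperature, wavelengths: np.ndarray | None = None) -> np.ndarray:
    """CIE 1960 (u, v) chromaticity of a black-body radiator.

    Integrates Planck's law against the color-matching functions on a 1 nm
    grid.  Accepts a scalar or array of temperatures; returns shape (..., 2).
    """
    if wavelengths is None:
        wavelengths = default_wavelengths()
    T = np.atleast_1d(np.asarray(temperature, dtype=float))
    spec = planck_spectrum(T, wavelengths)
    spec = spec / spec.max(axis=-1, keepdims=True)
    cmf = cie1931_cmf(wavelengths)
    xyz = np.trapezoid(spec[..., None] * cmf[None, :, :], wavelengths, axis=-2)
    uv = xyz_to_uv1960(xyz)
    return uv if np.ndim(temperature) else uv[0]


def daylight_chromaticity(cct: float) -> tuple[float, float]:
    """CIE daylight-locus xy chromaticity for a given CCT in kelvin.

    The standard CIE polynomials are defined for 4000-25000 K; below 4000 K
    the low-temperature branch is extrapolated (used only for named white
    points such as D30 that the literature plots on an extended locus).
    """
    t = 1e3 / float(cct)
    if cct <= 7000.0:
        x = 0.244063 + 0.09911 * t + 2.9678 * t**2 - 4.6070 * t**3
    else:
        x = 0.237040 + 0.24748 * t + 1.9018 * t**2 - 2.0064 * t**3
    y = -3.000 * x**2 + 2.870 * x - 0.275
    return float(x), float(y)


# --------------------------------------------------------------------------
# White points
# --------------------------------------------------------------------------


def xy_to_xyz(xy, Y: float = 1.0) -> np.ndarray:
    """Tristimulus values with luminance Y from an xy chromaticity pair."""
    x, y = float(xy[0]), float(xy[1])
    if y <= 0:
        raise ValueError("y chromaticity must be positive")
    return np.array([x * Y / y, Y, (1.0 - x - y) * Y / y])


def xyz_to_xy(xyz) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    s = xyz.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        xy = xyz[..., :2] / s
    return xy


def uv_to_xy(uv) -> np.ndarray:
    """CIE 1960 (u, v) back to CIE 1931 (x, y)."""
    uv = np.asarray(uv, dtype=float)
    u, v = uv[..., 0], uv[..., 1]
    denom = 2.0 * u - 8.0 * v + 4.0
    return np.stack([3.0 * u / denom, 2.0 * v / denom], axis=-1)


@dataclass(frozen=True)
class WhitePoint:
    """Display white: the chromaticity that RGB = (1, 1, 1) is assumed to map to."""

    name: str
    xy: tuple[float, float]
    XYZ_n: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        x, y = self.xy
        if not (x > 0 and y > 0 and x + y < 1):
            raise ValueError(f"invalid chromaticity {self.xy}")
        object.__setattr__(self, "XYZ_n", xy_to_xyz(self.xy, 1.0))


# Canonical CIE daylight illuminant chromaticities (2-deg observer).
_NAMED_WHITE_POINTS = {
    "D50": (0.3457, 0.3585),
    "D55": (0.3324, 0.3474),
    "D65": (0.3127, 0.3290),
    "D75": (0.2990, 0.3149),
}


def get_white_point(name_or_xy) -> WhitePoint:
    """Resolve a white point from a name ('D65', 'D40', ...) or an xy pair.

    Names of the form D<nn> not in the canonical table are placed on the CIE
    daylight locus at nn x 100 K.
    """
    if isinstance(name_or_xy, WhitePoint):
        return name_or_xy
    if isinstance(name_or_xy, str):
        name = name_or_xy.upper()
        if name in _NAMED_WHITE_POINTS:
            return WhitePoint(name, _NAMED_WHITE_POINTS[name])
        m = re.fullmatch(r"D(\d{2,3})", name)
        if m:
            cct = int(m.group(1)) * 100.0
            return WhitePoint(name, daylight_chromaticity(cct))
        raise ValueError(f"unknown white point name: {name_or_xy!r}")
    xy = tuple(float(c) for c in name_or_xy)
    return WhitePoint(f"xy({xy[0]:.4f},{xy[1]:.4f})", xy)


D65 = get_white_point("D65")


# --------------------------------------------------------------------------
# Transfer function and RGB <-> XYZ
# --------------------------------------------------------------------------


def decode_srgb(img: EncodedImage, gamma: float = DEFAULT_GAMMA) -> LinearImage:
    """Decode gamma-encoded values to linear intensity via ``I = v**gamma``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return LinearImage(np.power(img.pixels, gamma))


def encode_srgb(img: LinearImage, gamma: float = DEFAULT_GAMMA) -> EncodedImage:
    """Inverse of :func:`decode_srgb`."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return EncodedImage(np.power(img.pixels, 1.0 / gamma))


def rgb_to_xyz_matrix(wp: WhitePoint = D65) -> np.ndarray:
    """3x3 linear-RGB -> XYZ matrix for sRGB primaries and the given white.

    Columns are the primary tristimulus vectors scaled so that
    RGB = (1, 1, 1) maps exactly to ``wp.XYZ_n`` (with Y = 1).
    """
    x, y = SRGB_PRIMARIES_XY[:, 0], SRGB_PRIMARIES_XY[:, 1]
    P = np.stack([x / y, np.ones(3), (1.0 - x - y) / y])  # 3x3, columns=primaries
    cond = np.linalg.cond(P)
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError("primary matrix is singular or ill-conditioned")
    scale = np.linalg.solve(P, wp.XYZ_n)
    return P * scale[None, :]


def rgb_to_xyz(img: LinearImage | np.ndarray, wp: WhitePoint = D65) -> np.ndarray:
    """Linear RGB map (..., 3) to CIE XYZ (Y = luminance, white maps to Y = 1)."""
    rgb = img.pixels if isinstance(img, LinearImage) else np.asarray(img, dtype=float)
    M = rgb_to_xyz_matrix(wp)
    return rgb @ M.T


def xyz_to_rgb(xyz: np.ndarray, wp: WhitePoint = D65) -> np.ndarray:
    """Inverse of :func:`rgb_to_xyz`; may return out-of-gamut (unclipped) values."""
    M = np.linalg.inv(rgb_to_xyz_matrix(wp))
    return np.asarray(xyz, dtype=float) @ M.T


# --------------------------------------------------------------------------
# CIELAB
# --------------------------------------------------------------------------


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _LAB_EPS, np.cbrt(np.maximum(t, 0.0)), _LAB_KAPPA * t + 4.0 / 29.0)


def _lab_finv(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    return np.where(f > _LAB_DELTA, f**3, (f - 4.0 / 29.0) / _LAB_KAPPA)


def xyz_to_lab(xyz: np.ndarray, wp: WhitePoint = D65) -> np.ndarray:
    """CIE XYZ (..., 3) to CIELAB, including the linear segment near black.

    Negative tristimulus values (possible for out-of-gamut inputs) are
    clamped to zero with a logged warning.
    """
    xyz = np.asarray(xyz, dtype=float)
    if np.any(xyz < 0):
        logger.warning("negative tristimulus values clamped to zero in xyz_to_lab")
        xyz = np.maximum(xyz, 0.0)
    f = _lab_f(xyz / wp.XYZ_n)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(lab: np.ndarray, wp: WhitePoint = D65) -> np.ndarray:
    """Inverse CIELAB transform (exact inverse of :func:`xyz_to_lab`)."""
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    return np.stack([_lab_finv(fx), _lab_finv(fy), _lab_finv(fz)], axis=-1) * wp.XYZ_n


def lab_to_polar(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CIELAB to (chroma, hue in degrees, saturation).

    Chroma is ``sqrt(a*^2 + b*^2)``; hue is ``atan2(b*, a*)`` in [0, 360)
    with hue = 0 at zero chroma; saturation is chroma relative to lightness
    (``C*/L*``), defined as 0 at L* = 0.
    """
    lab = np.asarray(lab, dtype=float)
    a, b = lab[..., 1], lab[..., 2]
    L = lab[..., 0]
    chroma = np.hypot(a, b)
    hue = np.degrees(np.arctan2(b, a)) % 360.0
    hue = np.where(chroma == 0.0, 0.0, hue)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(L > 0.0, chroma / L, 0.0)
    return chroma, hue, saturation


# --------------------------------------------------------------------------
# CIE 1960 uv and CCT / Duv
# --------------------------------------------------------------------------


def xyz_to_uv1960(xyz: np.ndarray) -> np.ndarray:
    """CIE 1960 uniform chromaticity coordinates u = 4X/(X+15Y+3Z), v = 6Y/(...).

    Pixels with a zero denominator come back as NaN (undefined chromaticity).
    """
    xyz = np.asarray(xyz, dtype=float)
    X, Y, Z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    denom = X + 15.0 * Y + 3.0 * Z
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(denom > 0, 4.0 * X / denom, np.nan)
        v = np.where(denom > 0, 6.0 * Y / denom, np.nan)
    return np.stack([u, v], axis=-1)


class PlanckianLocus:
    """Precomputed Planckian locus in CIE 1960 (u, v) for CCT/Duv lookup.

    The locus is tabulated at ``step`` kelvin over [t_min, t_max] from the
    package's color-matching functions; queries use a k-d tree nearest
    neighbor followed by local parabolic refinement of the temperature, and
    Duv is the perpendicular offset signed positive above the locus
    (toward green).
    """

    def __init__(self, t_min: float = 1000.0, t_max: float = 25000.0, step: float = 1.0):
        self.t_min, self.t_max, self.step = float(t_min), float(t_max), float(step)
        self.temps = np.arange(self.t_min, self.t_max + step / 2, step)
        self.uv = planck_uv(self.temps)
        self._tree = cKDTree(self.uv)

    def cct(
        self,
        uv: np.ndarray,
        duv_cap: float = 0.05,
        refine: bool = True,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CCT (K), signed Duv, and an out-of-range flag for (u, v) points.

        Points whose perpendicular distance to the locus exceeds ``duv_cap``
        or that are NaN come back with NaN CCT/Duv.  Points nearest a table
        boundary are flagged out-of-range.
        """
        q = np.asarray(uv, dtype=float)
        scalar = q.ndim == 1
        q = np.atleast_2d(q)
        cct = np.full(q.shape[0], np.nan)
        duv = np.full(q.shape[0], np.nan)
        oor = np.zeros(q.shape[0], dtype=bool)

        ok = np.all(np.isfinite(q), axis=1)
        if ok.any():
            qf = q[ok]
            _, idx = self._tree.query(qf)
            oor_ok = (idx == 0) | (idx == len(self.temps) - 1)
            ic = np.clip(idx, 1, len(self.temps) - 2)
            tstar = self.temps[ic].astype(float)
            frac = np.zeros_like(tstar)
            if refine:
                d2 = np.stack(
                    [((qf - self.uv[ic + o]) ** 2).sum(axis=1) for o in (-1, 0, 1)],
                    axis=0,
                )
                denom = d2[2] - 2.0 * d2[1] + d2[0]
                with np.errstate(divide="ignore", invalid="ignore"):
                    shift = np.where(
                        denom > 1e-30, -0.5 * (d2[2] - d2[0]) / denom, 0.0
                    )
                frac = np.clip(shift, -1.0, 1.0)
                tstar = np.clip(tstar + frac * self.step, self.t_min, self.t_max)
            # Locus point and tangent by linear interpolation of the 1 K
            # table (interpolation error is orders below the Duv scale).
            nxt = np.where(frac >= 0, ic + 1, ic - 1)
            locus_pt = self.uv[ic] + np.abs(frac)[:, None] * (self.uv[nxt] - self.uv[ic])
            # Tangent along increasing T; normal rotated +90deg then oriented
            # so the +v (greenish) side of the locus is positive.
            tang = self.uv[ic + 1] - self.uv[ic - 1]
            normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
            normal /= np.linalg.norm(normal, axis=1, keepdims=True)
            flip = normal[:, 1] < 0
            normal[flip] *= -1.0
            offset = qf - locus_pt
            d_signed = (offset * normal).sum(axis=1)
            within = np.abs(d_signed) <= duv_cap
            out_c = np.where(within, tstar, np.nan)
            out_d = np.where(within, d_signed, np.nan)
            cct[ok] = out_c
            duv[ok] = out_d
            oor[ok] = oor_ok
        if scalar:
            return float(cct[0]), float(duv[0]), bool(oor[0])
        return cct, duv, oor


@lru_cache(maxsize=4)
def _default_locus(t_min: float, t_max: float, step: float) -> PlanckianLocus:
    return PlanckianLocus(t_min, t_max, step)


def compute_cct(
    uv,
    t_min: float = 1000.0,
    t_max: float = 25000.0,
    step: float = 1.0,
    duv_cap: float = 0.05,
):
    """Correlated color temperature and Duv for one or many (u, v) points.

    Scalar input (a single pair) returns ``(cct, duv, out_of_range)`` floats;
    array input returns arrays.  See :class:`PlanckianLocus`.
    """
    return _default_locus(t_min, t_max, step).cct(np.asarray(uv, dtype=float), duv_cap)


# --------------------------------------------------------------------------
# CIEDE2000
# --------------------------------------------------------------------------


def delta_e_2000(lab1, lab2) -> np.ndarray | float:
    """CIEDE2000 color difference between CIELAB values (kL = kC = kH = 1).

    Implements the full formula including the a* rescaling, hue-rotation
    term, and the S_L/S_C/S_H weighting functions; broadcasts over leading
    dimensions and is symmetric in its arguments.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    scalar = lab1.ndim == 1 and lab2.ndim == 1
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p, a2p = (1.0 + G) * a1, (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.where(C1p == 0.0, 0.0, np.degrees(np.arctan2(b1, a1p)) % 360.0)
    h2p = np.where(C2p == 0.0, 0.0, np.degrees(np.arctan2(b2, a2p)) % 360.0)

    dLp = L2 - L1
    dCp = C2p - C1p
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0.0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        C1p * C2p == 0.0,
        hsum,
        np.where(habs <= 180.0, 0.5 * hsum,
                 np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0))),
    )
    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    Rc = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * Rc

    dE = np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )
    return float(dE) if scalar else dE


# --------------------------------------------------------------------------
# Luma and aggregate maps
# --------------------------------------------------------------------------


def compute_luma(
    img: EncodedImage, weights: tuple[float, float, float] = REC709_LUMA_WEIGHTS
) -> np.ndarray:
    """Luma: weighted sum of the gamma-encoded channels (Rec. 709 weights)."""
    w = np.asarray(weights, dtype=float)
    return img.pixels @ w


@dataclass(frozen=True)
class ColorMaps:
    """Per-pixel color-appearance maps derived from one image.

    ``cct``/``duv`` are computed on a row/column-subsampled grid (see
    ``cct_stride``) and are NaN where undefined (near-black pixels or
    chromaticities too far from the Planckian locus).
    """

    xyz: np.ndarray
    lab: np.ndarray
    chroma: np.ndarray
    hue: np.ndarray
    saturation: np.ndarray
    uv: np.ndarray
    cct: np.ndarray
    duv: np.ndarray
    cct_stride: int

    @property
    def luminance(self) -> np.ndarray:
        return self.xyz[..., 1]


def compute_color_maps(
    linear: LinearImage,
    wp: WhitePoint = D65,
    cct_stride: int | None = None,
    cct_pixel_cap: int = 100_000,
    duv_cap: float = 0.05,
    min_luminance: float = 1e-4,
    cct_t_min: float = 1000.0,
    cct_t_max: float = 25000.0,
) -> ColorMaps:
    """All per-pixel color maps for one linear image.

    The per-pixel CCT search is the cost hot spot, so it runs on a strided
    grid chosen to keep at most ``cct_pixel_cap`` pixels unless an explicit
    ``cct_stride`` is given.  Pixels with luminance below ``min_luminance``
    or |Duv| above ``duv_cap`` get NaN CCT (no meaningful chromaticity).
    """
    xyz = rgb_to_xyz(linear, wp)
    lab = xyz_to_lab(xyz, wp)
    chroma, hue, saturation = lab_to_polar(lab)
    uv = xyz_to_uv1960(xyz)

    h, w = xyz.shape[:2]
    if cct_stride is None:
        cct_stride = max(1, int(np.ceil(np.sqrt(h * w / cct_pixel_cap))))
    sub = uv[::cct_stride, ::cct_stride].reshape(-1, 2)
    sub_y = xyz[::cct_stride, ::cct_stride, 1].reshape(-1)
    cct_flat = np.full(sub.shape[0], np.nan)
    duv_flat = np.full(sub.shape[0], np.nan)
    valid = np.all(np.isfinite(sub), axis=1) & (sub_y >= min_luminance)
    if valid.any():
        c, d, _ = compute_cct(sub[valid], t_min=cct_t_min, t_max=cct_t_max,
                              duv_cap=duv_cap)
        cct_flat[valid] = c
        duv_flat[valid] = d
    sh = uv[::cct_stride, ::cct_stride].shape[:2]
    return ColorMaps(
        xyz=xyz,
        lab=lab,
        chroma=chroma,
        hue=hue,
        saturation=saturation,
        uv=uv,
        cct=cct_flat.reshape(sh),
        duv=duv_flat.reshape(sh),
        cct_stride=cct_stride,
    )
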