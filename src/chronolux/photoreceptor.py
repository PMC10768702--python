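"""Photoreceptor activations from linear RGB via spectral reconstruction.

A display pixel's spectrum is modeled as a nonnegative linear combination of
three fixed primary spectra, ``S(lambda) = r*P_R + g*P_G + b*P_B``.
Integrating that spectrum against photoreceptor sensitivity curves gives
L/M/S cone, rod (scotopic), and melanopic activations per pixel.  Because
both steps are linear, the whole map collapses to a precomputed 5x3 matrix
applied to linear RGB, which is how :func:`receptor_activations` evaluates
it; the integral path is kept for verification.

Bundled data
------------
The bundled primary spectra are smooth nonnegative curves least-squares
fitted (ridge-regularized NNLS over Gaussian bumps) so that each primary's
spectrum reproduces that primary's XYZ tristimulus values under the
package's color-matching functions; :func:`roundtrip_check` verifies the
spectrum -> XYZ -> RGB round trip.  The bundled sensitivity curves are
*synthetic* analytic stand-ins: asymmetric Gaussians placed at the
canonical peak wavelengths of the human photoreceptors (L 570 nm, M 543 nm,
S 442 nm, rod 507 nm, melanopsin 490 nm), normalized to unit peak.  They
reproduce the ordinal structure of the real curves (band positions and
overlaps) but not their exact shapes; downstream statistics use only
relative activations.  All bundled CSVs carry ``synthetic`` in their
filenames and can be overridden with measured tables via the config.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from .colorimetry import WhitePoint, D65, cie1931_cmf, rgb_to_xyz_matrix, xyz_to_rgb

__all__ = [
    "SpectralBasis",
    "SensitivitySet",
    "ReceptorMaps",
    "RECEPTOR_NAMES",
    "load_basis",
    "load_sensitivities",
    "synthetic_sensitivities",
    "fit_primary_basis",
    "reconstruct_spectrum",
    "activation_matrix",
    "receptor_activations",
    "roundtrip_check",
    "write_bundled_data",
]

RECEPTOR_NAMES = ("l_cone", "m_cone", "s_cone", "rod", "melanopic")

_DEFAULT_GRID = np.arange(380.0, 780.0 + 2.5, 5.0)

_SENSITIVITY_FILES = {
    "l_cone": "cone_l_synthetic.csv",
    "m_cone": "cone_m_synthetic.csv",
    "s_cone": "cone_s_synthetic.csv",
    "rod": "rod_synthetic.csv",
    "melanopic": "melanopic_synthetic.csv",
}
_PRIMARY_FILES = ("primary_r_synthetic.csv", "primary_g_synthetic.csv",
                  "primary_b_synthetic.csv")


@dataclass(frozen=True)
class SpectralBasis:
    """Three display-primary spectra on a common wavelength grid (nm)."""

    wavelengths: np.ndarray
    primary_spectra: np.ndarray  # (3, N), power per nm

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        spec = np.asarray(self.primary_spectra, dtype=float)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if spec.shape != (3, wl.size):
            raise ValueError(f"expected (3, {wl.size}) primary spectra, got {spec.shape}")
        if np.any(spec < -1e-12):
            raise ValueError("primary spectra must be nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "primary_spectra", np.maximum(spec, 0.0))


@dataclass(frozen=True)
class SensitivitySet:
    """Five unit-peak sensitivity curves on a common wavelength grid."""

    wavelengths: np.ndarray
    curves: np.ndarray  # (5, N) ordered as RECEPTOR_NAMES

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        cur = np.asarray(self.curves, dtype=float)
        if cur.shape != (5, wl.size):
            raise ValueError(f"expected (5, {wl.size}) curves, got {cur.shape}")
        if np.any(cur < 0):
            raise ValueError("sensitivity curves must be nonnegative")
        peaks = cur.max(axis=1)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "curves", cur / peaks[:, None])

    def curve(self, name: str) -> np.ndarray:
        return self.curves[RECEPTOR_NAMES.index(name)]


@dataclass(frozen=True)
class ReceptorMaps:
    """Per-pixel activation maps (arbitrary linear units, white = 1)."""

    l_cone: np.ndarray
    m_cone: np.ndarray
    s_cone: np.ndarray
    rod: np.ndarray
    melanopic: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in RECEPTOR_NAMES}


# --------------------------------------------------------------------------
# Synthetic sensitivity curves (analytic stand-ins, unit peak)
# --------------------------------------------------------------------------


def _asym_gauss(wl, mu, sigma_lo, sigma_hi):
    sigma = np.where(wl < mu, sigma_lo, sigma_hi)
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


# (peak nm, sigma short side, sigma long side)
_SENSITIVITY_SHAPES = {
    "l_cone": (570.0, 45.0, 50.0),
    "m_cone": (543.0, 42.0, 48.0),
    "s_cone": (442.0, 25.0, 32.0),
    "rod": (507.0, 38.0, 46.0),
    "melanopic": (490.0, 38.0, 46.0),
}


def synthetic_sensitivities(wavelengths: np.ndarray | None = None) -> SensitivitySet:
    """Synthetic photoreceptor sensitivity curves (asymmetric Gaussians).

    Analytic stand-ins for the measured cone fundamentals, scotopic
    luminosity, and melanopic efficiency curves; peak wavelengths match the
    canonical values, shapes are smooth approximations.
    """
    wl = _DEFAULT_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    curves = np.stack(
        [_asym_gauss(wl, *_SENSITIVITY_SHAPES[name]) for name in RECEPTOR_NAMES]
    )
    return SensitivitySet(wl, curves)


# --------------------------------------------------------------------------
# Primary basis fitting
# --------------------------------------------------------------------------


def fit_primary_basis(
    wavelengths: np.ndarray | None = None,
    wp: WhitePoint = D65,
    n_bumps: int = 13,
    bump_sigma: float = 30.0,
) -> SpectralBasis:
    """Fit smooth nonnegative primary spectra reproducing the primaries' XYZ.

    Each primary spectrum is a nonnegative combination of Gaussian bumps
    solved by heavily weighted ridge NNLS so that its XYZ under the
    package's color-matching functions matches the corresponding column of
    the RGB->XYZ matrix almost exactly (residual ~1e-8), while the ridge
    term keeps the spectrum smooth.
    """
    wl = _DEFAULT_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    centers = np.linspace(410.0, 700.0, n_bumps)
    bumps = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / bump_sigma) ** 2)
    cmf = cie1931_cmf(wl)  # (N, 3)
    # A[j, k] = integral of bump_k against cmf_j
    A = np.stack([np.trapezoid(bumps * cmf[:, j][None, :], wl, axis=1) for j in range(3)])
    M = rgb_to_xyz_matrix(wp)
    weight = 1e4
    spectra = []
    for i in range(3):
        target = M[:, i]
        A_aug = np.vstack([weight * A, np.eye(n_bumps)])
        b_aug = np.concatenate([weight * target, np.zeros(n_bumps)])
        coef, _ = nnls(A_aug, b_aug)
        spectra.append(coef @ bumps)
    return SpectralBasis(wl, np.stack(spectra))


# --------------------------------------------------------------------------
# Bundled-data I/O
# --------------------------------------------------------------------------


def _read_curve_csv(path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return arr[:, 0], arr[:, 1]


def _write_curve_csv(path: Path, wl: np.ndarray, values: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("wavelength_nm,value\n")
        for w, v in zip(wl, values):
            fh.write(f"{w:.1f},{v:.9g}\n")


def _data_path(filename: str):
    return resources.files("chronolux") / "data" / filename


def load_sensitivities(directory: str | Path | None = None) -> SensitivitySet:
    """Load the five sensitivity curves from CSVs (bundled synthetic set by default)."""
    curves = []
    wl_ref = None
    for name in RECEPTOR_NAMES:
        fname = _SENSITIVITY_FILES[name]
        path = Path(directory) / fname if directory else _data_path(fname)
        wl, vals = _read_curve_csv(path)
        if wl_ref is None:
            wl_ref = wl
        elif not np.allclose(wl, wl_ref):
            raise ValueError(f"wavelength grid mismatch in {fname}")
        curves.append(vals)
    return SensitivitySet(wl_ref, np.stack(curves))


def load_basis(directory: str | Path | None = None) -> SpectralBasis:
    """Load the three primary spectra from CSVs (bundled fitted set by default)."""
    spectra = []
    wl_ref = None
    for fname in _PRIMARY_FILES:
        path = Path(directory) / fname if directory else _data_path(fname)
        wl, vals = _read_curve_csv(path)
        if wl_ref is None:
            wl_ref = wl
        elif not np.allclose(wl, wl_ref):
            raise ValueError(f"wavelength grid mismatch in {fname}")
        spectra.append(vals)
    return SpectralBasis(wl_ref, np.stack(spectra))


def write_bundled_data(directory: str | Path) -> None:
    """Regenerate the bundled synthetic sensitivity and basis CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sens = synthetic_sensitivities()
    for name in RECEPTOR_NAMES:
        _write_curve_csv(directory / _SENSITIVITY_FILES[name],
                         sens.wavelengths, sens.curve(name))
    basis = fit_primary_basis()
    for i, fname in enumerate(_PRIMARY_FILES):
        _write_curve_csv(directory / fname, basis.wavelengths,
                         basis.primary_spectra[i])


# --------------------------------------------------------------------------
# Activations
# --------------------------------------------------------------------------


def reconstruct_spectrum(rgb, basis: SpectralBasis) -> np.ndarray:
    """Display spectrum of a linear RGB triple: r*P_R + g*P_G + b*P_B."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,):
        raise ValueError("rgb must be a triple")
    return rgb @ basis.primary_spectra


def activation_matrix(basis: SpectralBasis, sens: SensitivitySet) -> np.ndarray:
    """Precomputed 5x3 matrix mapping linear RGB to receptor activations.

    Entry (j, i) is the trapezoidal integral of primary i's spectrum against
    sensitivity j, with each row scaled so white RGB = (1, 1, 1) activates
    each receptor with value 1.
    """
    if basis.wavelengths.shape != sens.wavelengths.shape or not np.allclose(
        basis.wavelengths, sens.wavelengths
    ):
        raise ValueError("basis and sensitivity wavelength grids differ")
    wl = basis.wavelengths
    mat = np.trapezoid(
        sens.curves[:, None, :] * basis.primary_spectra[None, :, :], wl, axis=2
    )
    white = mat.sum(axis=1, keepdims=True)
    return mat / white


def receptor_activations(
    img, basis: SpectralBasis | None = None, sens: SensitivitySet | None = None
) -> ReceptorMaps:
    """Five activation maps for a linear image (white pixel activates at 1).

    Equivalent to integrating each pixel's reconstructed spectrum against
    each sensitivity curve, evaluated through the precomputed 5x3 matrix.
    """
    from .colorimetry import LinearImage

    rgb = img.pixels if isinstance(img, LinearImage) else np.asarray(img, dtype=float)
    if basis is None:
        basis = load_basis()
    if sens is None:
        sens = load_sensitivities()
    mat = activation_matrix(basis, sens)
    act = rgb @ mat.T  # (..., 5)
    return ReceptorMaps(*(act[..., j] for j in range(5)))


def roundtrip_check(basis: SpectralBasis, wp: WhitePoint = D65) -> dict:
    """Max RGB round-trip error over the RGB cube corners.

    For each corner, reconstruct the spectrum, integrate it to XYZ with the
    color-matching functions, convert back to linear RGB, and report the
    worst absolute channel error.  Deterministic for a fixed basis.
    """
    wl = basis.wavelengths
    cmf = cie1931_cmf(wl)
    corners = np.array(
        [[r, g, b] for r in (0.0, 1.0) for g in (0.0, 1.0) for b in (0.0, 1.0)]
    )
    spectra = corners @ basis.primary_spectra  # (8, N)
    xyz = np.trapezoid(spectra[:, :, None] * cmf[None, :, :], wl, axis=1)
    back = xyz_to_rgb(xyz, wp)
    errors = np.abs(back - corners)
    return {
        "max_error": float(errors.max()),
        "per_corner": {tuple(c): float(e.max()) for c, e in zip(map(tuple, corners), errors)},
    }
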