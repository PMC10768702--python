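"""Synthetic outdoor scenes and observer ratings for end-to-end testing.

Real painting corpora cannot be redistributed, so this module fabricates
miniature "paintings" whose illumination parameters are controlled: a
vertical sky gradient toward an illuminant chromaticity drawn from the
Planckian locus (CCT plus a signed Duv offset), a textured ground band with
adjustable mean luminance and contrast, an optional sun disk, and haze
composited as ``I = J*t + A*(1 - t)`` with airlight color A and a
transmission ``t`` that decreases with scene depth (sky far, ground near).

A study interpolates scene parameters between a morning pole (high CCT,
bright, contrasty, cool airlight, more haze) and an evening pole (low CCT,
dim, flat, warm airlight) along a latent time-of-day score in [0, 1] —
the illumination regularities that solar elevation imposes on real
daylight.  Synthetic observers rate each image by quantizing the latent
score plus Gaussian noise onto a rating scale.  All randomness flows
through one explicitly passed seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import colorimetry as cm
from .colorimetry import EncodedImage
from .perception import RatingScale, FOUR_POINT_MERGED

__all__ = [
    "SceneParams",
    "SyntheticStudy",
    "illuminant_rgb",
    "simulate_scene",
    "simulate_observer_ratings",
    "generate_study",
    "MORNING_POLE",
    "EVENING_POLE",
]

# Depth runs from DEPTH_NEAR at the bottom row to 1 at the top row; the
# exponent scale makes haze_density = 1 collapse the image to the airlight.
_DEPTH_NEAR = 0.25
_HAZE_EXPONENT = 3.0


@dataclass(frozen=True)
class SceneParams:
    """Illumination parameters of one synthetic scene."""

    illuminant_cct: float = 6500.0
    illuminant_duv: float = 0.003
    mean_luminance: float = 0.4
    contrast: float = 0.3
    haze_density: float = 0.2
    airlight_cct: float = 6500.0
    sun_disk: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (2000.0 <= self.illuminant_cct <= 15000.0):
            raise ValueError("illuminant_cct must be in [2000, 15000] K")
        if not (2000.0 <= self.airlight_cct <= 15000.0):
            raise ValueError("airlight_cct must be in [2000, 15000] K")
        if not (0.0 <= self.mean_luminance <= 1.0):
            raise ValueError("mean_luminance must be in [0, 1]")
        if self.contrast < 0.0:
            raise ValueError("contrast must be nonnegative")
        if not (0.0 <= self.haze_density <= 1.0):
            raise ValueError("haze_density must be in [0, 1]")


#: Scene parameters of the latent-score endpoints: morning is bright, cool,
#: contrasty and hazier; evening dim, warm, and flat.
MORNING_POLE = dict(
    illuminant_cct=7500.0, mean_luminance=0.60, contrast=0.50,
    haze_density=0.45, airlight_cct=8000.0,
)
EVENING_POLE = dict(
    illuminant_cct=3000.0, mean_luminance=0.18, contrast=0.12,
    haze_density=0.10, airlight_cct=4000.0,
)


def illuminant_rgb(cct: float, duv: float = 0.0,
                   wp: cm.WhitePoint = cm.D65) -> np.ndarray:
    """Linear RGB (unit peak) of a Planckian-locus illuminant with a Duv offset.

    The chromaticity is the locus point at ``cct`` displaced ``duv`` along
    the locus normal (positive toward green); out-of-gamut channels are
    clipped to [0, 1].
    """
    uv0 = cm.planck_uv(cct)
    tang = cm.planck_uv(cct + 10.0) - cm.planck_uv(cct - 10.0)
    normal = np.array([-tang[1], tang[0]])
    normal /= np.linalg.norm(normal)
    if normal[1] < 0:
        normal = -normal
    xy = cm.uv_to_xy(uv0 + duv * normal)
    xyz = cm.xy_to_xyz(xy, 1.0)
    rgb = cm.xyz_to_rgb(xyz, wp)
    rgb = np.clip(rgb, 0.0, None)
    return rgb / rgb.max()


def _smooth_noise(rng: np.random.Generator, shape, sigma: float = 2.0) -> np.ndarray:
    """Zero-mean, unit-SD smooth random field (Gaussian-filtered white noise)."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def simulate_scene(
    p: SceneParams,
    size: tuple[int, int] = (96, 128),
    gamma: float = cm.DEFAULT_GAMMA,
    wp: cm.WhitePoint = cm.D65,
) -> EncodedImage:
    """Render one synthetic scene; bit-identical for a fixed seed.

    The sky band (upper 55%) blends from near-white at the zenith toward
    the illuminant color at the horizon; the ground band is an albedo
    texture lit by the illuminant at the requested mean luminance and
    contrast; haze is composited with a transmission that falls with depth
    and density, ``t = (1 - haze_density)**(3 * depth)``.
    """
    h, w = size
    if h < 8 or w < 8:
        raise ValueError("scene must be at least 8 x 8 pixels")
    rng = np.random.default_rng(p.seed)
    horizon = int(round(0.55 * h))

    illum = illuminant_rgb(p.illuminant_cct, p.illuminant_duv, wp)
    sky_brightness = np.clip(0.55 + 0.5 * p.mean_luminance, 0.0, 1.0)

    J = np.zeros((h, w, 3))
    # Sky: vertical gradient from a whitened zenith toward the illuminant.
    rows = np.arange(horizon) / max(horizon - 1, 1)
    zenith = 0.35 * illum + 0.65 * np.ones(3)
    sky = (1.0 - rows[:, None]) * zenith[None, :] + rows[:, None] * illum[None, :]
    J[:horizon] = sky[:, None, :] * sky_brightness

    # Ground: noisy albedo lit by the illuminant.
    albedo = np.array([0.52, 0.48, 0.38])  # earthy, slightly yellow
    tex = 1.0 + p.contrast * _smooth_noise(rng, (h - horizon, w))
    tex = np.clip(tex, 0.0, None)
    ground = (p.mean_luminance * tex)[:, :, None] * (albedo * illum)[None, None, :]
    J[horizon:] = ground

    if p.sun_disk:
        cy, cx = int(0.8 * horizon), int(rng.integers(w // 4, 3 * w // 4))
        yy, xx = np.ogrid[:h, :w]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= max(2, h // 24) ** 2
        J[disk] = np.clip(illum * 1.5, 0.0, 1.0)

    # Haze compositing toward the airlight color.
    A = illuminant_rgb(p.airlight_cct, 0.0, wp) * np.clip(
        0.6 + 0.4 * p.mean_luminance, 0.0, 1.0
    )
    depth = 1.0 - (1.0 - _DEPTH_NEAR) * (np.arange(h) / max(h - 1, 1))
    t = (1.0 - p.haze_density) ** (_HAZE_EXPONENT * depth)
    I = J * t[:, None, None] + A[None, None, :] * (1.0 - t[:, None, None])
    I = np.clip(I, 0.0, 1.0)
    return EncodedImage(np.power(I, 1.0 / gamma))


def simulate_observer_ratings(
    latent: float,
    n_obs: int,
    noise_sd: float,
    scale: RatingScale = FOUR_POINT_MERGED,
    seed: int | np.random.Generator = 0,
    image_id: str = "img",
    observer_offset: int = 0,
) -> pd.DataFrame:
    """Categorical ratings from a noisy latent time-of-day score.

    Each observer responds with the category whose scale score is nearest
    to ``divisor * (latent + N(0, noise_sd))``, clipped to the scale range
    (ties break toward the earlier category).  Reproducible for a fixed
    seed or generator.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cats = scale.categories
    cat_scores = np.array([scale.score(c) for c in cats])
    lo, hi = cat_scores.min(), cat_scores.max()
    target = scale.divisor * (latent + rng.normal(0.0, noise_sd, size=n_obs))
    target = np.clip(target, lo, hi)
    idx = np.argmin(np.abs(target[:, None] - cat_scores[None, :]), axis=1)
    return pd.DataFrame(
        {
            "observer_id": [f"obs{observer_offset + i:03d}" for i in range(n_obs)],
            "image_id": image_id,
            "category": [cats[i] for i in idx],
        }
    )


@dataclass
class SyntheticStudy:
    """A complete simulated experiment: images, truth, and ratings."""

    images: dict  # image_id -> EncodedImage
    truth: pd.DataFrame  # image_id, latent, and the SceneParams fields
    ratings: pd.DataFrame
    config: dict = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        """Serialize to PNG images plus truth/ratings CSVs and a metadata JSON."""
        from PIL import Image

        directory = Path(directory)
        (directory / "images").mkdir(parents=True, exist_ok=True)
        for image_id, img in sorted(self.images.items()):
            arr = np.round(img.pixels * 255.0).astype(np.uint8)
            Image.fromarray(arr).save(directory / "images" / f"{image_id}.png")
        self.truth.to_csv(directory / "truth.csv", index=False)
        self.ratings.to_csv(directory / "ratings.csv", index=False)
        (directory / "study.json").write_text(json.dumps(self.config, indent=1))


def generate_study(
    n_images: int,
    n_obs: int = 20,
    noise_sd: float = 0.1,
    seed: int = 0,
    size: tuple[int, int] = (96, 128),
    scale: RatingScale = FOUR_POINT_MERGED,
    morning_pole: dict | None = None,
    evening_pole: dict | None = None,
    illuminant_duv: float = 0.003,
) -> SyntheticStudy:
    """Generate a full synthetic study with known latent time-of-day scores.

    Latent scores are evenly spaced over [0, 1]; scene parameters are
    linearly interpolated between the morning pole (latent 0) and the
    evening pole (latent 1).  Every image receives ``n_obs`` ratings.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images")
    m = dict(MORNING_POLE, **(morning_pole or {}))
    e = dict(EVENING_POLE, **(evening_pole or {}))
    if set(m) != set(e):
        raise ValueError("pole parameter sets must match")
    rng = np.random.default_rng(seed)
    latents = np.linspace(0.0, 1.0, n_images)

    images: dict[str, EncodedImage] = {}
    truth_rows = []
    rating_frames = []
    for i, lat in enumerate(latents):
        interp = {k: (1.0 - lat) * m[k] + lat * e[k] for k in m}
        p = SceneParams(
            illuminant_duv=illuminant_duv,
            sun_disk=False,
            seed=int(rng.integers(0, 2**31 - 1)),
            **interp,
        )
        image_id = f"img{i:04d}"
        images[image_id] = simulate_scene(p, size=size)
        truth_rows.append({"image_id": image_id, "latent": lat, **asdict(p)})
        rating_frames.append(
            simulate_observer_ratings(
                lat, n_obs, noise_sd, scale, rng, image_id=image_id
            )
        )
    truth = pd.DataFrame(truth_rows)
    ratings = pd.concat(rating_frames, ignore_index=True)
    config = {
        "n_images": n_images,
        "n_obs": n_obs,
        "noise_sd": noise_sd,
        "seed": seed,
        "size": list(size),
        "scale": scale.name,
        "morning_pole": m,
        "evening_pole": e,
        "illuminant_duv": illuminant_duv,
    }
    return SyntheticStudy(images, truth, ratings, config)
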