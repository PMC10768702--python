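"""Image/table I/O and the batch pipeline driver.

Reads PNG/JPEG images into [0, 1] encoded arrays, standardizes their size
(longer side to 1,000 pixels by default, aspect ratio preserved,
area-averaged resampling), and runs the full analysis over a directory:
per-image statistics and airlight estimates, and — when observer ratings
are supplied — score summaries, the PCA model, the forward-AIC regression
models, per-image predictions, and per-category covariance ellipses.

Every output embeds the configuration hash so results are traceable; reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

from . import colorimetry as cm
from . import image_stats as ist
from . import perception as per
from .colorimetry import EncodedImage
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["load_image", "resize_longest_side", "run_pipeline"]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def load_image(path: str | Path) -> EncodedImage:
    """Read a PNG/JPEG into an encoded RGB array scaled to [0, 1].

    Alpha channels are dropped and single-channel images replicated to
    three channels, each with a logged warning.  Unreadable files raise an
    IOError naming the path.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        logger.warning("%s: greyscale image replicated to 3 channels", path.name)
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("%s: alpha channel dropped", path.name)
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"cannot read image {path}: unsupported shape {arr.shape}")
    return EncodedImage(np.clip(arr, 0.0, 1.0))


def resize_longest_side(img: EncodedImage, target: int = 1000) -> EncodedImage:
    """Resize so the longer side equals ``target``, keeping the aspect ratio.

    Uses area-averaging (anti-aliased box) resampling, which best preserves
    mean statistics.  Images whose longer side is already at or below the
    target are returned unchanged (upsampling would fabricate detail).
    """
    if target < 1:
        raise ValueError("target must be at least 1 pixel")
    h, w = img.height, img.width
    longest = max(h, w)
    if longest <= target:
        return img
    scale = target / longest
    new_w = max(1, int(round(w * scale)))
    new_h = max(1, int(round(h * scale)))
    channels = [
        np.asarray(
            Image.fromarray(img.pixels[:, :, c].astype(np.float32), mode="F").resize(
                (new_w, new_h), resample=Image.Resampling.BOX
            )
        )
        for c in range(3)
    ]
    return EncodedImage(np.clip(np.stack(channels, axis=2).astype(float), 0.0, 1.0))


def _list_images(image_dir: Path) -> list[Path]:
    return sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )


def run_pipeline(
    cfg: PipelineConfig,
    image_dir: str | Path,
    out_dir: str | Path,
    ratings_path: str | Path | None = None,
) -> dict:
    """Run the full analysis over an image directory; write outputs to disk.

    Always writes ``statistics.csv`` (one row per image, 30 named columns)
    and ``airlight.csv``.  With a ratings table, also writes ``scores.csv``,
    ``pca_model.json``, ``regression_models.json``, ``predictions.csv``,
    and ``ellipses.csv``.  Per-image failures are logged and skipped; the
    run fails only on global errors.  Returns a manifest of written files.
    """
    image_dir = Path(image_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash
    logger.info("pipeline start: config_hash=%s seed=%d", chash, cfg.seed)

    paths = _list_images(image_dir)
    if not paths:
        raise ValueError(f"no images found in {image_dir}")
    wp = cfg.resolved_white_point()

    stat_rows, air_rows, skipped = [], [], []
    for path in paths:
        image_id = path.stem
        try:
            img = resize_longest_side(load_image(path), cfg.resize_target)
            stats = ist.extract_statistics(img, cfg)
            linear = cm.decode_srgb(img, cfg.gamma)
            air = ist.estimate_airlight(
                linear, cfg.airlight_patch, cfg.airlight_top_frac, wp
            )
        except Exception as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            skipped.append(image_id)
            continue
        stat_rows.append(pd.Series(stats.values, index=list(stats.names),
                                   name=image_id))
        air_rows.append(
            pd.Series(
                {
                    "r": air.rgb[0], "g": air.rgb[1], "b": air.rgb[2],
                    "x": air.xy[0], "y": air.xy[1],
                    "cct": air.cct, "duv": air.duv,
                    "n_pixels_used": air.n_pixels_used,
                },
                name=image_id,
            )
        )
    if not stat_rows:
        raise ValueError("every image failed; nothing to write")

    stats_df = pd.DataFrame(stat_rows).sort_index()
    stats_df.index.name = "image_id"
    air_df = pd.DataFrame(air_rows).sort_index()
    air_df.index.name = "image_id"
    for df in (stats_df, air_df):
        df["config_hash"] = chash

    manifest = {"config_hash": chash, "skipped": skipped}
    stats_path = out_dir / "statistics.csv"
    stats_df.to_csv(stats_path)
    air_df.to_csv(out_dir / "airlight.csv")
    manifest["statistics"] = str(stats_path)
    manifest["airlight"] = str(out_dir / "airlight.csv")

    if ratings_path is not None:
        ratings = pd.read_csv(ratings_path)
        scale = per.get_scale(cfg.scale)
        scores = per.score_ratings(ratings, scale)
        scores["config_hash"] = chash
        scores.to_csv(out_dir / "scores.csv")
        manifest["scores"] = str(out_dir / "scores.csv")

        feature_df = stats_df.drop(columns=["config_hash"])
        common = feature_df.index.intersection(scores.index)
        if len(common) < 5:
            raise ValueError("too few images with both statistics and ratings")
        X = feature_df.loc[common]
        y = scores.loc[common, "normalized_mean"].to_numpy()

        pca = per.fit_pca(X, config_hash=chash)
        pca.to_json(out_dir / "pca_model.json")
        manifest["pca_model"] = str(out_dir / "pca_model.json")

        pcs = pca.transform(X)
        models, selected = per.forward_aic_regression(pcs, y)
        models_payload = {
            "config_hash": chash,
            "seed": cfg.seed,
            "models": [m.to_dict() for m in models],
            "selected": selected.to_dict(),
        }
        (out_dir / "regression_models.json").write_text(
            json.dumps(models_payload, indent=1)
        )
        manifest["regression_models"] = str(out_dir / "regression_models.json")

        k = len(selected.predictors)
        pred_df = pd.DataFrame(
            pcs[:, : max(k, 2)],
            index=common,
            columns=[f"PC{i + 1}" for i in range(max(k, 2))],
        )
        pred_df["observed"] = y
        pred_df["predicted"] = selected.predict(pcs[:, :k])
        pred_df["config_hash"] = chash
        pred_df.index.name = "image_id"
        pred_df.to_csv(out_dir / "predictions.csv")
        manifest["predictions"] = str(out_dir / "predictions.csv")

        ellipse_rows = []
        for cat, group in scores.loc[common].groupby("categorical"):
            pts = pred_df.loc[group.index, ["PC1", "PC2"]].to_numpy()
            if len(pts) < 3:
                logger.warning("category %s has <3 images; no ellipse", cat)
                continue
            ell = per.covariance_ellipse(pts)
            ellipse_rows.append(
                {
                    "category": cat,
                    "center_pc1": ell.center[0],
                    "center_pc2": ell.center[1],
                    "semi_major": ell.semi_axes[0],
                    "semi_minor": ell.semi_axes[1],
                    "angle_deg": ell.angle_deg,
                    "coverage": ell.coverage,
                    "degenerate": ell.degenerate,
                    "n_points": len(pts),
                    "config_hash": chash,
                }
            )
        pd.DataFrame(ellipse_rows).to_csv(out_dir / "ellipses.csv", index=False,
                                          )
        manifest["ellipses"] = str(out_dir / "ellipses.csv")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline done: %d images, %d skipped", len(stat_rows), len(skipped))
    return manifest
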