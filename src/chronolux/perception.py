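"""Observer-rating scores and the PCA + forward-AIC time-of-day model.

Observers label images with time-of-day categories.  Ratings are scored on
chronological scales — a 7-point scale (sunrise=1 ... night=7, with sunset
placed before evening), a 4-point merged scale (morning/sunrise=1,
noon/afternoon=3, evening/sunset=5, night=7), or a binary morning=0 /
evening=1 scale — and summarized per image as the mean score, the
normalized mean (mean divided by the top score), per-category proportions,
and the modal category.

The image-statistics matrix is reduced by PCA on z-scored features
(correlation-matrix PCA), retaining components with eigenvalues greater
than 1 (Kaiser criterion), with signs oriented so that mean luminance
loads negatively on PC1 and mean saturation negatively on PC2.  Nested
linear models on PC1, PC1+PC2, ... are compared by AIC
(n*ln(RSS/n) + 2k, k = predictors + 1) and Akaike weights; forward
selection stops at the first component whose addition fails to lower the
AIC.  The published two-component model

    mean time-of-day rating = 0.583 + 0.034*PC1 + 0.017*PC2

is shipped as a frozen, versioned asset for prediction without refitting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from sklearn.decomposition import PCA as _SKPCA

logger = logging.getLogger(__name__)

__all__ = [
    "CHRONOLOGICAL_ORDER",
    "RatingScale",
    "SEVEN_POINT",
    "FOUR_POINT_MERGED",
    "BINARY",
    "get_scale",
    "validate_ratings",
    "filter_observers",
    "score_ratings",
    "PCAModel",
    "fit_pca",
    "project",
    "RegressionModel",
    "forward_aic_regression",
    "load_published_model",
    "predict_time_of_day",
    "CovarianceEllipse",
    "covariance_ellipse",
    "classify_morning_evening",
]

#: The seven categories in the scored chronological order (sunset before
#: evening, as the scales define it).
CHRONOLOGICAL_ORDER = (
    "sunrise", "morning", "noon", "afternoon", "sunset", "evening", "night",
)


@dataclass(frozen=True)
class RatingScale:
    """A chronological scoring of rating categories.

    ``divisor`` is the top score; the normalized mean is mean / divisor.
    """

    name: str
    mapping: dict
    divisor: float

    @property
    def categories(self) -> tuple:
        return tuple(c for c in CHRONOLOGICAL_ORDER if c in self.mapping)

    def score(self, category: str) -> float:
        return float(self.mapping[category])


SEVEN_POINT = RatingScale(
    "seven_point",
    {c: i + 1 for i, c in enumerate(CHRONOLOGICAL_ORDER)},
    7.0,
)

FOUR_POINT_MERGED = RatingScale(
    "four_point_merged",
    {"sunrise": 1, "morning": 1, "noon": 3, "afternoon": 3,
     "sunset": 5, "evening": 5, "night": 7},
    7.0,
)

BINARY = RatingScale("binary", {"morning": 0, "evening": 1}, 1.0)

_SCALES = {s.name: s for s in (SEVEN_POINT, FOUR_POINT_MERGED, BINARY)}


def get_scale(name: str) -> RatingScale:
    if name not in _SCALES:
        raise ValueError(f"unknown scale {name!r}; choose from {sorted(_SCALES)}")
    return _SCALES[name]


# --------------------------------------------------------------------------
# Rating tables
# --------------------------------------------------------------------------

_RATING_COLUMNS = ("observer_id", "image_id", "category")


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check the (observer_id, image_id, category) table shape and uniqueness."""
    missing = set(_RATING_COLUMNS) - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    dup = ratings.duplicated(subset=["observer_id", "image_id"])
    if dup.any():
        raise ValueError("more than one rating per observer x image")
    return ratings


def filter_observers(
    ratings: pd.DataFrame,
    catch_ids,
    correct_label: str,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Drop observers below the catch-trial accuracy threshold (default 80%).

    Observers whose fraction of correct responses on the catch images is
    below ``threshold`` are removed entirely.  Observers with no catch
    trials — or an empty catch set — are retained with a logged warning.
    """
    validate_ratings(ratings)
    catch_ids = set(catch_ids)
    if not catch_ids:
        logger.warning("empty catch set: no observers excluded")
        return ratings
    catch = ratings[ratings["image_id"].isin(catch_ids)]
    keep = []
    for obs, group in ratings.groupby("observer_id", sort=False):
        obs_catch = catch[catch["observer_id"] == obs]
        if obs_catch.empty:
            logger.warning("observer %r has no catch trials; retained", obs)
            keep.append(obs)
            continue
        frac = (obs_catch["category"] == correct_label).mean()
        if frac >= threshold:
            keep.append(obs)
    return ratings[ratings["observer_id"].isin(keep)].reset_index(drop=True)


def score_ratings(ratings: pd.DataFrame, scale: RatingScale) -> pd.DataFrame:
    """Per-image score summary on the given scale.

    Returns a DataFrame indexed by image id with the mean score, the
    normalized mean (mean / divisor), one proportion column per category,
    the modal category (ties break to the earliest chronological category,
    recorded in ``mode_tied``), and the number of ratings.  Records with
    labels outside the scale vocabulary are rejected with their ids logged.
    """
    validate_ratings(ratings)
    known = ratings["category"].isin(scale.mapping)
    if not known.all():
        bad = ratings.loc[~known]
        logger.warning(
            "rejected %d ratings with unknown categories: %s",
            len(bad), sorted(bad["category"].unique()),
        )
        ratings = ratings[known]
    if ratings.empty:
        raise ValueError("no valid ratings to score")

    cats = scale.categories
    rows = []
    for image_id, group in ratings.groupby("image_id", sort=True):
        scores = group["category"].map(scale.mapping).astype(float)
        counts = group["category"].value_counts()
        props = {f"prop_{c}": counts.get(c, 0) / len(group) for c in cats}
        # the mode is taken over scores, so categories merged by the scale
        # pool their counts; ties break to the earlier (lower) score
        score_counts = scores.value_counts()
        top = score_counts.max()
        modal_scores = sorted(s for s, c in score_counts.items() if c == top)
        modal_score = modal_scores[0]
        categorical = next(c for c in cats if scale.score(c) == modal_score)
        row = {
            "image_id": image_id,
            "mean_score": scores.mean(),
            "normalized_mean": scores.mean() / scale.divisor,
            "modal_score": modal_score,
            "categorical": categorical,
            "mode_tied": len(modal_scores) > 1,
            "n_ratings": len(group),
        }
        row.update(props)
        rows.append(row)
    return pd.DataFrame(rows).set_index("image_id")


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Standardization parameters, loadings, and eigenvalues of a fitted PCA.

    ``loadings`` has one column per component (orthonormal); eigenvalues
    are those of the feature correlation matrix (nonincreasing);
    ``n_retained`` counts eigenvalues greater than 1 (Kaiser criterion).
    """

    feature_names: tuple
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (p, k_all)
    eigenvalues: np.ndarray
    n_retained: int
    sign_flips: tuple = ()
    dropped_features: tuple = ()
    n_imputed: int = 0
    config_hash: str | None = None

    @property
    def component_names(self) -> tuple:
        return tuple(f"PC{i + 1}" for i in range(self.n_retained))

    def transform(self, stats, n_components: int | None = None) -> np.ndarray:
        """Standardize and project onto the retained components."""
        k = self.n_retained if n_components is None else n_components
        if isinstance(stats, pd.DataFrame):
            missing = set(self.feature_names) - set(stats.columns)
            if missing:
                raise ValueError(f"missing features: {sorted(missing)}")
            X = stats[list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(stats, dtype=float))
            if X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features, got {X.shape[1]}"
                )
        Z = (X - self.means) / self.sds
        return Z @ self.loadings[:, :k]

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_retained": self.n_retained,
            "sign_flips": list(self.sign_flips),
            "dropped_features": list(self.dropped_features),
            "n_imputed": self.n_imputed,
            "config_hash": self.config_hash,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            feature_names=tuple(d["feature_names"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            loadings=np.array(d["loadings"]),
            eigenvalues=np.array(d["eigenvalues"]),
            n_retained=int(d["n_retained"]),
            sign_flips=tuple(d.get("sign_flips", ())),
            dropped_features=tuple(d.get("dropped_features", ())),
            n_imputed=int(d.get("n_imputed", 0)),
            config_hash=d.get("config_hash"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_pca(
    stats,
    feature_names=None,
    config_hash: str | None = None,
) -> PCAModel:
    """Correlation-matrix PCA of an images x features statistics matrix.

    Features are z-scored (sample SD); missing entries are mean-imputed
    with a logged count; constant features are dropped with a warning.
    Components with eigenvalues greater than 1 are retained.  Signs are
    oriented so mean luminance loads negatively on PC1 and mean saturation
    negatively on PC2 (when those features are present); every other
    component is oriented so its largest-magnitude loading is positive.
    """
    if isinstance(stats, pd.DataFrame):
        feature_names = tuple(stats.columns)
        X = stats.to_numpy(dtype=float)
    else:
        X = np.asarray(stats, dtype=float)
        if feature_names is None:
            feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
        feature_names = tuple(feature_names)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 images")

    n_imputed = int(np.isnan(X).sum())
    if n_imputed:
        logger.warning("mean-imputing %d missing statistic entries", n_imputed)
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)

    sds_all = X.std(axis=0, ddof=1)
    constant = sds_all == 0.0
    dropped = tuple(np.array(feature_names)[constant])
    if dropped:
        logger.warning("dropping constant features before PCA: %s", dropped)
        X = X[:, ~constant]
        feature_names = tuple(np.array(feature_names)[~constant])

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    Z = (X - means) / sds
    pca = _SKPCA(svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T  # (p, k)
    eigenvalues = pca.explained_variance_

    flips = []
    names = list(feature_names)
    for j in range(loadings.shape[1]):
        anchor = None
        if j == 0 and "mean_luminance" in names:
            anchor = ("mean_luminance", -1.0)
        elif j == 1 and "mean_saturation" in names:
            anchor = ("mean_saturation", -1.0)
        if anchor is not None:
            val = loadings[names.index(anchor[0]), j]
            want_flip = np.sign(val) == -anchor[1] and val != 0.0
        else:
            imax = int(np.argmax(np.abs(loadings[:, j])))
            want_flip = loadings[imax, j] < 0.0
        if want_flip:
            loadings[:, j] *= -1.0
            flips.append(j)

    n_retained = max(1, int((eigenvalues > 1.0).sum()))
    return PCAModel(
        feature_names=feature_names,
        means=means,
        sds=sds,
        loadings=loadings,
        eigenvalues=eigenvalues,
        n_retained=n_retained,
        sign_flips=tuple(flips),
        dropped_features=dropped,
        n_imputed=n_imputed,
        config_hash=config_hash,
    )


def project(model: PCAModel, stats) -> np.ndarray:
    """PC coordinates of one statistics vector (or a matrix of them)."""
    out = model.transform(stats)
    return out[0] if np.asarray(stats).ndim == 1 else out


# --------------------------------------------------------------------------
# Forward-AIC regression
# --------------------------------------------------------------------------


@dataclass
class RegressionModel:
    """One OLS fit of the time-of-day score on leading PCs."""

    predictors: tuple
    intercept: float
    coefficients: np.ndarray
    r2: float
    adjusted_r2: float
    aic: float
    akaike_weight: float = float("nan")
    selected: bool = False
    n: int = 0

    def predict(self, pcs) -> np.ndarray | float:
        pcs = np.asarray(pcs, dtype=float)
        scalar = pcs.ndim == 1
        pcs = np.atleast_2d(pcs)
        if pcs.shape[1] != len(self.predictors):
            raise ValueError(
                f"model has {len(self.predictors)} predictors, got {pcs.shape[1]}"
            )
        out = self.intercept + pcs @ np.asarray(self.coefficients, dtype=float)
        return float(out[0]) if scalar else out

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "intercept": self.intercept,
            "coefficients": np.asarray(self.coefficients).tolist(),
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "aic": self.aic,
            "akaike_weight": self.akaike_weight,
            "selected": self.selected,
            "n": self.n,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        return cls(
            predictors=tuple(d["predictors"]),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            r2=float(d.get("r2", float("nan"))),
            adjusted_r2=float(d.get("adjusted_r2", float("nan"))),
            aic=float(d.get("aic", float("nan"))),
            akaike_weight=float(d.get("akaike_weight", float("nan"))),
            selected=bool(d.get("selected", False)),
            n=int(d.get("n", 0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _aic(n: int, rss: float, n_predictors: int) -> float:
    # k counts the intercept; the additive constant is conventional and
    # cancels in AIC differences.
    return n * np.log(rss / n) + 2.0 * (n_predictors + 1)


def forward_aic_regression(
    pcs: np.ndarray,
    response: np.ndarray,
    component_names=None,
) -> tuple[list[RegressionModel], RegressionModel]:
    """Nested OLS fits on PC1, PC1+PC2, ... compared by AIC.

    Adds one component at a time in order and computes, for every candidate,
    AIC = n*ln(RSS/n) + 2k (k = predictors + 1) and its Akaike weight.
    Selection follows the forward stepwise rule: components are added only
    while the AIC strictly improves, and the first non-improving addition
    stops the search.  When the AIC profile has a single minimum — the
    typical case with components ordered by explained variance — this is
    the minimum-AIC (maximum Akaike weight) candidate.  Returns
    (all candidates, selected).
    """
    X = np.asarray(pcs, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("pcs must be (n, k) aligned with response")
    n, k = X.shape
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < k + 1:
        raise ValueError("rank-deficient predictor matrix")
    if component_names is None:
        component_names = tuple(f"PC{i + 1}" for i in range(k))

    models: list[RegressionModel] = []
    for j in range(1, k + 1):
        design = sm.add_constant(X[:, :j])
        fit = sm.OLS(y, design).fit()
        rss = float(fit.ssr)
        models.append(
            RegressionModel(
                predictors=tuple(component_names[:j]),
                intercept=float(fit.params[0]),
                coefficients=np.asarray(fit.params[1:], dtype=float),
                r2=float(fit.rsquared),
                adjusted_r2=float(fit.rsquared_adj),
                aic=_aic(n, rss, j),
                n=n,
            )
        )
    aics = np.array([m.aic for m in models])
    delta = aics - aics.min()
    rel = np.exp(-0.5 * delta)
    weights = rel / rel.sum()
    for m, w in zip(models, weights):
        m.akaike_weight = float(w)
    # forward stepwise stopping: keep adding components only while the AIC
    # strictly improves; the first non-improving addition ends the search
    best = 0
    while best + 1 < len(models) and models[best + 1].aic < models[best].aic:
        best += 1
    models[best].selected = True
    return models, models[best]


# --------------------------------------------------------------------------
# Published (frozen) model
# --------------------------------------------------------------------------


def load_published_model() -> RegressionModel:
    """The frozen published two-component model (versioned JSON asset)."""
    path = resources.files("chronolux") / "data" / "published_model.json"
    with resources.as_file(path) as p:
        return RegressionModel.from_json(p)


def predict_time_of_day(pc1: float, pc2: float,
                        model: RegressionModel | None = None) -> float:
    """Predicted normalized mean time-of-day score at (PC1, PC2).

    Uses the frozen published model unless another two-predictor model is
    given.
    """
    if model is None:
        model = load_published_model()
    if len(model.predictors) != 2:
        raise ValueError("predict_time_of_day requires a two-predictor model")
    return model.predict(np.array([pc1, pc2], dtype=float))


# --------------------------------------------------------------------------
# Covariance ellipses and binary classification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CovarianceEllipse:
    """Coverage ellipse of a 2-D point cloud (center, semi-axes, orientation)."""

    center: np.ndarray
    semi_axes: np.ndarray  # (major, minor)
    angle_deg: float  # orientation of the major axis, CCW from +x
    coverage: float
    degenerate: bool = False

    def contains(self, points) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        t = np.radians(self.angle_deg)
        R = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
        q = p @ R.T
        return (q[:, 0] / self.semi_axes[0]) ** 2 + (
            q[:, 1] / self.semi_axes[1]
        ) ** 2 <= 1.0


def covariance_ellipse(points, coverage: float = 0.68) -> CovarianceEllipse:
    """Ellipse enclosing the given fraction of a bivariate-normal cloud.

    Centered on the mean, axes along the covariance eigenvectors, with
    semi-axis lengths sqrt(eigenvalue * q) where q is the chi-square(2 df)
    quantile at the coverage level (the bivariate region, not the per-axis
    one-sigma band).  Collinear input yields a degenerate-flagged ellipse.
    """
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must be in (0, 1)")
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2 or P.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    center = P.mean(axis=0)
    cov = np.cov(P.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = bool(evals[1] <= max(evals[0], 1.0) * 1e-12)
    q = chi2.ppf(coverage, df=2)
    semi = np.sqrt(np.maximum(evals, 0.0) * q)
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return CovarianceEllipse(center, semi, angle, coverage, degenerate)


def classify_morning_evening(summary: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Morning/evening labels from binary-scale mean scores.

    Mean below the threshold is morning, above is evening; means exactly at
    the threshold are flagged 'tie' (excluded from counts).
    """
    means = summary["mean_score"]
    labels = pd.Series(
        np.where(means < threshold, "morning",
                 np.where(means > threshold, "evening", "tie")),
        index=summary.index,
        name="label",
    )
    return labels
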