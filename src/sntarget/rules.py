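"""Learned targeting rules: GP classifiers, probability maps, depth rule.

Two independent binary Gaussian-process classifiers are trained - one for
SNr engagement, one for SNc engagement - on the four trajectory features
(X, Y offsets at the max-RN plane; midsagittal and AC-PC plane angles).
The kernel is an anisotropic squared-exponential over z-scored features
with a Bernoulli observation model; being Bayesian, predictions revert to
the prior p = 0.5 far from the training data.  Probability maps over a
feature grid yield "rules of thumb": per (X, Y) panel, the angle
combinations whose predicted engagement probability reaches a threshold
(default 0.95), summarized as conservative axis-aligned angle bounds.

A separate one-dimensional logistic model maps arc-length depth below the
max-RN plane to the probability that a contact sits in the SN, and reports
the minimum depth at which that probability reaches 95%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .atlas import LabelAtlas
from .geometry import trajectory_norm
from .models import Lead

__all__ = [
    "GpcConfig",
    "GpcModel",
    "CvReport",
    "GridSpec",
    "RuleMap",
    "RulePanel",
    "DepthRule",
    "train_gpc",
    "cross_validate",
    "permutation_null_accuracy",
    "probability_map",
    "extract_rules",
    "rule_precision",
    "fit_depth_rule",
    "on_track",
]

FEATURE_NAMES = ("x_mm", "y_mm", "ms_angle_deg", "acpc_angle_deg")


@dataclass(frozen=True)
class GpcConfig:
    """Kernel and optimizer settings for the engagement classifiers."""

    seed: int = 0
    optimize_hyperparams: bool = True
    n_restarts: int = 2
    lengthscale_init: float = 1.0  # in z-scored feature units
    lengthscale_bounds: tuple[float, float] = (1e-1, 1e3)
    variance_bounds: tuple[float, float] = (1e-2, 1e3)


def _as_feature_array(features) -> np.ndarray:
    """Coerce a feature table / array / list of TrajectoryFeatures to (n, 4)."""
    if hasattr(features, "loc") and hasattr(features, "columns"):  # DataFrame
        cols = [c for c in FEATURE_NAMES if c in features.columns]
        if len(cols) == 4:
            return features[list(cols)].to_numpy(dtype=float)
        return features.to_numpy(dtype=float)
    if isinstance(features, (list, tuple)) and features and hasattr(features[0], "as_array"):
        return np.stack([f.as_array() for f in features])
    return np.asarray(features, dtype=float)


@dataclass
class GpcModel:
    """A fitted engagement classifier for one SN compartment."""

    region: str
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    gpc: GaussianProcessClassifier
    config: GpcConfig

    def predict_proba(self, features) -> np.ndarray:
        """P(engagement) for each row of ``features``."""
        X = (_as_feature_array(features) - self.feature_mean) / self.feature_sd
        return self.gpc.predict_proba(X)[:, 1]

    @property
    def lengthscales(self) -> np.ndarray:
        """Fitted kernel lengthscales in original feature units."""
        rbf = self.gpc.kernel_.k2
        return np.asarray(rbf.length_scale, dtype=float) * self.feature_sd


def train_gpc(features, labels, region: str = "SNr", config: GpcConfig | None = None) -> GpcModel:
    """Fit a binary GP classifier for engagement of ``region``.

    Features are z-scored per column; the kernel is variance * anisotropic
    RBF with hyperparameters chosen by marginal-likelihood optimization
    (seeded restarts) unless ``config.optimize_hyperparams`` is false.
    """
    config = config or GpcConfig()
    X = _as_feature_array(features)
    y = np.asarray(labels).astype(int).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, d) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            f"need >= 2 examples of each class; got {counts[0]} negative, {counts[1]} positive"
        )
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    kernel = ConstantKernel(1.0, config.variance_bounds) * RBF(
        np.full(Z.shape[1], config.lengthscale_init), config.lengthscale_bounds
    )
    gpc = GaussianProcessClassifier(
        kernel=kernel,
        optimizer="fmin_l_bfgs_b" if config.optimize_hyperparams else None,
        n_restarts_optimizer=config.n_restarts if config.optimize_hyperparams else 0,
        random_state=config.seed,
    )
    gpc.fit(Z, y)
    return GpcModel(region, mean, sd, gpc, config)


# ----------------------------------------------------------------- validation


@dataclass(frozen=True)
class CvReport:
    """Pooled out-of-fold cross-validation results."""

    k: int
    seed: int
    confidence_threshold: float
    overall_accuracy: float
    confident_accuracy: float | None  # None when no prediction is confident
    confident_fraction: float
    n: int
    oof_prob: np.ndarray = field(repr=False)  # out-of-fold P(engagement)
    labels: np.ndarray = field(repr=False)


def cross_validate(
    features,
    labels,
    k: int = 5,
    confidence_threshold: float = 0.95,
    seed: int = 0,
    config: GpcConfig | None = None,
    refit_hyperparams_per_fold: bool = False,
) -> CvReport:
    """Stratified k-fold CV of the GP classifier, pooled out of fold.

    Kernel hyperparameters are optimized once on the full data and held
    fixed across folds (set ``refit_hyperparams_per_fold`` to re-optimize
    inside every training fold).  The confident subset contains predictions
    whose max-class probability reaches ``confidence_threshold``.
    """
    config = config or GpcConfig(seed=seed)
    X = _as_feature_array(features)
    y = np.asarray(labels).astype(int).ravel()
    if len(y) < k:
        raise ValueError(f"need at least k={k} samples")
    if np.bincount(y, minlength=2).min() < k:
        raise ValueError("each class needs at least k members for stratified folds")

    base = train_gpc(X, y, config=config)
    oof = np.empty(len(y), dtype=float)
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in folds.split(X, y):
        if refit_hyperparams_per_fold:
            model = train_gpc(X[train_idx], y[train_idx], config=config)
        else:
            Z = (X[train_idx] - base.feature_mean) / base.feature_sd
            gpc = GaussianProcessClassifier(kernel=base.gpc.kernel_, optimizer=None)
            gpc.fit(Z, y[train_idx])
            model = GpcModel(base.region, base.feature_mean, base.feature_sd, gpc, config)
        oof[test_idx] = model.predict_proba(X[test_idx])

    pred = (oof >= 0.5).astype(int)
    correct = pred == y
    overall = float(correct.mean())
    conf_sel = np.maximum(oof, 1.0 - oof) >= confidence_threshold
    confident = float(correct[conf_sel].mean()) if conf_sel.any() else None
    return CvReport(
        k=k,
        seed=seed,
        confidence_threshold=confidence_threshold,
        overall_accuracy=overall,
        confident_accuracy=confident,
        confident_fraction=float(conf_sel.mean()),
        n=len(y),
        oof_prob=oof,
        labels=y,
    )


def permutation_null_accuracy(
    report: CvReport, n_permutations: int = 1000, seed: int = 0
) -> np.ndarray:
    """Null distribution of CV accuracy under label-prediction independence.

    The out-of-fold predicted labels are held fixed while the true labels
    are permuted; each permutation yields one null accuracy.
    """
    rng = np.random.default_rng(seed)
    pred = (report.oof_prob >= 0.5).astype(int)
    y = report.labels
    return np.array(
        [float((pred == rng.permutation(y)).mean()) for _ in range(n_permutations)]
    )


# --------------------------------------------------------------- rule maps


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


@dataclass(frozen=True)
class GridSpec:
    """Feature-space evaluation grid: (lo, hi, step) per feature."""

    x: tuple[float, float, float] = (-1.0, 3.0, 0.5)
    y: tuple[float, float, float] = (-2.0, 2.0, 0.5)
    ms: tuple[float, float, float] = (10.0, 35.0, 1.0)
    acpc: tuple[float, float, float] = (35.0, 65.0, 1.0)

    def axes(self) -> dict[str, np.ndarray]:
        return {
            "x": _axis(*self.x),
            "y": _axis(*self.y),
            "ms": _axis(*self.ms),
            "acpc": _axis(*self.acpc),
        }


@dataclass
class RuleMap:
    """Predicted engagement probabilities on a 4-D feature grid."""

    region: str
    axes: dict[str, np.ndarray]
    probability: np.ndarray  # shape (nx, ny, nms, nacpc)
    threshold: float = 0.95

    @property
    def region_tensor(self) -> np.ndarray:
        """Boolean grid of cells at or above the probability threshold."""
        return self.probability >= self.threshold

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "threshold": self.threshold,
            "axes": {k: v.tolist() for k, v in self.axes.items()},
            "probability": np.round(self.probability, 9).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleMap":
        return cls(
            d["region"],
            {k: np.asarray(v, dtype=float) for k, v in d["axes"].items()},
            np.asarray(d["probability"], dtype=float),
            d["threshold"],
        )


def probability_map(
    model: GpcModel, grid: GridSpec | None = None, threshold: float = 0.95
) -> RuleMap:
    """Evaluate the classifier on every node of the feature grid."""
    grid = grid or GridSpec()
    axes = grid.axes()
    mesh = np.meshgrid(axes["x"], axes["y"], axes["ms"], axes["acpc"], indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    prob = model.predict_proba(pts).reshape(mesh[0].shape)
    return RuleMap(model.region, axes, prob, threshold)


@dataclass(frozen=True)
class RulePanel:
    """Admissible angle cells and conservative bounds at one (X, Y) panel."""

    region: str
    x: float
    y: float
    cells: tuple[tuple[float, float], ...]  # (ms, acpc) grid nodes in the region
    bounds: dict[str, float | None]  # ms_min/ms_max/acpc_min/acpc_max, None = unbounded
    summary: str


def _largest_true_box(region2d: np.ndarray) -> tuple[int, int, int, int] | None:
    """(i0, i1, j0, j1) inclusive indices of the largest all-true rectangle."""
    ni, nj = region2d.shape
    best, best_area = None, 0
    for i0 in range(ni):
        colwise = np.ones(nj, dtype=bool)
        for i1 in range(i0, ni):
            colwise &= region2d[i1]
            # longest run of true columns
            j = 0
            while j < nj:
                if not colwise[j]:
                    j += 1
                    continue
                j1 = j
                while j1 + 1 < nj and colwise[j1 + 1]:
                    j1 += 1
                area = (i1 - i0 + 1) * (j1 - j + 1)
                if area > best_area:
                    best, best_area = (i0, i1, j, j1), area
                j = j1 + 1
    return best


def extract_rules(rule_map: RuleMap, x: float, y: float) -> RulePanel:
    """Angle rules for the (X, Y) panel of a rule map.

    Returns all admissible (MS, AC-PC) grid cells plus conservative
    threshold-style bounds: the largest axis-aligned angle box lying
    entirely inside the thresholded region, so every angle pair satisfying
    the emitted bounds is admissible.  An empty region yields an empty
    panel, not an error.
    """
    ix = np.flatnonzero(np.isclose(rule_map.axes["x"], x))
    iy = np.flatnonzero(np.isclose(rule_map.axes["y"], y))
    if len(ix) != 1 or len(iy) != 1:
        raise ValueError(f"(x={x}, y={y}) is not a grid panel of this rule map")
    region2d = rule_map.region_tensor[ix[0], iy[0]]
    ms_ax, ap_ax = rule_map.axes["ms"], rule_map.axes["acpc"]
    cells = tuple(
        (float(ms_ax[i]), float(ap_ax[j])) for i, j in np.argwhere(region2d)
    )
    bounds: dict[str, float | None] = {
        "ms_min": None, "ms_max": None, "acpc_min": None, "acpc_max": None
    }
    if not cells:
        return RulePanel(rule_map.region, x, y, cells, bounds,
                         "no angle combination reaches the probability threshold")
    box = _largest_true_box(region2d)
    i0, i1, j0, j1 = box
    parts = []
    if i0 > 0:
        bounds["ms_min"] = float(ms_ax[i0])
        parts.append(f"MS >= {ms_ax[i0]:g} deg")
    if i1 < len(ms_ax) - 1:
        bounds["ms_max"] = float(ms_ax[i1])
        parts.append(f"MS <= {ms_ax[i1]:g} deg")
    if j0 > 0:
        bounds["acpc_min"] = float(ap_ax[j0])
        parts.append(f"AC-PC >= {ap_ax[j0]:g} deg")
    if j1 < len(ap_ax) - 1:
        bounds["acpc_max"] = float(ap_ax[j1])
        parts.append(f"AC-PC <= {ap_ax[j1]:g} deg")
    summary = ", ".join(parts) if parts else "all sampled angle combinations admissible"
    return RulePanel(rule_map.region, x, y, cells, bounds, summary)


def rule_precision(
    model: GpcModel, features, labels, threshold: float = 0.95
) -> tuple[float | None, int]:
    """Precision of the >= threshold recommendation on held-out trajectories.

    Returns (precision, n_selected); precision is None when no held-out
    trajectory meets the probability threshold.
    """
    X = _as_feature_array(features)
    if len(X) == 0:
        raise ValueError("holdout set is empty")
    y = np.asarray(labels).astype(int).ravel()
    p = model.predict_proba(X)
    selected = p >= threshold
    n_sel = int(selected.sum())
    if n_sel == 0:
        return None, 0
    return float(y[selected].mean()), n_sel


# --------------------------------------------------------------- depth rule

LOGIT_95 = math.log(19.0)  # logit(0.95)


@dataclass(frozen=True)
class DepthRule:
    """Logistic depth rule P(in SN | depth) and its 95% crossing.

    ``min_depth_95`` refers to the contact *center*;
    ``min_depth_95_lower_border`` adds half a typical 1.5 mm contact height
    so the rule can also be read as "lower border of the deepest contact".
    """

    intercept: float
    slope: float  # per mm of depth
    min_depth_95: float | None  # None when the slope is not positive
    min_depth_95_lower_border: float | None
    penalized: bool  # ridge penalty applied due to perfect separation
    n: int
    contact_half_height_mm: float = 0.75

    def predict_proba(self, depth_mm) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(depth_mm, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def min_depth_for_probability(intercept: float, slope: float, p: float = 0.95) -> float:
    """Closed-form depth at which the logistic probability reaches ``p``."""
    if slope <= 0:
        raise ValueError("crossing depth requires a positive slope")
    return (math.log(p / (1.0 - p)) - intercept) / slope


def fit_depth_rule(
    depths_mm,
    in_sn,
    contact_half_height_mm: float = 0.75,
    separation_penalty: float = 1e-4,
) -> DepthRule:
    """Logistic fit of SN membership against arc-length depth.

    Expects on-track filtering upstream (see :func:`on_track`).  Perfect
    separation is detected and handled with a ridge penalty of
    ``separation_penalty`` on the coefficients; otherwise the fit is
    effectively unpenalized.
    """
    d = np.asarray(depths_mm, dtype=float).ravel()
    y = np.asarray(in_sn).astype(int).ravel()
    if len(d) != len(y):
        raise ValueError("depths and labels must have equal length")
    if y.min() == y.max():
        cls = "in-SN" if y[0] == 1 else "not-in-SN"
        raise ValueError(f"all contacts are {cls}: both classes are required")
    pos, neg = d[y == 1], d[y == 0]
    separated = pos.min() > neg.max() or pos.max() < neg.min()
    C = 1.0 / separation_penalty if separated else 1e10
    lr = LogisticRegression(C=C, solver="lbfgs", max_iter=10_000, tol=1e-12)
    lr.fit(d[:, None], y)
    intercept = float(lr.intercept_[0])
    slope = float(lr.coef_[0, 0])
    if slope > 0:
        center = min_depth_for_probability(intercept, slope, 0.95)
        lower = center + contact_half_height_mm
    else:
        center = lower = None
    return DepthRule(
        intercept, slope, center, lower, separated, len(y), contact_half_height_mm
    )


def on_track(lead: Lead, atlas: LabelAtlas, step_mm: float = 0.1) -> bool:
    """Whether the infinite trajectory line passes through the SN.

    The line through the lead is sampled at ``step_mm`` arc-length steps
    across the atlas bounding box and checked against the SNr/SNc voxels.
    """
    direction = trajectory_norm(lead)
    point = lead.ventralmost
    lo, hi = atlas.world_bounds()
    # slab intersection of the line with the bounding box
    t_lo, t_hi = -np.inf, np.inf
    for k in range(3):
        if abs(direction[k]) < 1e-12:
            if not (lo[k] <= point[k] <= hi[k]):
                return False
            continue
        t1 = (lo[k] - point[k]) / direction[k]
        t2 = (hi[k] - point[k]) / direction[k]
        t_lo = max(t_lo, min(t1, t2))
        t_hi = min(t_hi, max(t1, t2))
    if t_lo > t_hi:
        return False
    ts = np.arange(t_lo, t_hi + step_mm, step_mm)
    pts = point + ts[:, None] * direction
    ijk = np.round(atlas.world_to_ijk(pts)).astype(int)
    shape = np.asarray(atlas.labels.shape)
    ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
    if not ok.any():
        return False
    sn = atlas.mask("SN")
    return bool(sn[tuple(ijk[ok].T)].any())
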