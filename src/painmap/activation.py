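"""Brain-wide discrimination analysis with forward-model activation patterns.

A linear classifier trained to separate two groups from region-wise
z-scored FOS counts yields a weight vector ``W`` (the backward model).
Those weights are not directly interpretable region by region: a region
can receive large weight merely to cancel noise shared with other
regions. The forward-model (Haufe) transformation

    A = Σx · W · Σŝ⁻¹,   Σŝ = Wᵀ · Σx · W

re-expresses the weights in data space, so that large ``|A_m|`` marks
regions whose signal actually drives the discrimination. With few
animals and many regions the sample covariance Σx is singular, so it is
shrunk toward its diagonal before use.

The sklearn-style :class:`ActivationMapper` bundles the full path
(z-scoring, linear SVM, shrunk covariance, Haufe transform); the
module-level functions expose each stage on the package containers.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .containers import RegionActivationMatrix, ValidationError

__all__ = [
    "ActivationMapper",
    "ActivationPattern",
    "ContributionCurve",
    "zscore_regions",
    "fit_linear_classifier",
    "feature_covariance",
    "haufe_transform",
    "contribution_curve",
    "rank_regions",
    "cross_validate",
]


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class LinearClassifierModel:
    """Linear backward model: decision function sign(Wᵀx + b)."""

    weights: np.ndarray  # M x K
    bias: np.ndarray  # length K
    training_accuracy: float
    regularization: float
    classes: tuple
    cv_scheme: str = "none"

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, float))
        if self.weights.shape[1] > self.weights.shape[0] and self.weights.shape[0] == 1:
            # accept a 1-D weight vector as M x 1
            self.weights = self.weights.T
        self.bias = np.atleast_1d(np.asarray(self.bias, float))
        if not np.isfinite(self.weights).all():
            raise ValidationError("classifier weights must be finite")


@dataclass
class ActivationPattern:
    """Forward-model pattern A with the covariances that produced it."""

    A: np.ndarray  # M x K
    sigma_x: np.ndarray  # M x M
    sigma_s: np.ndarray  # K x K
    shrinkage_used: float
    region_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, float))
        if not np.isfinite(self.A).all():
            raise ValidationError("activation pattern contains non-finite values")
        if not np.allclose(self.sigma_x, self.sigma_x.T, atol=1e-8):
            raise ValidationError("sigma_x must be symmetric")

    @property
    def K(self) -> int:
        return self.A.shape[1]


@dataclass
class ContributionCurve:
    """Regions ranked by |A| with their cumulative share of total |A|."""

    ordered_regions: list[str]
    ordered_abs_pattern: np.ndarray
    cumulative_fraction: np.ndarray

    def regions_for_fraction(self, fraction: float) -> list[str]:
        """Smallest prefix of ranked regions reaching ``fraction`` of total |A|."""
        idx = int(np.searchsorted(self.cumulative_fraction, fraction - 1e-12))
        return self.ordered_regions[: idx + 1]


# ---------------------------------------------------------------------------
# Stage functions
# ---------------------------------------------------------------------------

def zscore_regions(data: RegionActivationMatrix) -> RegionActivationMatrix:
    """Standardize each region column to mean 0, sample SD 1 (ddof=1), pooled.

    Pooling across both groups matches the convention of standardizing
    the full count table before classification. Zero-variance columns
    are set to 0 and flagged in ``degenerate_regions`` instead of
    raising, so large region tables remain usable.
    """
    x = data.counts
    if x.shape[0] < 2:
        raise ValidationError("z-scoring needs N >= 2 animals")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd == 0
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (x - mu) / safe_sd
    z[:, degenerate] = 0.0
    return replace(data, zscores=z, degenerate_regions=degenerate)


def _require_z(data: RegionActivationMatrix) -> np.ndarray:
    if data.zscores is None:
        raise ValidationError("input must be z-scored first (call zscore_regions)")
    return data.zscores


def fit_linear_classifier(
    z: RegionActivationMatrix,
    regularization: float = 1.0,
    seed: int = 0,
) -> LinearClassifierModel:
    """Fit a soft-margin linear SVM separating the two groups.

    For two classes the backward model has K = 1: ``weights`` is M x 1
    and the decision function is sign(Wᵀx + b). The positive decision
    side is the alphabetically later group label (e.g. MA over CON), so
    positive pattern entries later read as "higher in that group".
    """
    x = _require_z(z)
    y = np.asarray(z.group_labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("need two classes to fit a classifier")
    if x.shape[1] == 0:
        raise ValidationError("no feature columns (M = 0)")
    if regularization <= 0:
        raise ValidationError("regularization (C) must be positive")
    clf = SVC(kernel="linear", C=regularization, random_state=seed)
    clf.fit(x, y)
    acc = float(clf.score(x, y))
    return LinearClassifierModel(
        weights=clf.coef_.T,
        bias=clf.intercept_,
        training_accuracy=acc,
        regularization=regularization,
        classes=tuple(clf.classes_),
    )


def _diag_shrinkage_auto(xc: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the diagonal target diag(S).

    Variance-of-covariances rule (Schäfer-Strimmer family): the optimal
    intensity for zeroing off-diagonal entries is the summed estimation
    variance of the off-diagonal sample covariances divided by their
    summed squares, clipped to [0, 1].
    """
    n, m = xc.shape
    if n < 2:
        return 1.0
    s = xc.T @ xc / (n - 1)
    w = np.einsum("ki,kj->kij", xc, xc)  # per-animal outer products
    wbar = w.mean(axis=0)
    var_s = n / (n - 1.0) ** 3 * ((w - wbar) ** 2).sum(axis=0)
    off = ~np.eye(m, dtype=bool)
    denom = (s[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))


def feature_covariance(
    z: Union[RegionActivationMatrix, np.ndarray],
    shrinkage: Union[float, str] = "auto",
) -> tuple[np.ndarray, float]:
    """Shrunk feature covariance Σ̂ = (1−s)·S + s·diag(S).

    ``shrinkage='auto'`` selects s by the analytic rule in
    :func:`_diag_shrinkage_auto`; a float in [0, 1] is used as-is.
    Returns ``(sigma, s_used)``.
    """
    x = _require_z(z) if isinstance(z, RegionActivationMatrix) else np.asarray(z, float)
    n = x.shape[0]
    if n < 2:
        raise ValidationError("covariance needs N >= 2")
    xc = x - x.mean(axis=0)
    s_mat = xc.T @ xc / (n - 1)
    if shrinkage == "auto":
        s = _diag_shrinkage_auto(xc)
    else:
        s = float(shrinkage)
        if not 0.0 <= s <= 1.0:
            raise ValidationError("shrinkage must be in [0, 1]")
    sigma = (1.0 - s) * s_mat + s * np.diag(np.diag(s_mat))
    sigma = (sigma + sigma.T) / 2.0  # enforce exact symmetry
    return sigma, s


def haufe_transform(
    model: Union[LinearClassifierModel, np.ndarray],
    sigma_x: np.ndarray,
    region_names: Optional[list[str]] = None,
    shrinkage_used: float = 0.0,
) -> ActivationPattern:
    """Forward-model transformation A = Σx·W·Σŝ⁻¹ with Σŝ = WᵀΣxW."""
    w = model.weights if isinstance(model, LinearClassifierModel) else np.asarray(model, float)
    if w.ndim == 1:
        w = w[:, None]
    sigma_x = np.asarray(sigma_x, float)
    if sigma_x.shape[0] != sigma_x.shape[1] or sigma_x.shape[0] != w.shape[0]:
        raise ValidationError(
            f"dimension mismatch: sigma_x {sigma_x.shape} vs weights {w.shape}"
        )
    sigma_s = w.T @ sigma_x @ w
    cond = np.linalg.cond(sigma_s)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            "latent covariance Σŝ = WᵀΣxW is singular; increase covariance shrinkage"
        )
    a = sigma_x @ w @ np.linalg.inv(sigma_s)
    return ActivationPattern(
        A=a,
        sigma_x=sigma_x,
        sigma_s=sigma_s,
        shrinkage_used=shrinkage_used,
        region_names=list(region_names) if region_names is not None else None,
    )


def _ranked_order(pattern: ActivationPattern) -> tuple[np.ndarray, list[str]]:
    if pattern.K != 1:
        raise ValidationError("ranking/contribution requires a K = 1 pattern")
    a = np.abs(pattern.A[:, 0])
    names = pattern.region_names or [f"region{i+1}" for i in range(len(a))]
    # descending |A|, ties broken alphabetically by region name
    order = sorted(range(len(a)), key=lambda i: (-a[i], names[i]))
    return a, [names[i] for i in order]


def contribution_curve(pattern: ActivationPattern) -> ContributionCurve:
    """Cumulative activation contribution of regions ranked by |A|."""
    a, ordered_names = _ranked_order(pattern)
    total = a.sum()
    if total == 0:
        raise ValidationError("all-zero activation pattern has no contribution curve")
    name_to_abs = dict(zip(pattern.region_names or
                           [f"region{i+1}" for i in range(len(a))], a))
    ordered_abs = np.array([name_to_abs[n] for n in ordered_names])
    cum = np.cumsum(ordered_abs) / total
    cum[-1] = 1.0  # guard against rounding at the terminus
    return ContributionCurve(
        ordered_regions=ordered_names,
        ordered_abs_pattern=ordered_abs,
        cumulative_fraction=cum,
    )


def rank_regions(pattern: ActivationPattern, top_k: int) -> list[str]:
    """Top-``top_k`` regions by |A| (ties alphabetical)."""
    a, ordered_names = _ranked_order(pattern)
    if top_k > len(a):
        raise ValidationError(f"top_k = {top_k} exceeds M = {len(a)} regions")
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    return ordered_names[:top_k]


def cross_validate(
    z: RegionActivationMatrix,
    scheme: str = "leave-one-out",
    seed: int = 0,
    regularization: float = 1.0,
    n_splits: int = 3,
) -> dict:
    """Held-out accuracy of the linear SVM under LOO or stratified k-fold."""
    x = _require_z(z)
    y = np.asarray(z.group_labels)
    _, counts = np.unique(y, return_counts=True)
    if scheme == "leave-one-out":
        if counts.min() < 2:
            raise ValidationError("leave-one-out needs >= 2 animals per group")
        cv = LeaveOneOut()
    elif scheme == "stratified-k":
        if counts.min() < n_splits:
            raise ValidationError(
                f"stratified {n_splits}-fold infeasible: smallest group has {counts.min()} animals"
            )
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    else:
        raise ValidationError(f"unknown CV scheme: {scheme!r}")
    clf = SVC(kernel="linear", C=regularization, random_state=seed)
    fold_scores = cross_val_score(clf, x, y, cv=cv)
    return {
        "scheme": scheme,
        "mean_accuracy": float(fold_scores.mean()),
        "fold_scores": fold_scores.tolist(),
    }


# ---------------------------------------------------------------------------
# sklearn-style estimator over the full path
# ---------------------------------------------------------------------------

class ActivationMapper(BaseEstimator, ClassifierMixin):
    """Linear SVM group discrimination with forward-model interpretation.

    Parameters
    ----------
    C : float
        Soft-margin penalty of the linear SVM.
    shrinkage : 'auto' or float in [0, 1]
        Intensity of covariance shrinkage toward the diagonal.
    random_state : int
        Seed forwarded to the SVM solver (determinism contract).

    Fitted attributes
    -----------------
    classes_, weights_ (M,), bias_, pattern_ (M,), sigma_x_, sigma_s_,
    shrinkage_, training_accuracy_, mean_, scale_, degenerate_mask_.
    """

    def __init__(self, C: float = 1.0, shrinkage: Union[float, str] = "auto",
                 random_state: int = 0):
        self.C = C
        self.shrinkage = shrinkage
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (animals x regions)")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValidationError("ActivationMapper requires exactly two classes")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.degenerate_mask_ = sd == 0
        self.scale_ = np.where(self.degenerate_mask_, 1.0, sd)
        z = (X - self.mean_) / self.scale_
        z[:, self.degenerate_mask_] = 0.0

        clf = SVC(kernel="linear", C=self.C, random_state=self.random_state)
        clf.fit(z, y)
        self._svc_ = clf
        self.classes_ = clf.classes_
        self.weights_ = clf.coef_.ravel()
        self.bias_ = float(clf.intercept_[0])
        self.training_accuracy_ = float(clf.score(z, y))

        self.sigma_x_, self.shrinkage_ = feature_covariance(z, self.shrinkage)
        pat = haufe_transform(self.weights_[:, None], self.sigma_x_,
                              shrinkage_used=self.shrinkage_)
        self.pattern_ = pat.A.ravel()
        self.sigma_s_ = pat.sigma_s
        return self

    def _transform(self, X):
        z = (np.asarray(X, float) - self.mean_) / self.scale_
        z[:, self.degenerate_mask_] = 0.0
        return z

    def decision_function(self, X):
        return self._svc_.decision_function(self._transform(X))

    def predict(self, X):
        return self._svc_.predict(self._transform(X))

    def activation_pattern(self, region_names: Optional[list[str]] = None) -> ActivationPattern:
        return ActivationPattern(
            A=self.pattern_[:, None],
            sigma_x=self.sigma_x_,
            sigma_s=self.sigma_s_,
            shrinkage_used=self.shrinkage_,
            region_names=region_names,
        )

    def contribution_curve(self, region_names: Optional[list[str]] = None) -> ContributionCurve:
        return contribution_curve(self.activation_pattern(region_names))


def map_activation(
    data: RegionActivationMatrix,
    shrinkage: Union[float, str] = "auto",
    regularization: float = 1.0,
    seed: int = 0,
) -> tuple[RegionActivationMatrix, LinearClassifierModel, ActivationPattern, ContributionCurve]:
    """Full discrimination pipeline on a region-count table.

    z-scores the counts, fits the linear SVM, estimates the shrunk
    feature covariance, applies the forward-model transformation, and
    ranks regions by cumulative activation contribution.
    """
    z = zscore_regions(data)
    model = fit_linear_classifier(z, regularization=regularization, seed=seed)
    sigma, s_used = feature_covariance(z, shrinkage)
    pattern = haufe_transform(model, sigma, region_names=data.region_names,
                              shrinkage_used=s_used)
    curve = contribution_curve(pattern)
    return z, model, pattern, curve
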