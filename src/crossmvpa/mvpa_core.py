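"""Voxel ranking and the L2-penalized logistic regression (PLR) classifier.

Feature selection ranks voxels by the one-way two-group ANOVA F statistic of
their trial features (between-class over within-class mean square), and keeps
the top k (study default k = 500). The classifier minimizes the convex
objective

    L(w, b) = sum_i [ log(1 + exp(z_i)) - y_i z_i ] + lambda * ||w||^2,
    z_i = w . x_i + b,

i.e. the logistic log-loss — the model of the class log-odds
log[p/(1-p)] = w.x + b — plus a ridge (Tikhonov) penalty on the weights with
tuning parameter lambda (study default 1.0). The intercept is not penalized
and lambda is not rescaled by the number of trials. Optimization is a damped
Newton iteration from w = 0; convexity makes the result independent of the
start and the zero start makes runs exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .bold_data import ValidationError
from .preprocessing import TrialFeatureMatrix

logger = logging.getLogger(__name__)

GRAD_TOL = 1e-6
MAX_ITER = 1000


class ConvergenceWarning(UserWarning):
    pass


@dataclasses.dataclass
class FeatureRanking:
    """Per-voxel F scores and the descending-score voxel order.

    Ties are broken by ascending voxel index (stable sort), so the ranking is
    deterministic.
    """

    scores: np.ndarray
    order: np.ndarray
    k: int = 500


def anova_rank(train: TrialFeatureMatrix) -> FeatureRanking:
    """Rank voxels by the two-group one-way ANOVA F statistic.

    F = MS_between / MS_within computed per voxel on the training features.
    Requires both classes present with at least 2 trials each.
    """
    classes = np.unique(train.labels)
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes.tolist()}")
    g1 = train.features[train.labels == classes[0]]
    g2 = train.features[train.labels == classes[1]]
    n1, n2 = len(g1), len(g2)
    if min(n1, n2) < 2:
        raise ValidationError("each class needs at least 2 training trials")
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ss_between = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ss_within = ((g1 - m1) ** 2).sum(axis=0) + ((g2 - m2) ** 2).sum(axis=0)
    ms_within = ss_within / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / ms_within  # df_between = 1
    f = np.where(ms_within == 0, np.where(ss_between > 0, np.inf, 0.0), f)
    order = np.argsort(-f, kind="stable")
    return FeatureRanking(scores=f, order=order)


def select_top_k(ranking: FeatureRanking, k: int) -> np.ndarray:
    """First k voxel indices of the ranking order."""
    n = len(ranking.order)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    return ranking.order[:k].copy()


@dataclasses.dataclass
class ClassifierModel:
    """A trained PLR model: weights, intercept, penalty and provenance."""

    w: np.ndarray
    intercept: float
    lam: float
    feature_subset: np.ndarray
    positive_class: str
    negative_class: str
    n_features_in: int
    converged: bool
    n_iter: int
    final_grad_norm: float
    objective_path: list[float] = dataclasses.field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "w": self.w.tolist(),
            "intercept": self.intercept,
            "lambda": self.lam,
            "feature_subset": self.feature_subset.tolist(),
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
            "n_features_in": self.n_features_in,
            "convergence": {
                "converged": self.converged,
                "n_iter": self.n_iter,
                "final_grad_norm": self.final_grad_norm,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            w=np.asarray(d["w"], dtype=float),
            intercept=float(d["intercept"]),
            lam=float(d["lambda"]),
            feature_subset=np.asarray(d["feature_subset"], dtype=int),
            positive_class=d["positive_class"],
            negative_class=d["negative_class"],
            n_features_in=int(d["n_features_in"]),
            converged=bool(d["convergence"]["converged"]),
            n_iter=int(d["convergence"]["n_iter"]),
            final_grad_norm=float(d["convergence"]["final_grad_norm"]),
        )


def plr_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, lam: float) -> float:
    """The penalized log-loss minimized by :func:`train_plr`."""
    z = X @ w + b
    return float(np.sum(np.logaddexp(0.0, z) - y * z) + lam * (w @ w))


def train_plr(
    train: TrialFeatureMatrix,
    lam: float = 1.0,
    feature_subset: np.ndarray | None = None,
    positive_class: str | None = None,
    tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
) -> ClassifierModel:
    """Fit ridge-penalized logistic regression by damped Newton iteration.

    Starts from w = 0, b = 0 and iterates Newton steps with backtracking line
    search until the gradient 2-norm falls below ``tol`` (or ``max_iter`` is
    hit, which emits a :class:`ConvergenceWarning` with the final gradient
    norm). The positive class defaults to the lexicographically first label;
    at lambda > 0 the objective is strictly convex in w.
    """
    if lam < 0:
        raise ValidationError(f"lambda must be non-negative, got {lam}")
    classes = np.unique(train.labels)
    if len(classes) != 2:
        raise ValidationError(f"training requires exactly 2 classes, got {classes.tolist()}")
    if positive_class is None:
        positive_class = str(classes[0])
    elif positive_class not in classes:
        raise ValidationError(f"positive_class {positive_class!r} absent from labels")
    negative_class = str([c for c in classes if c != positive_class][0])

    n_features_in = train.n_voxels
    if feature_subset is None:
        feature_subset = np.arange(n_features_in)
    feature_subset = np.asarray(feature_subset, dtype=int)
    X = np.ascontiguousarray(train.features[:, feature_subset], dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("training features must be finite")
    y = (train.labels == positive_class).astype(float)

    d = X.shape[1]
    w = np.zeros(d)
    b = 0.0
    f = plr_objective(X, y, w, b, lam)
    path = [f]
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        z = X @ w + b
        p = expit(z)
        g_w = X.T @ (p - y) + 2.0 * lam * w
        g_b = float(np.sum(p - y))
        grad = np.concatenate([g_w, [g_b]])
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm <= tol:
            it -= 1
            break
        wt = np.clip(p * (1.0 - p), 1e-12, None)
        Xw = X * wt[:, None]
        H = np.empty((d + 1, d + 1))
        H[:d, :d] = X.T @ Xw
        H[:d, :d][np.diag_indices(d)] += 2.0 * lam
        H[:d, d] = Xw.sum(axis=0)
        H[d, :d] = H[:d, d]
        H[d, d] = wt.sum()
        try:
            step = cho_solve(cho_factor(H, lower=True), grad)
        except np.linalg.LinAlgError:
            H[np.diag_indices(d + 1)] += 1e-8
            step = cho_solve(cho_factor(H, lower=True), grad)
        # backtracking line search (Armijo) keeps the objective monotone
        t = 1.0
        descent = float(grad @ step)
        for _ in range(60):
            w_new = w - t * step[:d]
            b_new = b - t * step[d]
            f_new = plr_objective(X, y, w_new, b_new, lam)
            if f_new <= f - 1e-4 * t * descent:
                break
            t *= 0.5
        w, b, f = w_new, b_new, f_new
        path.append(f)
    converged = grad_norm <= tol
    if not converged:
        warnings.warn(
            f"PLR did not converge in {max_iter} iterations "
            f"(final gradient norm {grad_norm:.3e})",
            ConvergenceWarning,
        )
    return ClassifierModel(
        w=w,
        intercept=float(b),
        lam=float(lam),
        feature_subset=feature_subset,
        positive_class=positive_class,
        negative_class=negative_class,
        n_features_in=n_features_in,
        converged=converged,
        n_iter=it,
        final_grad_norm=grad_norm,
        objective_path=path,
    )


def predict(model: ClassifierModel, test) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial positive-class probability and predicted label.

    ``test`` may be a :class:`TrialFeatureMatrix` or a plain array; full-width
    inputs are sliced to the model's feature subset, inputs already restricted
    to the subset are used as-is. A probability tie at exactly 0.5 is labeled
    as the positive class.
    """
    X = test.features if isinstance(test, TrialFeatureMatrix) else np.asarray(test, dtype=float)
    if X.ndim != 2:
        raise ValidationError("test features must be a 2-D matrix")
    if X.shape[1] == model.n_features_in:
        X = X[:, model.feature_subset]
    elif X.shape[1] != len(model.feature_subset):
        raise ValidationError(
            f"test has {X.shape[1]} features; expected {model.n_features_in} "
            f"(full) or {len(model.feature_subset)} (subset)"
        )
    p = expit(X @ model.w + model.intercept)
    labels = np.where(p >= 0.5, model.positive_class, model.negative_class).astype(str)
    return p, labels
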