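"""L1-penalized logistic regression, the feature-selection engine.

The model minimizes

    F(w, b) = L(w, b) + lambda * ||w||_1

where L is the mean Bernoulli negative log-likelihood under the logit link
and the intercept b is never penalized. Features with nonzero weight at the
solution are the selected features: the absolute-value penalty drives
irrelevant coefficients exactly to zero.

Solver: proximal gradient with backtracking line search, accelerated with a
monotone (restarted) Nesterov scheme so the penalized objective never
increases across iterations. Convergence is declared on the KKT residual

    r = max( |dL/db|,
             max_{w_j = 0}  max(|dL/dw_j| - lambda, 0),
             max_{w_j != 0} |dL/dw_j + lambda * sign(w_j)| )

falling below ``tolerance``. Features are z-scored internally (training data
only) so a single lambda is meaningful across features; reported weights are
transformed back to the original scale.

``lambda_max`` — the smallest penalty at which the all-zero weight vector is
optimal — anchors the regularization path; the default selection strategy
picks lambda on a log grid below it by stratified inner cross-validation on
held-out log-loss, then refits once on all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateLabelsError, EmptyDatasetError
from .io_model import FilteredDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverConfig:
    """Tunables of the penalized solver and the lambda-selection strategy."""

    lambda_: float | None = None  # fixed penalty; None -> choose by strategy
    lambda_grid_size: int = 50
    lambda_min_ratio: float = 1e-3
    tolerance: float = 1e-6
    max_iter: int = 5000
    standardize: bool = True
    accelerate: bool = True
    inner_folds: int = 5
    zero_tol: float = 1e-9  # |w_j| below this counts as zero for support
    seed: int = 0

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")


@dataclass(frozen=True)
class ModelFit:
    """A fitted model: weights w (original feature scale), intercept b."""

    weights: np.ndarray
    intercept: float
    lambda_: float
    objective: float
    converged: bool
    n_iter: int
    kkt_residual: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability; strictly inside (0, 1)."""
        p = _sigmoid(self.decision(X))
        eps = 1e-15  # keep log(p) and log1p(-p) finite downstream
        return np.clip(p, eps, 1.0 - eps)


@dataclass(frozen=True)
class SelectionResult:
    """Nonzero-coefficient features from a full-data L1 fit."""

    dataset_type: str
    variant: str | None
    selected_features: tuple[str, ...]
    coefficients: tuple[float, ...]
    lambda_: float
    fit: ModelFit

    @property
    def tag(self) -> str:
        return self.dataset_type if self.variant is None else f"{self.dataset_type}-{self.variant}"

    @property
    def feature_set(self) -> frozenset[str]:
        return frozenset(self.selected_features)


def logistic_loss_grad(
    weights: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Mean logistic log-loss and its gradient in (w, b).

    X is samples x features; y in {0,1}. Returns (loss, grad_w, grad_b).
    The loss is the negative average Bernoulli log-likelihood, convex in
    (w, b) and invariant to duplicating every sample.
    """
    y = np.asarray(y, dtype=float)
    z = X @ weights + intercept
    # log(1 + e^z) - y z, computed stably
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = _sigmoid(z)
    resid = (p - y) / len(y)
    return loss, X.T @ resid, float(np.sum(resid))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which w = 0 is optimal.

    Evaluates max_j |dL/dw_j| at w = 0 with the intercept at the
    positive-class prevalence logit (the unpenalized optimum given w = 0).
    """
    y = np.asarray(y, dtype=float)
    prev = float(np.mean(y))
    if prev in (0.0, 1.0):
        raise DegenerateLabelsError("lambda_max requires both classes present")
    resid = (prev - y) / len(y)
    grad_w = X.T @ resid
    return float(np.max(np.abs(grad_w))) if grad_w.size else 0.0


class _Scaler:
    """Per-feature z-scoring; constant features get scale 1 (stay zero)."""

    def __init__(self, X: np.ndarray, enabled: bool):
        if enabled:
            self.mean = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale = np.where(sd > 0, sd, 1.0)
        else:
            self.mean = np.zeros(X.shape[1])
            self.scale = np.ones(X.shape[1])

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale

    def backtransform(self, w: np.ndarray, b: float) -> tuple[np.ndarray, float]:
        w_orig = w / self.scale
        return w_orig, b - float(w_orig @ self.mean)


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _kkt_residual(grad_w: np.ndarray, grad_b: float, w: np.ndarray, lam: float) -> float:
    zero = w == 0.0
    r = abs(grad_b)
    if zero.any():
        r = max(r, float(np.max(np.maximum(np.abs(grad_w[zero]) - lam, 0.0))))
    if (~zero).any():
        r = max(r, float(np.max(np.abs(grad_w[~zero] + lam * np.sign(w[~zero])))))
    return r


def _penalized_objective(Xs, yf, w, b, lam) -> float:
    z = Xs @ w + b
    return float(np.mean(np.logaddexp(0.0, z) - yf * z)) + lam * float(np.abs(w).sum())


def _active_grad_norm(Xs, yf, lam, w, b) -> float:
    """Inf-norm of the smooth-plus-sign gradient restricted to the active set."""
    n, p = Xs.shape
    active = np.arange(p) if lam == 0.0 else np.flatnonzero(w)
    signs = np.zeros(len(active)) if lam == 0.0 else np.sign(w[active])
    z = Xs[:, active] @ w[active] + b
    r = (_sigmoid(z) - yf) / n
    g = np.concatenate([Xs[:, active].T @ r + lam * signs, [np.sum(r)]])
    return float(np.max(np.abs(g), initial=0.0))


def _newton_polish(Xs, yf, lam, w, b, obj, config):
    """Damped Newton on the active set with signs fixed.

    Proximal gradient identifies the support quickly but closes the last
    digits of the KKT residual slowly; once the signs are fixed the problem
    is smooth in the active coordinates and Newton finishes it. Coordinates
    that would cross zero are clipped to exactly zero; steps are accepted
    only when the full penalized objective decreases, preserving
    monotonicity.
    """
    n, p = Xs.shape
    w = w.copy()
    for _ in range(50):
        active = np.arange(p) if lam == 0.0 else np.flatnonzero(w)
        signs = np.zeros(len(active)) if lam == 0.0 else np.sign(w[active])
        Xa1 = np.hstack([Xs[:, active], np.ones((n, 1))])
        z = Xa1[:, :-1] @ w[active] + b
        pr = _sigmoid(z)
        r = (pr - yf) / n
        g = np.concatenate([Xa1[:, :-1].T @ r + lam * signs, [np.sum(r)]])
        if np.max(np.abs(g), initial=0.0) <= 0.1 * config.tolerance:
            break
        weights_h = pr * (1.0 - pr) / n
        H = Xa1.T @ (Xa1 * weights_h[:, None]) + 1e-10 * np.eye(len(active) + 1)
        try:
            direction = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        g_norm = float(np.max(np.abs(g)))
        improved = False
        t = 1.0
        for _ls in range(30):
            wa = w[active] - t * direction[:-1]
            if lam > 0.0:
                wa = np.where(np.sign(wa) * signs < 0, 0.0, wa)
            w_new = w.copy()
            w_new[active] = wa
            b_new = b - t * direction[-1]
            obj_new = _penalized_objective(Xs, yf, w_new, b_new, lam)
            if obj_new < obj:
                w, b, obj = w_new, b_new, obj_new
                improved = True
                break
            # near the optimum the objective is flat at float resolution while
            # Newton still contracts the gradient; accept on gradient decrease
            if obj_new <= obj + 1e-14 * (1.0 + abs(obj)) and (
                _active_grad_norm(Xs, yf, lam, w_new, b_new) < 0.5 * g_norm
            ):
                w, b, obj = w_new, b_new, min(obj, obj_new)
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    return w, b, obj


def _fit_standardized(
    Xs: np.ndarray,
    y: np.ndarray,
    lam: float,
    config: SolverConfig,
    w0: np.ndarray | None = None,
    b0: float | None = None,
) -> tuple[np.ndarray, float, float, bool, int, float]:
    """Proximal-gradient solve in the standardized space.

    Monotone accelerated scheme: the Nesterov extrapolated step is taken
    only when it does not increase the penalized objective, so F is
    non-increasing across iterations by construction. An active-set Newton
    polish runs periodically to close the KKT residual.
    """
    n, p = Xs.shape
    yf = np.asarray(y, dtype=float)
    w = np.zeros(p) if w0 is None else w0.copy()
    prev = float(np.mean(yf))
    b = float(np.log(prev / (1.0 - prev))) if b0 is None else b0
    loss, gw, gb = logistic_loss_grad(w, b, Xs, yf)
    obj = loss + lam * np.abs(w).sum()
    step = 1.0
    vw, vb = w.copy(), b  # extrapolation point
    t_acc = 1.0
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        loss_v, gw_v, gb_v = logistic_loss_grad(vw, vb, Xs, yf)
        # backtracking line search on the smooth part at the extrapolation point
        step = min(step * 2.0, 1e6)
        while True:
            w_new = _soft_threshold(vw - step * gw_v, step * lam)
            b_new = vb - step * gb_v
            dw, db = w_new - vw, b_new - vb
            quad = loss_v + gw_v @ dw + gb_v * db + (dw @ dw + db * db) / (2.0 * step)
            loss_new = float(np.mean(np.logaddexp(0.0, Xs @ w_new + b_new) - yf * (Xs @ w_new + b_new)))
            if loss_new <= quad + 1e-12 or step < 1e-14:
                break
            step *= 0.5
        obj_new = loss_new + lam * np.abs(w_new).sum()
        if config.accelerate and obj_new <= obj:
            t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2)) / 2.0
            vw = w_new + ((t_acc - 1.0) / t_next) * (w_new - w)
            vb = b_new + ((t_acc - 1.0) / t_next) * (b_new - b)
            t_acc = t_next
            w, b, obj = w_new, b_new, obj_new
        elif obj_new <= obj:
            w, b, obj = w_new, b_new, obj_new
            vw, vb, t_acc = w.copy(), b, 1.0
        else:
            # restart acceleration from the last accepted point
            vw, vb, t_acc = w.copy(), b, 1.0
            continue
        _, gw, gb = logistic_loss_grad(w, b, Xs, yf)
        res = _kkt_residual(gw, gb, w, lam)
        if res <= config.tolerance:
            converged = True
            break
        if it % 10 == 0 or res <= 1e3 * config.tolerance:
            w, b, obj = _newton_polish(Xs, yf, lam, w, b, obj, config)
            vw, vb, t_acc = w.copy(), b, 1.0
            _, gw, gb = logistic_loss_grad(w, b, Xs, yf)
            res = _kkt_residual(gw, gb, w, lam)
            if res <= config.tolerance:
                converged = True
                break
    if not converged:
        w, b, obj = _newton_polish(Xs, yf, lam, w, b, obj, config)
    _, gw, gb = logistic_loss_grad(w, b, Xs, yf)
    res = _kkt_residual(gw, gb, w, lam)
    return w, b, obj, converged or res <= config.tolerance, it, res


def fit_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    config: SolverConfig | None = None,
    lambda_: float | None = None,
) -> ModelFit:
    """Fit the penalized model at a single lambda.

    X is samples x features; y in {0,1} with both classes present.
    Non-convergence returns a fit flagged ``converged=False`` with a warning.
    """
    config = config or SolverConfig()
    lam = config.lambda_ if lambda_ is None else lambda_
    if lam is None:
        raise ValueError("no lambda given: set config.lambda_ or pass lambda_")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("fit requires both classes present")
    scaler = _Scaler(np.asarray(X, dtype=float), config.standardize)
    Xs = scaler.transform(np.asarray(X, dtype=float))
    w_s, b_s, obj, conv, n_iter, res = _fit_standardized(Xs, y, lam, config)
    if not conv:
        logger.warning(
            "L1 solver did not converge in %d iterations (KKT residual %.3g)",
            n_iter,
            res,
        )
    w, b = scaler.backtransform(w_s, b_s)
    return ModelFit(w, b, lam, obj, conv, n_iter, res)


def fit_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, config: SolverConfig | None = None
) -> list[ModelFit]:
    """Fit along a descending lambda grid with warm starts."""
    config = config or SolverConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    lambdas = np.asarray(sorted(lambdas, reverse=True), dtype=float)
    scaler = _Scaler(X, config.standardize)
    Xs = scaler.transform(X)
    fits = []
    w0, b0 = None, None
    for lam in lambdas:
        w_s, b_s, obj, conv, n_iter, res = _fit_standardized(Xs, y, float(lam), config, w0, b0)
        w0, b0 = w_s, b_s
        w, b = scaler.backtransform(w_s, b_s)
        fits.append(ModelFit(w, b, float(lam), obj, conv, n_iter, res))
    return fits


def lambda_grid(X: np.ndarray, y: np.ndarray, config: SolverConfig) -> np.ndarray:
    """Log-spaced grid from lambda_max down to lambda_max * lambda_min_ratio."""
    lmax = lambda_max(_Scaler(np.asarray(X, float), config.standardize).transform(np.asarray(X, float)), y)
    if lmax == 0.0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * config.lambda_min_ratio, config.lambda_grid_size)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold indices preserving class balance (shared with evaluation)."""
    n = len(y)
    assign = np.empty(n, dtype=int)
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % k
    return assign


def _mean_heldout_logloss(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, config: SolverConfig
) -> np.ndarray:
    """Inner-CV held-out mean log-loss for each lambda on the grid."""
    rng = np.random.default_rng(config.seed)
    k = min(config.inner_folds, int(np.min(np.bincount(y))))
    if k < 2:
        raise DegenerateLabelsError("inner CV needs >= 2 samples in each class")
    folds = _stratified_folds(y, k, rng)
    losses = np.zeros((k, len(lambdas)))
    for f in range(k):
        tr, te = folds != f, folds == f
        fits = fit_path(X[tr], y[tr], lambdas, config)
        for j, fit in enumerate(fits):
            p = fit.predict_proba(X[te])
            losses[f, j] = -np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log1p(-p))
    return losses.mean(axis=0)


def select_features(
    ds: FilteredDataset,
    config: SolverConfig | None = None,
    strategy: str = "inner-cv",
) -> SelectionResult:
    """Select features on one pre-filtered dataset.

    ``inner-cv`` (default): lambda is chosen on a log grid below lambda_max
    by stratified inner cross-validation on held-out log-loss (ties broken
    toward the larger, sparser lambda), then the model is refit once on all
    samples. ``fixed``: use ``config.lambda_`` directly. The selected
    features are those with weight magnitude above ``config.zero_tol``
    after back-transformation to the original scale.
    """
    config = config or SolverConfig()
    if ds.is_empty:
        raise EmptyDatasetError(f"dataset {ds.tag} has no features to select from")
    y = ds.labels.aligned_to(ds.matrix.sample_ids)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError(f"dataset {ds.tag} has a single class")
    X = ds.matrix.values.T  # samples x features

    if strategy == "fixed":
        if config.lambda_ is None:
            raise ValueError("fixed strategy requires config.lambda_")
        lam = config.lambda_
    elif strategy == "inner-cv":
        grid = lambda_grid(X, y, config)
        mean_loss = _mean_heldout_logloss(X, y, grid, config)
        # grid is descending; argmin returns the first (largest-lambda) minimum
        lam = float(np.asarray(sorted(grid, reverse=True))[int(np.argmin(mean_loss))])
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    fit = fit_l1_logistic(X, y, config, lambda_=lam)
    nz = np.abs(fit.weights) > config.zero_tol
    selected = tuple(f for f, keep in zip(ds.matrix.feature_ids, nz) if keep)
    coefs = tuple(float(c) for c in fit.weights[nz])
    logger.info(
        "select_features[%s]: lambda=%.4g, %d/%d features selected",
        ds.tag,
        lam,
        len(selected),
        ds.matrix.n_features,
    )
    return SelectionResult(ds.dataset_type, ds.variant, selected, coefs, lam, fit)
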