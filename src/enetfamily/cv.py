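"""Model-building engine: λ grid, repeated randomized folds, per-run
cross-validated elastic-net fits, OOB prediction collection and λ* selection.

The elastic-net penalty is λ(α‖β‖₁ + (1−α)/2 ‖β‖₂²) on the loss averaged over
in-bag samples, the glmnet parametrization.  Solving is delegated to
scikit-learn: ``enet_path`` (coordinate descent) for the linear family with
α > 0, a closed-form SVD ridge solve at α = 0, and saga-solver logistic
regression for binomial/multinomial.  Features are standardized on in-bag
data only — out-of-bag rows never influence training — and coefficients are
returned on the original feature scale.

λ* is the grid point maximizing the unweighted mean over runs of the
out-of-bag quality function; exact ties break toward the larger (more
regularized) λ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, enet_path
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

# glmnet convention: λ_max is infinite at α=0, so the ridge grid is anchored
# at the α=0.001 path top.
_ALPHA_FLOOR = 1e-3


def _standardize_params(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population sd
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def make_lambda_grid(
    x_values: np.ndarray,
    y_encoded: np.ndarray,
    family: str,
    alpha: float,
    n_lambda: int,
    n_classes: int | None = None,
    lambda_min_ratio: float | None = None,
) -> np.ndarray:
    """Geometric λ path computed from the full data, strictly decreasing.

    λ_max is the smallest penalty that zeroes every coefficient at the null
    model: max_j |⟨x_j, r⟩| / (N·max(α, 0.001)) with x standardized and r the
    null-model residual (centered response for linear, centered class
    indicators otherwise).  The grid descends geometrically to
    λ_max·lambda_min_ratio over ``n_lambda`` points.
    """
    x = np.asarray(x_values, dtype=float)
    n, p = x.shape
    mu, sd = _standardize_params(x)
    xs = (x - mu) / sd
    if family == "linear":
        r = np.asarray(y_encoded, dtype=float)
        r = (r - r.mean())[:, None]
    else:
        k = n_classes if n_classes is not None else int(np.max(y_encoded)) + 1
        onehot = np.zeros((n, k))
        onehot[np.arange(n), np.asarray(y_encoded, dtype=int)] = 1.0
        r = onehot - onehot.mean(axis=0)
    lam_max = np.abs(xs.T @ r).max() / (n * max(alpha, _ALPHA_FLOOR))
    if lam_max <= 0:
        raise ValueError("degenerate data: null-model gradient is zero everywhere")
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-4 if n > p else 1e-2
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def extend_lambda_grid(grid: np.ndarray, n_lambda_ext: int) -> np.ndarray:
    """Extend a descending geometric grid symmetrically at constant log density.

    The original values are preserved as a contiguous sub-grid; the surplus
    points split evenly between the two ends, an odd extra point going to the
    small-λ side.  A non-geometric input is extended with its mean log step
    (logged).
    """
    grid = np.asarray(grid, dtype=float)
    m = len(grid)
    if n_lambda_ext <= m:
        raise ValueError("n_lambda_ext must exceed the current grid length")
    steps = np.diff(np.log(grid))
    if m > 2 and np.ptp(steps) > 1e-8 * abs(steps.mean()):
        logger.warning("input grid is not geometric; extending with the mean log step")
    step = steps.mean()  # negative: grid is descending
    n_add = n_lambda_ext - m
    n_high = n_add // 2
    n_low = n_add - n_high  # odd surplus goes to the small-λ side
    high = np.exp(np.log(grid[0]) - step * np.arange(n_high, 0, -1))
    low = np.exp(np.log(grid[-1]) + step * np.arange(1, n_low + 1))
    return np.concatenate([high, grid, low])


def _run_seed(seed: int, run: int) -> int:
    ss = np.random.SeedSequence((int(seed), 1, int(run)))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def assign_folds(y_encoded, family: str, n_samples: int, n_runs: int, n_folds: int,
                 seed: int) -> np.ndarray:
    """Per-run fold memberships, shape (n_runs, N) with entries in 0..n_folds-1.

    Categorical families use stratified folds so that every class appears in
    every in-bag set; assignments are reproducible from (seed, run) alone and
    therefore shared across α values.
    """
    folds = np.empty((n_runs, n_samples), dtype=int)
    idx = np.arange(n_samples)
    for r in range(n_runs):
        rs = _run_seed(seed, r)
        if family == "linear":
            splitter = KFold(n_splits=n_folds, shuffle=True, random_state=rs)
            split = splitter.split(idx)
        else:
            y_int = np.asarray(y_encoded, dtype=int)
            counts = np.bincount(y_int)
            small = np.nonzero((counts > 0) & (counts < n_folds))[0]
            if len(small):
                raise ValueError(
                    f"class index {small.tolist()} has fewer members than n_folds={n_folds}"
                )
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
            split = splitter.split(idx, y_int)
        for f, (_, test) in enumerate(split):
            folds[r, test] = f
    return folds


def _ridge_path(xs: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Closed-form ridge coefficients (p, L) for standardized X, centered y:
    minimize (1/2n)‖y − Xβ‖² + (λ/2)‖β‖²."""
    n = xs.shape[0]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    uty = u.T @ yc
    shrink = s[:, None] / (s[:, None] ** 2 + n * np.asarray(lambdas)[None, :])
    return vt.T @ (shrink * uty[:, None])


def fit_fold_path_linear(x, y, in_bag, alpha, lambdas, tol=1e-4, max_iter=2000):
    """Fit the elastic-net path on in-bag rows; return original-scale
    coefficients (p, L) and intercepts (L,)."""
    xb = x[in_bag]
    yb = np.asarray(y, dtype=float)[in_bag]
    mu, sd = _standardize_params(xb)
    xs = (xb - mu) / sd
    ym = yb.mean()
    yc = yb - ym
    lambdas = np.asarray(lambdas, dtype=float)
    if alpha <= 0:
        coefs_std = _ridge_path(xs, yc, lambdas)
    else:
        _, coefs_std, _ = enet_path(
            xs, yc, l1_ratio=alpha, alphas=lambdas, tol=tol, max_iter=max_iter
        )
    coefs = coefs_std / sd[:, None]
    intercepts = ym - mu @ coefs
    return coefs, intercepts


def fit_fold_path_logistic(x, y_encoded, n_classes, in_bag, alpha, lambdas,
                           tol=1e-4, max_iter=2000):
    """Regularized logistic path on in-bag rows via the saga solver.

    Returns original-scale coefficients, shape (C, p, L) with C = 1 for
    binomial (positive class = class index 1) and C = K for multinomial,
    plus intercepts (C, L).  A non-converged λ is retried once with a relaxed
    tolerance; on solver failure that λ is marked undefined (NaN) and logged.
    """
    xb = x[in_bag]
    yb = np.asarray(y_encoded, dtype=int)[in_bag]
    mu, sd = _standardize_params(xb)
    xs = (xb - mu) / sd
    n_ib = xs.shape[0]
    lambdas = np.asarray(lambdas, dtype=float)
    n_coef = 1 if n_classes == 2 else n_classes
    p = x.shape[1]
    coefs = np.full((n_coef, p, len(lambdas)), np.nan)
    intercepts = np.full((n_coef, len(lambdas)), np.nan)
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        warm_start=True,
        tol=tol,
        max_iter=max_iter,
        fit_intercept=True,
    )
    for li, lam in enumerate(lambdas):
        clf.C = 1.0 / (n_ib * lam)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(xs, yb)
                if clf.n_iter_.max() >= max_iter:
                    clf.tol = tol * 10
                    clf.fit(xs, yb)
                    clf.tol = tol
        except Exception as exc:  # pragma: no cover - solver failure path
            logger.warning("solver failed at λ=%.4g (α=%.2f): %s", lam, alpha, exc)
            continue
        w = clf.coef_ / sd[None, :]
        coefs[:, :, li] = w
        intercepts[:, li] = clf.intercept_ - w @ mu
    return coefs, intercepts


def _probabilities(x_oob, coefs, intercepts, n_classes):
    """OOB class probabilities (n_oob, K, L) from original-scale coefficients."""
    n_coef, p, n_lam = coefs.shape
    n_oob = x_oob.shape[0]
    prob = np.full((n_oob, n_classes, n_lam), np.nan)
    for li in range(n_lam):
        w = coefs[:, :, li]
        if np.isnan(w).any():
            continue
        z = x_oob @ w.T + intercepts[:, li]
        if n_classes == 2:
            p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
            prob[:, 1, li] = p1
            prob[:, 0, li] = 1.0 - p1
        else:
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            prob[:, :, li] = e / e.sum(axis=1, keepdims=True)
    return prob


@dataclass
class AlphaFit:
    """Fitted elastic-net family member at one α."""

    alpha: float
    lambdas: np.ndarray               # (L,), descending
    qf_by_lambda_run: np.ndarray      # (L, R)
    lambda_star: float
    lambda_star_idx: int
    qf_model_runs: np.ndarray         # (R,) QF at λ*
    oob_predictions: np.ndarray       # (R, N) linear or (R, N, K) categorical, at λ*
    coefficients: np.ndarray          # (R, F, C, p) original scale at λ*
    flat_profile: bool


def select_lambda_star(qf_by_lambda_run: np.ndarray, lambdas: np.ndarray):
    """Maximize the run-averaged QF over the grid.

    A λ with an undefined QF in any run is treated as worst possible.  Exact
    ties choose the larger λ.  A flat or monotonic profile triggers a warning
    (the λ range may need extension).
    """
    q = np.asarray(qf_by_lambda_run, dtype=float)
    means = q.mean(axis=1)  # NaN wherever any run undefined
    valid = ~np.isnan(means)
    if not valid.any():
        raise RuntimeError("quality function undefined at every λ")
    objective = np.where(valid, means, -np.inf)
    idx = int(np.argmax(objective))  # first max = largest λ (grid descends)
    vm = means[valid]
    flat = bool(np.ptp(vm) < 1e-12) or idx in (0, len(lambdas) - 1)
    if flat:
        logger.warning(
            "QF(λ) profile is flat or peaks at the grid boundary; "
            "consider extending the λ range (n_lambda_ext)"
        )
    return idx, float(lambdas[idx]), q[idx, :], flat


def fit_alpha(x_values, y_encoded, family, n_classes, alpha, lambdas, folds, scorer,
              tol=1e-4, max_iter=2000) -> AlphaFit:
    """Run the model-building module at one α: per-run CV fits across the λ
    grid, per-(λ, run) OOB quality, λ* selection, and λ*-slice extraction."""
    x = np.asarray(x_values, dtype=float)
    n, p = x.shape
    n_runs, _ = folds.shape
    n_folds = int(folds.max()) + 1
    n_lam = len(lambdas)
    n_coef = 1 if family in ("linear", "binomial") else n_classes

    qf = np.full((n_lam, n_runs), np.nan)
    if family == "linear":
        oob_all = np.full((n_runs, n, n_lam), np.nan)
    else:
        oob_all = np.full((n_runs, n, n_classes, n_lam), np.nan)
    coef_all = np.full((n_runs, n_folds, n_coef, p, n_lam), np.nan)

    for r in range(n_runs):
        for f in range(n_folds):
            oob = folds[r] == f
            ib = ~oob
            if family == "linear":
                coefs, icpt = fit_fold_path_linear(
                    x, y_encoded, ib, alpha, lambdas, tol=tol, max_iter=max_iter
                )
                coef_all[r, f, 0] = coefs
                oob_all[r, oob, :] = x[oob] @ coefs + icpt
            else:
                coefs, icpt = fit_fold_path_logistic(
                    x, y_encoded, n_classes, ib, alpha, lambdas,
                    tol=tol, max_iter=max_iter,
                )
                coef_all[r, f] = coefs
                oob_all[r, oob, :, :] = _probabilities(x[oob], coefs, icpt, n_classes)
        for li in range(n_lam):
            pred = oob_all[r, :, li] if family == "linear" else oob_all[r, :, :, li]
            if np.isnan(np.asarray(pred, dtype=float)).any():
                continue
            qf[li, r] = scorer(pred, y_encoded)

    idx, lam_star, qf_runs, flat = select_lambda_star(qf, lambdas)
    oob_star = oob_all[:, :, idx] if family == "linear" else oob_all[:, :, :, idx]
    return AlphaFit(
        alpha=float(alpha),
        lambdas=np.asarray(lambdas, dtype=float),
        qf_by_lambda_run=qf,
        lambda_star=lam_star,
        lambda_star_idx=idx,
        qf_model_runs=qf_runs,
        oob_predictions=oob_star.copy(),
        coefficients=coef_all[:, :, :, :, idx].copy(),
        flat_profile=flat,
    )


def summarize_oob(fit: AlphaFit, y_encoded, family: str, n_classes: int | None = None):
    """Per-sample OOB summary.

    Linear: mean and sd (ddof=1, NaN for a single run) of the OOB prediction
    across runs.  Categorical: per-sample fraction of runs with a correct OOB
    class, plus the run-averaged K×K contingency matrix (true × predicted);
    its row sums equal the true class sizes.
    """
    from .quality import predicted_labels

    if family == "linear":
        preds = fit.oob_predictions  # (R, N)
        mean = preds.mean(axis=0)
        if preds.shape[0] < 2:
            logger.warning("single run: per-sample OOB sd is undefined")
            sd = np.full(preds.shape[1], np.nan)
        else:
            sd = preds.std(axis=0, ddof=1)
        return {"pred_mean": mean, "pred_sd": sd}
    y_int = np.asarray(y_encoded, dtype=int)
    n_runs, n, _ = fit.oob_predictions.shape
    correct = np.zeros(n)
    contingency = np.zeros((n_classes, n_classes))
    for r in range(n_runs):
        labels = predicted_labels(fit.oob_predictions[r], family)
        correct += labels == y_int
        np.add.at(contingency, (y_int, labels), 1.0)
    return {
        "accuracy_per_sample": correct / n_runs,
        "contingency_mean": contingency / n_runs,
    }
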