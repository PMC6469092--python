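"""Null-model ensembles and empirical significance.

For each α, a null ensemble is built by refitting the cross-validation models
after randomly permuting the response's sample labels — the feature matrix
and the model's fold assignments stay fixed, and every null fit is evaluated
at the model's λ*.  The empirical model p-value compares the per-run model QF
against the pooled null QF draws:

    p = (1 + Σ_{r,p} Θ(QF_null^{r,p} − QF_model^r)) / (1 + n_r·n_p)

with Θ the right-continuous Heaviside step, so exact ties count against the
model; under permutation sampling with replacement this is a conservative
estimate bounded below by 1/(1 + n_r·n_p).  Feature-level p-values reuse the
same formula with ν (selection frequency) or |κ| (coefficient magnitude) in
place of QF.  Undefined entries (NaN) are dropped from both the count and the
denominator, with a logged tally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import cv as _cv
from . import features as _features

logger = logging.getLogger(__name__)


def permute_response(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of the response values over the samples."""
    return rng.permutation(np.asarray(values))


def empirical_pvalue(model_values, null_values) -> float:
    """Permutation p-value of Eq. form (1 + #{null ≥ model}) / (1 + n_r·n_p).

    ``model_values`` has length n_r; ``null_values`` is (n_r, n_p) with
    null_values[r, p] compared against model_values[r].  NaN entries on
    either side remove the pair from numerator and denominator.
    """
    model = np.asarray(model_values, dtype=float)
    null = np.asarray(null_values, dtype=float)
    if null.ndim == 1:
        null = null[None, :]
    if null.shape[0] != model.shape[0]:
        raise ValueError("null_values must have one row per model run")
    if null.size == 0:
        raise ValueError("empty null ensemble")
    defined = ~np.isnan(null) & ~np.isnan(model)[:, None]
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValueError("no defined model-null comparisons")
    dropped = null.size - n_def
    if dropped:
        logger.warning("dropped %d undefined model-null comparisons", dropped)
    exceed = int(np.sum((null >= model[:, None]) & defined))
    return (1 + exceed) / (1 + n_def)


def feature_pvalues(model_stat_runs: np.ndarray, null_stat: np.ndarray) -> np.ndarray:
    """Per-feature (per-class) empirical p-values.

    ``model_stat_runs``: (R, C, p) per-run statistic (ν, or |κ| with missing
    as 0); ``null_stat``: (R, P, C, p).  Vectorized over features with the
    same tie rule Θ(0)=1 as the model p-value.
    """
    model = np.asarray(model_stat_runs, dtype=float)
    null = np.asarray(null_stat, dtype=float)
    exceed = (null >= model[:, None]).sum(axis=(0, 1))
    n_cmp = null.shape[0] * null.shape[1]
    return (1 + exceed) / (1 + n_cmp)


def annotate_significance(p: float) -> str:
    """Customary dot/asterisk annotation: *** <0.001, ** <0.01, * <0.05, · <0.1."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "·"
    return ""


@dataclass
class NullEnsemble:
    """Permutation-null results at one α, evaluated at the model's λ*."""

    qf: np.ndarray        # (R, P)
    nu: np.ndarray        # (R, P, C, p)
    kappa: np.ndarray     # (R, P, C, p), NaN where never selected
    n_undefined: int


def _permutation_rng(seed: int, alpha_idx: int, run: int, perm: int) -> np.random.Generator:
    ss = np.random.SeedSequence((int(seed), 2, int(alpha_idx), int(run), int(perm)))
    return np.random.default_rng(ss)


def build_null_ensemble(
    x_values: np.ndarray,
    y_encoded: np.ndarray,
    family: str,
    n_classes: int | None,
    alpha: float,
    alpha_idx: int,
    lambda_star: float,
    folds: np.ndarray,
    n_perm_per_run: int,
    scorer,
    seed: int,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> NullEnsemble:
    """Fit n_r × n_p permutation-null CV models at λ* with the model's folds.

    Each (run, permutation) pair draws an independent response permutation
    from a seed derived from (master seed, α index, run, permutation).  A
    permutation whose QF is undefined is kept as NaN; more than 20% undefined
    entries is a hard error.
    """
    x = np.asarray(x_values, dtype=float)
    n, p = x.shape
    n_runs = folds.shape[0]
    n_folds = int(folds.max()) + 1
    n_coef = 1 if family in ("linear", "binomial") else n_classes
    lam = np.array([lambda_star], dtype=float)

    qf_null = np.full((n_runs, n_perm_per_run), np.nan)
    nu_null = np.full((n_runs, n_perm_per_run, n_coef, p), np.nan)
    kappa_null = np.full((n_runs, n_perm_per_run, n_coef, p), np.nan)

    for r in range(n_runs):
        for pi in range(n_perm_per_run):
            rng = _permutation_rng(seed, alpha_idx, r, pi)
            y_perm = permute_response(y_encoded, rng)
            if family == "linear":
                oob_pred = np.full(n, np.nan)
            else:
                oob_pred = np.full((n, n_classes), np.nan)
            coefs_folds = np.full((n_folds, n_coef, p), np.nan)
            for f in range(n_folds):
                oob = folds[r] == f
                ib = ~oob
                if family == "linear":
                    coefs, icpt = _cv.fit_fold_path_linear(
                        x, y_perm, ib, alpha, lam, tol=tol, max_iter=max_iter
                    )
                    coefs_folds[f, 0] = coefs[:, 0]
                    oob_pred[oob] = x[oob] @ coefs[:, 0] + icpt[0]
                else:
                    coefs, icpt = _cv.fit_fold_path_logistic(
                        x, y_perm, n_classes, ib, alpha, lam, tol=tol, max_iter=max_iter
                    )
                    coefs_folds[f] = coefs[:, :, 0]
                    oob_pred[oob] = _cv._probabilities(x[oob], coefs, icpt, n_classes)[:, :, 0]
            if not np.isnan(np.asarray(oob_pred, dtype=float)).any():
                qf_null[r, pi] = scorer(oob_pred, y_perm)
            nu_null[r, pi] = _features.run_feature_frequency(coefs_folds)
            kappa_null[r, pi] = _features.run_feature_coefficient(coefs_folds)

    n_undef = int(np.isnan(qf_null).sum())
    if n_undef:
        logger.warning("%d of %d null QF entries undefined", n_undef, qf_null.size)
    if n_undef > 0.2 * qf_null.size:
        raise RuntimeError(
            f"{n_undef}/{qf_null.size} null fits undefined (>20%); "
            "null ensemble is unreliable"
        )
    return NullEnsemble(qf=qf_null, nu=nu_null, kappa=kappa_null, n_undefined=n_undef)
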