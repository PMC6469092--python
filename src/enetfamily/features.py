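"""Per-run and aggregated feature statistics at λ*.

Within a run, each feature is summarized by its selection frequency ν — the
fraction of folds in which it received a non-zero coefficient — and its
coefficient κ — the mean of its non-zero coefficients across folds (missing
when the feature was never selected in the run).  Across runs, frequencies
are averaged plainly (mean and sample sd) while coefficients are averaged
with weights w^r ∝ ν^r, so runs that selected the feature more often count
more; the weighted sd uses the population form.  For multinomial models all
statistics are computed independently per class.

Array convention: coefficient tensors have shape (runs, folds, C, p) where
C = 1 for linear/binomial and C = K for multinomial; statistics keep the
(C, p) trailing shape.
"""

from __future__ import annotations

import numpy as np


def run_feature_frequency(coefs_by_fold: np.ndarray) -> np.ndarray:
    """ν for one run: fraction of folds with a non-zero coefficient.

    ``coefs_by_fold`` has shape (n_folds, C, p); folds whose fit failed
    entirely (all-NaN) are excluded from the denominator.
    """
    c = np.asarray(coefs_by_fold, dtype=float)
    defined = ~np.isnan(c)
    nonzero = defined & (c != 0)
    denom = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        nu = np.where(denom > 0, nonzero.sum(axis=0) / np.maximum(denom, 1), 0.0)
    return nu


def run_feature_coefficient(coefs_by_fold: np.ndarray) -> np.ndarray:
    """κ for one run: mean of non-zero coefficients across folds; NaN if none."""
    c = np.asarray(coefs_by_fold, dtype=float)
    nonzero = ~np.isnan(c) & (c != 0)
    count = nonzero.sum(axis=0)
    total = np.where(nonzero, c, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        kappa = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return kappa


def run_stats(coefficients: np.ndarray):
    """ν and κ for every run from a (runs, folds, C, p) coefficient tensor."""
    nu = np.stack([run_feature_frequency(coefficients[r]) for r in range(coefficients.shape[0])])
    kappa = np.stack(
        [run_feature_coefficient(coefficients[r]) for r in range(coefficients.shape[0])]
    )
    return nu, kappa


def aggregate_feature_stats(nu_runs: np.ndarray, kappa_runs: np.ndarray) -> dict:
    """Aggregate per-run ν and κ over runs.

    freq_mean / freq_sd: plain mean and sample sd (ddof=1; NaN for one run)
    of ν.  coef_wmean / coef_wsd: ν-weighted mean and population-form weighted
    sd of κ; missing (NaN) wherever ν = 0 in every run.
    """
    nu = np.asarray(nu_runs, dtype=float)          # (R, C, p)
    kappa = np.asarray(kappa_runs, dtype=float)
    n_runs = nu.shape[0]
    freq_mean = nu.mean(axis=0)
    freq_sd = nu.std(axis=0, ddof=1) if n_runs > 1 else np.full(nu.shape[1:], np.nan)
    w = nu
    k0 = np.where(np.isnan(kappa), 0.0, kappa)     # weight is 0 wherever κ missing
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        wmean = np.where(wsum > 0, (w * k0).sum(axis=0) / wsum, np.nan)
        wvar = np.where(wsum > 0, (w * (k0 - wmean) ** 2).sum(axis=0) / wsum, np.nan)
    return {
        "freq_mean": freq_mean,
        "freq_sd": freq_sd,
        "coef_wmean": wmean,
        "coef_wsd": np.sqrt(wvar),
    }
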