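"""Model and results objects for elastic-net family exploration.

:class:`ElasticNetFamily` holds the data and configuration; ``fit()`` runs,
for every mixing parameter α, the three-stage procedure — (a) model building:
λ-path construction on the full data, n_r randomized cross-validation runs of
n_f folds each, λ* selection by out-of-bag quality maximization; (b) null
building: n_p response permutations per run refit at λ* with the same folds;
(c) model-vs-null comparison: empirical p-values for the whole model and for
every feature via its selection frequency ν and coefficient magnitude |κ|.

The returned :class:`ElasticNetFamilyResults` carries estimates,
uncertainties and significance, and exposes ``summary()``, per-α feature
tables, OOB summaries, plotting and a diff-able CSV/JSON archive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cv as _cv
from . import features as _features
from . import significance as _sig
from .data import FamilyConfig, FeatureMatrix, Response, validate_inputs
from .quality import make_scorer


@dataclass
class AlphaResult:
    """Everything fitted at one α: model arm, null arm and their comparison."""

    fit: _cv.AlphaFit
    null: _sig.NullEnsemble | None
    model_pvalue: float
    nu_runs: np.ndarray          # (R, C, p)
    kappa_runs: np.ndarray       # (R, C, p)
    feature_stats: dict          # freq_mean/freq_sd/coef_wmean/coef_wsd, each (C, p)
    pvalue_freq: np.ndarray | None   # (C, p)
    pvalue_coef: np.ndarray | None   # (C, p)


def _coerce_x(x) -> FeatureMatrix:
    if isinstance(x, FeatureMatrix):
        return x
    if isinstance(x, pd.DataFrame):
        return FeatureMatrix.from_dataframe(x)
    x = np.asarray(x, dtype=float)
    return FeatureMatrix(
        x,
        [f"s{i + 1:04d}" for i in range(x.shape[0])],
        [f"f{j + 1:03d}" for j in range(x.shape[1])],
    )


def _coerce_y(y, family: str | None, x: FeatureMatrix) -> Response:
    if isinstance(y, Response):
        resp = y
    else:
        ids = list(y.index.astype(str)) if isinstance(y, pd.Series) else None
        arr = np.asarray(y)
        if family is None:
            family = "linear" if np.issubdtype(arr.dtype, np.floating) else None
            if family is None:
                family = "binomial" if len(set(map(str, arr))) == 2 else "multinomial"
        resp = Response(arr, family, sample_ids=ids)
    if family is not None and resp.family != family:
        raise ValueError(
            f"response family {resp.family!r} does not match requested {family!r}"
        )
    if resp.sample_ids is not None and resp.sample_ids != x.sample_ids:
        resp = resp.align_to(x.sample_ids)
    return resp


class ElasticNetFamily:
    """Elastic-net model family over a feature matrix and a response.

    Parameters
    ----------
    x : FeatureMatrix, DataFrame or ndarray
        N × p predictors; DataFrame index/columns become sample IDs and
        feature names.
    y : Response, Series or array
        Numeric (linear), 2-level (binomial) or K-level (multinomial)
        response; a Series is aligned to ``x`` by its index.
    family : str, optional
        linear / binomial / multinomial; inferred from ``y`` when omitted.
    config : FamilyConfig, optional
        Full run configuration; keyword overrides (``alphas=…``,
        ``n_runs=…``, ...) are applied on top.

    Examples
    --------
    >>> model = ElasticNetFamily(x, y, family="linear", alphas=(0, 0.5, 1),
    ...                          n_runs=10, n_folds=5, n_perm_per_run=10)
    >>> results = model.fit(seed=42)
    >>> results.summary()
    """

    def __init__(self, x, y, family: str | None = None,
                 config: FamilyConfig | None = None, **overrides):
        self.x = _coerce_x(x)
        self.y = _coerce_y(y, family, self.x)
        self.family = self.y.family
        cfg = config if config is not None else FamilyConfig()
        if overrides:
            cfg = FamilyConfig(**{**cfg.to_dict(), **overrides})
        self.config = cfg
        report = validate_inputs(self.x, self.y, cfg)
        report.raise_if_invalid()
        self.classes = self.y.classes
        self.n_classes = None if self.classes is None else len(self.classes)

    @classmethod
    def from_files(cls, x_path, y_path, family: str, sep: str | None = None, **overrides):
        """Build from a matrix CSV/TSV and a two-column response file."""
        x = FeatureMatrix.read_csv(x_path, sep=sep)
        y = Response.read_csv(y_path, family, sep=sep)
        return cls(x, y.align_to(x.sample_ids), family=family, **overrides)

    def fit(self, seed: int | None = None, compute_null: bool = True
            ) -> "ElasticNetFamilyResults":
        """Run the full procedure for every α.

        Parameters
        ----------
        seed : int, optional
            Overrides ``config.seed`` for fold assignment and permutations.
        compute_null : bool
            When False, skip the permutation arm (no p-values); useful for
            quick model-quality exploration.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        y_enc = self.y.encoded()
        scorer = make_scorer(self.family, cfg.qf_name, cfg.cor_method, self.classes)
        folds = _cv.assign_folds(
            y_enc, self.family, self.x.n, cfg.n_runs, cfg.n_folds, seed
        )
        results: dict[float, AlphaResult] = {}
        for ai, alpha in enumerate(cfg.alphas):
            grid = _cv.make_lambda_grid(
                self.x.values, y_enc, self.family, alpha, cfg.n_lambda,
                n_classes=self.n_classes, lambda_min_ratio=cfg.lambda_min_ratio,
            )
            if cfg.n_lambda_ext is not None:
                grid = _cv.extend_lambda_grid(grid, cfg.n_lambda_ext)
            fit = _cv.fit_alpha(
                self.x.values, y_enc, self.family, self.n_classes, alpha, grid,
                folds, scorer, tol=cfg.tol, max_iter=cfg.max_iter,
            )
            nu_runs, kappa_runs = _features.run_stats(fit.coefficients)
            stats = _features.aggregate_feature_stats(nu_runs, kappa_runs)
            null = None
            model_p = float("nan")
            p_freq = p_coef = None
            if compute_null:
                null = _sig.build_null_ensemble(
                    self.x.values, y_enc, self.family, self.n_classes, alpha, ai,
                    fit.lambda_star, folds, cfg.n_perm_per_run, scorer, seed,
                    tol=cfg.tol, max_iter=cfg.max_iter,
                )
                model_p = _sig.empirical_pvalue(fit.qf_model_runs, null.qf)
                abs_k_model = np.abs(np.where(np.isnan(kappa_runs), 0.0, kappa_runs))
                abs_k_null = np.abs(np.where(np.isnan(null.kappa), 0.0, null.kappa))
                p_freq = _sig.feature_pvalues(nu_runs, null.nu)
                p_coef = _sig.feature_pvalues(abs_k_model, abs_k_null)
            results[float(alpha)] = AlphaResult(
                fit=fit, null=null, model_pvalue=model_p,
                nu_runs=nu_runs, kappa_runs=kappa_runs, feature_stats=stats,
                pvalue_freq=p_freq, pvalue_coef=p_coef,
            )
        return ElasticNetFamilyResults(self, results, seed)


class ElasticNetFamilyResults:
    """Fitted elastic-net family: estimates, significance and exports."""

    def __init__(self, model: ElasticNetFamily, alpha_results: dict, seed: int):
        self.model = model
        self.family = model.family
        self.classes = model.classes
        self.feature_names = model.x.feature_names
        self.sample_ids = model.x.sample_ids
        self.config = model.config
        self.seed = seed
        self.alphas = list(alpha_results)
        self.alpha_results = alpha_results

    def _res(self, alpha: float) -> AlphaResult:
        key = float(alpha)
        if key not in self.alpha_results:
            raise KeyError(f"alpha {alpha} not fitted; available: {self.alphas}")
        return self.alpha_results[key]

    # ------------------------------------------------------------------ tables

    def summary(self) -> pd.DataFrame:
        """Per-α model summary: λ*, mean±sd of the OOB QF across runs, and the
        model-vs-null empirical p-value with its annotation."""
        rows = []
        for alpha in self.alphas:
            r = self._res(alpha)
            q = r.fit.qf_model_runs
            rows.append({
                "alpha": alpha,
                "lambda_star": r.fit.lambda_star,
                "qf_mean": float(np.nanmean(q)),
                "qf_sd": float(np.nanstd(q, ddof=1)) if len(q) > 1 else float("nan"),
                "model_pvalue": r.model_pvalue,
                "significance": _sig.annotate_significance(r.model_pvalue),
            })
        return pd.DataFrame(rows)

    def _class_labels(self):
        if self.family == "multinomial":
            return self.classes
        return [None]

    def feature_table(self, alpha: float, cls: str | None = None) -> pd.DataFrame:
        """Per-feature statistics and p-values at one α (one class for
        multinomial).  Missing coefficients stay NaN (exported as empty)."""
        r = self._res(alpha)
        if self.family == "multinomial":
            if cls is None:
                raise ValueError(f"multinomial family: pass cls from {self.classes}")
            ci = self.classes.index(cls)
        else:
            ci = 0
        stats = r.feature_stats
        df = pd.DataFrame({
            "feature": self.feature_names,
            "freq_mean": stats["freq_mean"][ci],
            "freq_sd": stats["freq_sd"][ci],
            "coef_wmean": stats["coef_wmean"][ci],
            "coef_wsd": stats["coef_wsd"][ci],
        })
        if r.null is not None:
            df["null_freq_mean"] = r.null.nu[:, :, ci, :].mean(axis=(0, 1))
            df["null_freq_sd"] = r.null.nu[:, :, ci, :].std(axis=(0, 1), ddof=1)
            k0 = np.where(np.isnan(r.null.kappa), 0.0, r.null.kappa)
            df["null_coef_mean"] = k0[:, :, ci, :].mean(axis=(0, 1))
            df["null_coef_sd"] = k0[:, :, ci, :].std(axis=(0, 1), ddof=1)
            df["pvalue_freq"] = r.pvalue_freq[ci]
            df["pvalue_coef"] = r.pvalue_coef[ci]
            df["sig_freq"] = [
                _sig.annotate_significance(p) for p in r.pvalue_freq[ci]
            ]
            df["sig_coef"] = [
                _sig.annotate_significance(p) for p in r.pvalue_coef[ci]
            ]
        return df

    def oob_summary(self, alpha: float) -> pd.DataFrame:
        """Per-sample OOB summary (prediction mean±sd, or accuracy across runs)."""
        r = self._res(alpha)
        s = _cv.summarize_oob(r.fit, self.model.y.encoded(), self.family, self.model.n_classes)
        if self.family == "linear":
            return pd.DataFrame({
                "sample_id": self.sample_ids,
                "observed": self.model.y.values,
                "pred_mean": s["pred_mean"],
                "pred_sd": s["pred_sd"],
            })
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "observed": self.model.y.values,
            "oob_accuracy": s["accuracy_per_sample"],
        })

    def contingency(self, alpha: float) -> pd.DataFrame:
        """Run-averaged true × predicted contingency matrix (categorical only)."""
        if self.family == "linear":
            raise ValueError("contingency matrix is undefined for the linear family")
        r = self._res(alpha)
        s = _cv.summarize_oob(r.fit, self.model.y.encoded(), self.family, self.model.n_classes)
        return pd.DataFrame(s["contingency_mean"], index=self.classes, columns=self.classes)

    def lambda_profile(self, alpha: float) -> pd.DataFrame:
        """λ grid with the run-averaged OOB QF (the λ* selection curve)."""
        r = self._res(alpha)
        with np.errstate(invalid="ignore"):
            qf_mean = r.fit.qf_by_lambda_run.mean(axis=1)
        return pd.DataFrame({"lambda": r.fit.lambdas, "qf_mean": qf_mean})

    # ----------------------------------------------------------------- exports

    def save(self, out_dir) -> None:
        from .io import save_results

        save_results(self, out_dir)

    def export_tables(self, out_dir) -> list:
        from .io import export_tables

        return export_tables(self, out_dir)

    # ------------------------------------------------------------------- plots

    def plot(self, which="all", out_dir=".", alpha: float | None = None, top_k: int = 15):
        from .plots import render_figures

        return render_figures(self, which=which, out_dir=out_dir, alpha=alpha, top_k=top_k)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ElasticNetFamilyResults(family={self.family}, "
            f"alphas={self.alphas}, n_runs={self.config.n_runs})"
        )
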