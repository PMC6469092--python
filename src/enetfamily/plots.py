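"""Standard visualizations of a fitted elastic-net family.

All functions consume any results view exposing the table accessors
(``summary``, ``feature_table``, ``oob_summary``, ``lambda_profile``,
``contingency``) — a fitted results object or a loaded archive — and write
PNG files.  Plot kinds:

summary           QF mean±sd (left axis) and model p-value (right axis) vs α
lambda_profile    run-averaged QF vs λ with the chosen λ* marked
oob_scatter       observed response vs OOB prediction mean±sd (linear)
caterpillar_freq  top features ranked by frequency p-value: model (red) vs
                  null (blue) mean±sd with dot/asterisk annotations
caterpillar_coef  same for coefficient statistics
heatmap_freq      feature × α heatmap of mean selection frequency
heatmap_coef      feature × α heatmap of weighted mean coefficients
                  (diverging scale centered at 0; missing cells blank)
contingency       run-averaged true × predicted class matrix (categorical)
class_boxplot     per-class distribution of per-sample OOB accuracy
"""

from __future__ import annotations

import logging
import pathlib

import matplotlib

if not matplotlib.get_backend().lower().startswith(("agg", "module")):  # pragma: no cover
    try:
        matplotlib.use("Agg")
    except Exception:
        pass

import matplotlib.pyplot as plt
import numpy as np

logger = logging.getLogger(__name__)

PLOT_KINDS = (
    "summary",
    "lambda_profile",
    "oob_scatter",
    "caterpillar_freq",
    "caterpillar_coef",
    "heatmap_freq",
    "heatmap_coef",
    "contingency",
    "class_boxplot",
)


def _save(fig, out_dir, name):
    path = pathlib.Path(out_dir) / f"{name}.png"
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_summary(results, out_dir="."):
    df = results.summary()
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.errorbar(df["alpha"], df["qf_mean"], yerr=df["qf_sd"], color="tab:red",
                 marker="o", capsize=3, label="OOB QF")
    ax1.set_xlabel("alpha (ridge → lasso)")
    ax1.set_ylabel("OOB quality function", color="tab:red")
    ax2 = ax1.twinx()
    ax2.plot(df["alpha"], df["model_pvalue"], color="tab:blue", marker="s",
             label="model p-value")
    ax2.set_ylabel("model vs null p-value", color="tab:blue")
    ax2.set_yscale("log")
    ax1.set_title("Model performance and significance across the family")
    return _save(fig, out_dir, "summary")


def plot_lambda_profile(results, alpha, out_dir="."):
    df = results.lambda_profile(alpha)
    lam_star = results.summary().set_index("alpha").loc[float(alpha), "lambda_star"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["lambda"], df["qf_mean"], marker=".", color="tab:red")
    ax.axvline(lam_star, linestyle="--", color="grey", label=f"λ* = {lam_star:.3g}")
    ax.set_xscale("log")
    ax.set_xlabel("lambda")
    ax.set_ylabel("mean OOB QF across runs")
    ax.set_title(f"λ selection (alpha = {alpha:g})")
    ax.legend()
    return _save(fig, out_dir, f"lambda_profile_alpha{alpha:g}")


def plot_oob_scatter(results, alpha, out_dir="."):
    if results.family != "linear":
        logger.warning("oob_scatter applies to the linear family only; skipped")
        return None
    df = results.oob_summary(alpha)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.errorbar(df["pred_mean"], df["observed"], xerr=df["pred_sd"], fmt="o",
                ms=4, alpha=0.7, ecolor="lightgray")
    lo = min(df["pred_mean"].min(), df["observed"].min())
    hi = max(df["pred_mean"].max(), df["observed"].max())
    ax.plot([lo, hi], [lo, hi], ls=":", color="grey")
    ax.set_xlabel("OOB prediction (mean ± sd across runs)")
    ax.set_ylabel("observed response")
    ax.set_title(f"Response vs out-of-bag predictions (alpha = {alpha:g})")
    return _save(fig, out_dir, f"oob_scatter_alpha{alpha:g}")


def _caterpillar(results, alpha, stat, out_dir, top_k, cls=None):
    df = results.feature_table(alpha, cls) if cls is not None else results.feature_table(alpha)
    pcol = f"pvalue_{stat}"
    if pcol not in df:
        logger.warning("no null ensemble in results; caterpillar plot skipped")
        return None
    mcol, scol = (("freq_mean", "freq_sd") if stat == "freq" else ("coef_wmean", "coef_wsd"))
    ncol, nscol = (("null_freq_mean", "null_freq_sd") if stat == "freq"
                   else ("null_coef_mean", "null_coef_sd"))
    # rank: ascending p-value, ties broken by freq_mean descending
    df = df.sort_values([pcol, "freq_mean"], ascending=[True, False]).head(top_k)
    df = df.iloc[::-1]  # most significant on top
    ypos = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(df) + 1.5))
    ax.errorbar(df[mcol], ypos + 0.12, xerr=df[scol], fmt="o", color="tab:red",
                capsize=2, label="model")
    ax.errorbar(df[ncol], ypos - 0.12, xerr=df[nscol], fmt="o", color="tab:blue",
                capsize=2, label="null")
    ax.set_yticks(ypos)
    sig = df[f"sig_{stat}"].fillna("") if f"sig_{stat}" in df else [""] * len(df)
    ax.set_yticklabels([f"{f} {s}" for f, s in zip(df["feature"], sig)])
    ax.set_xlabel("selection frequency" if stat == "freq" else "coefficient")
    title = f"Top features by {stat} p-value (alpha = {alpha:g}"
    title += f", class {cls})" if cls is not None else ")"
    ax.set_title(title)
    ax.legend()
    suffix = f"_class_{cls}" if cls is not None else ""
    return _save(fig, out_dir, f"caterpillar_{stat}_alpha{alpha:g}{suffix}")


def plot_caterpillar(results, alpha, stat="freq", out_dir=".", top_k=15):
    if results.family == "multinomial":
        return [
            _caterpillar(results, alpha, stat, out_dir, top_k, cls=c)
            for c in results.classes
        ]
    return _caterpillar(results, alpha, stat, out_dir, top_k)


def _heatmap(results, stat, out_dir, top_k, cls=None):
    alphas = sorted(float(a) for a in results.alphas)
    cols = {}
    for a in alphas:
        df = results.feature_table(a, cls) if cls is not None else results.feature_table(a)
        df = df.set_index("feature")
        cols[a] = df["freq_mean" if stat == "freq" else "coef_wmean"]
    mat = np.column_stack([cols[a].to_numpy() for a in alphas])
    feats = list(cols[alphas[0]].index)
    # order rows by the last α's frequency p-value when available
    ref = results.feature_table(alphas[-1], cls) if cls is not None else results.feature_table(alphas[-1])
    if "pvalue_freq" in ref:
        order = ref.sort_values(["pvalue_freq", "freq_mean"],
                                ascending=[True, False])["feature"].head(top_k)
        keep = [feats.index(f) for f in order]
    else:
        keep = list(range(min(top_k, len(feats))))
    mat = mat[keep]
    feats = [feats[i] for i in keep]
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(alphas), 0.35 * len(feats) + 1.5))
    if stat == "freq":
        im = ax.imshow(mat, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    else:
        masked = np.ma.masked_invalid(mat)
        vmax = np.nanmax(np.abs(mat)) if np.isfinite(mat).any() else 1.0
        cmap = matplotlib.colormaps["RdBu_r"].copy()
        cmap.set_bad("white")
        im = ax.imshow(masked, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(alphas)))
    ax.set_xticklabels([f"{a:g}" for a in alphas])
    ax.set_yticks(range(len(feats)))
    ax.set_yticklabels(feats)
    ax.set_xlabel("alpha")
    fig.colorbar(im, ax=ax, shrink=0.8,
                 label="mean frequency" if stat == "freq" else "weighted mean coefficient")
    title = "Feature frequencies" if stat == "freq" else "Feature coefficients"
    ax.set_title(title + (f" (class {cls})" if cls is not None else "") + " across α")
    suffix = f"_class_{cls}" if cls is not None else ""
    return _save(fig, out_dir, f"heatmap_{stat}{suffix}")


def plot_heatmap(results, stat="freq", out_dir=".", top_k=15):
    if results.family == "multinomial":
        return [_heatmap(results, stat, out_dir, top_k, cls=c) for c in results.classes]
    return _heatmap(results, stat, out_dir, top_k)


def plot_contingency(results, alpha, out_dir="."):
    if results.family == "linear":
        logger.warning("contingency matrix is inapplicable to the linear family; skipped")
        return None
    cm = results.contingency(alpha)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(cm.to_numpy(), cmap="Blues")
    ax.set_xticks(range(len(cm.columns)))
    ax.set_xticklabels(cm.columns)
    ax.set_yticks(range(len(cm.index)))
    ax.set_yticklabels(cm.index)
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, f"{cm.iloc[i, j]:.1f}", ha="center", va="center")
    ax.set_xlabel("predicted class (OOB)")
    ax.set_ylabel("true class")
    ax.set_title(f"Contingency matrix, run-averaged (alpha = {alpha:g})")
    fig.colorbar(im, ax=ax, shrink=0.8)
    return _save(fig, out_dir, f"contingency_alpha{alpha:g}")


def plot_class_boxplot(results, alpha, out_dir="."):
    if results.family == "linear":
        logger.warning("class boxplot is inapplicable to the linear family; skipped")
        return None
    df = results.oob_summary(alpha)
    groups = [df.loc[df["observed"] == c, "oob_accuracy"] for c in results.classes]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(groups, tick_labels=results.classes)
    ax.set_ylabel("per-sample OOB accuracy across runs")
    ax.set_xlabel("true class")
    ax.set_title(f"Out-of-bag accuracy per class (alpha = {alpha:g})")
    return _save(fig, out_dir, f"class_boxplot_alpha{alpha:g}")


def render_figures(results, which="all", out_dir=".", alpha=None, top_k=15) -> list:
    """Render the requested plot kinds; returns the list of written paths.

    ``alpha`` defaults to the largest fitted α for per-α plots.  Kinds that do
    not apply to the family are skipped with a warning.
    """
    pathlib.Path(out_dir).mkdir(parents=True, exist_ok=True)
    kinds = PLOT_KINDS if which in ("all", None) else (
        (which,) if isinstance(which, str) else tuple(which)
    )
    unknown = set(kinds) - set(PLOT_KINDS)
    if unknown:
        raise ValueError(f"unknown plot kinds {sorted(unknown)}; choose from {PLOT_KINDS}")
    a = float(alpha) if alpha is not None else max(float(v) for v in results.alphas)
    written = []
    for kind in kinds:
        if kind == "summary":
            out = plot_summary(results, out_dir)
        elif kind == "lambda_profile":
            out = plot_lambda_profile(results, a, out_dir)
        elif kind == "oob_scatter":
            out = plot_oob_scatter(results, a, out_dir)
        elif kind == "caterpillar_freq":
            out = plot_caterpillar(results, a, "freq", out_dir, top_k)
        elif kind == "caterpillar_coef":
            out = plot_caterpillar(results, a, "coef", out_dir, top_k)
        elif kind == "heatmap_freq":
            out = plot_heatmap(results, "freq", out_dir, top_k)
        elif kind == "heatmap_coef":
            out = plot_heatmap(results, "coef", out_dir, top_k)
        elif kind == "contingency":
            out = plot_contingency(results, a, out_dir)
        else:
            out = plot_class_boxplot(results, a, out_dir)
        if out is None:
            continue
        written.extend(out if isinstance(out, list) else [out])
    return [p for p in written if p is not None]
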