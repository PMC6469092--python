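"""Result archives: a diff-able directory of JSON metadata and CSV tables.

The archive is language-neutral and deterministic: identical (inputs, config,
seed) produce byte-identical files, with all floats written at 12 significant
digits and missing coefficient statistics rendered as empty fields, never 0.
``load_archive`` reads it back into a lightweight results view that supports
the same table accessors (and therefore the same plots) as a freshly fitted
results object.
"""

from __future__ import annotations

import json
import pathlib

import pandas as pd

from . import __version__

FLOAT_FMT = "%.12g"


def _alpha_dirname(alpha: float) -> str:
    return f"alpha_{alpha:g}"


def _write_csv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)


def export_tables(results, out_dir) -> list:
    """Write the summary, per-α feature tables and OOB tables; returns paths."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / "summary.csv"
    _write_csv(results.summary(), path)
    written.append(path)

    for alpha in results.alphas:
        adir = out / _alpha_dirname(alpha)
        adir.mkdir(exist_ok=True)
        _write_csv(results.lambda_profile(alpha), adir / "lambda_profile.csv")
        written.append(adir / "lambda_profile.csv")
        if results.family == "multinomial":
            for cls in results.classes:
                p = adir / f"features_{cls}.csv"
                _write_csv(results.feature_table(alpha, cls), p)
                written.append(p)
        else:
            p = adir / "features.csv"
            _write_csv(results.feature_table(alpha), p)
            written.append(p)
        _write_csv(results.oob_summary(alpha), adir / "oob.csv")
        written.append(adir / "oob.csv")
        if results.family != "linear":
            _write_csv(results.contingency(alpha), adir / "contingency.csv", index=True)
            written.append(adir / "contingency.csv")
    return written


def save_results(results, out_dir) -> None:
    """Write the full archive: metadata JSON plus every exported table."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "package": "enetfamily",
        "version": __version__,
        "family": results.family,
        "classes": results.classes,
        "seed": results.seed,
        "alphas": [float(a) for a in results.alphas],
        "n_samples": len(results.sample_ids),
        "n_features": len(results.feature_names),
        "config": results.config.to_dict(),
    }
    (out / "config.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    export_tables(results, out)


class ArchiveResults:
    """Read-only view over a saved archive, table-compatible with
    :class:`~enetfamily.model.ElasticNetFamilyResults`."""

    def __init__(self, directory):
        self.dir = pathlib.Path(directory)
        meta = json.loads((self.dir / "config.json").read_text())
        self.family = meta["family"]
        self.classes = meta["classes"]
        self.seed = meta["seed"]
        self.alphas = meta["alphas"]
        self.meta = meta

    def summary(self) -> pd.DataFrame:
        df = pd.read_csv(self.dir / "summary.csv")
        df["alpha"] = df["alpha"].astype(float)
        df["significance"] = df["significance"].fillna("").astype(str)
        return df

    def _adir(self, alpha: float) -> pathlib.Path:
        d = self.dir / _alpha_dirname(float(alpha))
        if not d.is_dir():
            raise KeyError(f"alpha {alpha} not in archive; available: {self.alphas}")
        return d

    def feature_table(self, alpha: float, cls: str | None = None) -> pd.DataFrame:
        if self.family == "multinomial":
            if cls is None:
                raise ValueError(f"multinomial archive: pass cls from {self.classes}")
            path = self._adir(alpha) / f"features_{cls}.csv"
        else:
            path = self._adir(alpha) / "features.csv"
        df = pd.read_csv(path)
        for col in ("sig_freq", "sig_coef"):
            if col in df:
                df[col] = df[col].fillna("")
        return df

    def oob_summary(self, alpha: float) -> pd.DataFrame:
        return pd.read_csv(self._adir(alpha) / "oob.csv")

    def lambda_profile(self, alpha: float) -> pd.DataFrame:
        return pd.read_csv(self._adir(alpha) / "lambda_profile.csv")

    def contingency(self, alpha: float) -> pd.DataFrame:
        if self.family == "linear":
            raise ValueError("contingency matrix is undefined for the linear family")
        return pd.read_csv(self._adir(alpha) / "contingency.csv", index_col=0)

    def plot(self, which="all", out_dir=".", alpha: float | None = None, top_k: int = 15):
        from .plots import render_figures

        return render_figures(self, which=which, out_dir=out_dir, alpha=alpha, top_k=top_k)


def load_archive(directory) -> ArchiveResults:
    return ArchiveResults(directory)
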