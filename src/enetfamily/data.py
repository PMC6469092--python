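"""Input containers, validation and multi-dataset aggregation.

The modelling entry point consumes a samples x features numeric matrix
(:class:`FeatureMatrix`) and a response (:class:`Response`) that is either a
numeric vector (linear family), a two-level factor (binomial) or a K-level
factor (multinomial).  Several feature matrices measured on the same samples
can be column-aggregated into one predictor matrix, keyed on sample IDs so
that row order never matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = ("linear", "binomial", "multinomial")


def _delimiter_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","


class FeatureMatrix:
    """N x p numeric predictor matrix with sample IDs and feature names.

    Parameters
    ----------
    values : array-like, shape (N, p)
        Numeric predictor values. Missing values are allowed at construction
        but rejected by :func:`validate_inputs`.
    sample_ids : sequence of str
        Unique sample identifiers, one per row.
    feature_names : sequence of str
        Unique feature names, one per column.
    """

    def __init__(self, values, sample_ids, feature_names):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        self.sample_ids = [str(s) for s in sample_ids]
        self.feature_names = [str(f) for f in feature_names]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("number of sample_ids does not match rows")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("number of feature_names does not match columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), df.index.astype(str), df.columns.astype(str))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    @classmethod
    def read_csv(cls, path, sep: str | None = None) -> "FeatureMatrix":
        """Read a matrix file: header row = feature names, first column = sample IDs."""
        df = pd.read_csv(path, sep=_delimiter_for(path, sep), index_col=0)
        return cls.from_dataframe(df)

    def write_csv(self, path, sep: str | None = None) -> None:
        self.to_dataframe().to_csv(path, sep=_delimiter_for(path, sep), index_label="sample_id")

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureMatrix(n={self.n}, p={self.p})"


class Response:
    """Observed outcome aligned to a feature matrix.

    For the linear family ``values`` is a numeric vector; for binomial and
    multinomial, a label vector.  ``classes`` is the sorted unique label set
    (the second class is the 'positive' class of binomial coefficient signs
    and probability outputs, mirroring the reference-level convention of
    GLM software).
    """

    def __init__(self, values, family: str, sample_ids=None):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
        self.family = family
        if family == "linear":
            self.values = np.asarray(values, dtype=float)
            self.classes = None
        else:
            self.values = np.asarray([str(v) for v in values], dtype=object)
            self.classes = sorted(set(self.values))
        self.sample_ids = None if sample_ids is None else [str(s) for s in sample_ids]

    def __len__(self) -> int:
        return len(self.values)

    def encoded(self) -> np.ndarray:
        """Integer-encoded labels (0..K-1 in `classes` order); floats for linear."""
        if self.family == "linear":
            return self.values
        index = {c: k for k, c in enumerate(self.classes)}
        return np.array([index[v] for v in self.values], dtype=int)

    def align_to(self, sample_ids) -> "Response":
        """Reorder the response to a target sample-ID order."""
        if self.sample_ids is None:
            raise ValueError("response carries no sample_ids to align by")
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"response is missing sample IDs: {missing[:5]}")
        order = [pos[s] for s in sample_ids]
        return Response(self.values[order], self.family, sample_ids=sample_ids)

    @classmethod
    def read_csv(cls, path, family: str, sep: str | None = None) -> "Response":
        """Read a two-column (sample_id, value) response file, headered or not."""
        delim = _delimiter_for(path, sep)
        df = pd.read_csv(path, sep=delim, header=None, dtype=str)
        if df.shape[1] < 2:
            raise ValueError("response file must have two columns: sample_id, value")
        first = str(df.iloc[0, 1])
        headered = False
        if family == "linear":
            try:
                float(first)
            except ValueError:
                headered = True
        else:
            # categorical: treat the first row as a header when its id cell
            # looks like a column name repeated nowhere else
            headered = str(df.iloc[0, 0]).lower() in {"sample_id", "id", "sample"}
        if headered:
            df = df.iloc[1:]
        ids = df.iloc[:, 0].astype(str).tolist()
        vals = df.iloc[:, 1].to_numpy()
        if family == "linear":
            vals = vals.astype(float)
        return cls(vals, family, sample_ids=ids)

    def __repr__(self) -> str:  # pragma: no cover
        k = "" if self.classes is None else f", K={len(self.classes)}"
        return f"Response(family={self.family}, n={len(self)}{k})"


@dataclass
class FamilyConfig:
    """Run configuration for an elastic-net family.

    Attributes
    ----------
    alphas : tuple of float
        Mixing parameters, ascending in [0, 1]; 0 = ridge, 1 = lasso.
    n_lambda : int
        Number of points on the regularization path computed from the full data.
    n_lambda_ext : int or None
        Optional extended grid length (> n_lambda); the extra points continue
        the geometric spacing symmetrically (odd surplus goes to the small-λ side).
    n_runs, n_folds : int
        Cross-validation repetitions and folds per repetition.
    n_perm_per_run : int
        Response permutations per run for the null ensemble.
    qf_name : str or None
        Quality function; None selects the per-family default (linear →
        correlation, binomial → accuracy, multinomial → average accuracy).
    cor_method : str
        pearson / spearman / kendall, for the linear-family correlation QF.
    seed : int
        Master seed for fold assignment and permutations.
    """

    alphas: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    n_lambda: int = 100
    n_lambda_ext: int | None = None
    n_runs: int = 100
    n_folds: int = 5
    n_perm_per_run: int = 25
    qf_name: str | None = None
    cor_method: str = "pearson"
    seed: int = 0
    lambda_min_ratio: float | None = None
    tol: float = 1e-4
    max_iter: int = 2000

    def __post_init__(self):
        self.alphas = tuple(float(a) for a in self.alphas)

    def to_dict(self) -> dict:
        return {
            "alphas": list(self.alphas),
            "n_lambda": self.n_lambda,
            "n_lambda_ext": self.n_lambda_ext,
            "n_runs": self.n_runs,
            "n_folds": self.n_folds,
            "n_perm_per_run": self.n_perm_per_run,
            "qf_name": self.qf_name,
            "cor_method": self.cor_method,
            "seed": self.seed,
            "lambda_min_ratio": self.lambda_min_ratio,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }


@dataclass
class ValidationIssue:
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover
        return f"[{self.code}] {self.message}"


@dataclass
class ValidationReport:
    issues: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, code: str, message: str) -> None:
        self.issues.append(ValidationIssue(code, message))

    def raise_if_invalid(self) -> None:
        if not self.ok:
            msg = "; ".join(str(i) for i in self.issues)
            raise ValueError(f"invalid inputs: {msg}")


def aggregate_datasets(datasets) -> FeatureMatrix:
    """Column-aggregate feature matrices sharing one sample-ID set.

    Every dataset is row-aligned to the first dataset's sample order before
    concatenation, so row order within inputs is irrelevant.  Duplicate
    feature names across datasets are made unique by deterministic ``_2``,
    ``_3``, ... suffixes (logged).
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets to aggregate")
    ref = datasets[0]
    ref_ids = ref.sample_ids
    ref_set = set(ref_ids)
    blocks, names = [], []
    for d, ds in enumerate(datasets):
        ids = set(ds.sample_ids)
        if ids != ref_set:
            extra = sorted(ids - ref_set)[:5]
            missing = sorted(ref_set - ids)[:5]
            raise ValueError(
                f"dataset {d} sample IDs differ from dataset 0: "
                f"unexpected={extra}, missing={missing}"
            )
        pos = {s: i for i, s in enumerate(ds.sample_ids)}
        order = [pos[s] for s in ref_ids]
        blocks.append(ds.values[order])
        names.extend(ds.feature_names)
    seen: dict[str, int] = {}
    unique = []
    for name in names:
        if name in seen:
            seen[name] += 1
            new = f"{name}_{seen[name]}"
            logger.warning("duplicate feature name %r renamed to %r", name, new)
            unique.append(new)
        else:
            seen[name] = 1
            unique.append(name)
    return FeatureMatrix(np.hstack(blocks), ref_ids, unique)


def validate_inputs(x: FeatureMatrix, y: Response, cfg: FamilyConfig) -> ValidationReport:
    """Check every admissibility invariant; the report lists all violations."""
    report = ValidationReport()
    vals = x.values
    if not np.isfinite(vals).all():
        rows, cols = np.nonzero(~np.isfinite(vals))
        where = ", ".join(
            f"({x.sample_ids[r]}, {x.feature_names[c]})" for r, c in list(zip(rows, cols))[:5]
        )
        report.add("missing_values", f"{len(rows)} non-finite entries, e.g. {where}")
    if len(set(x.sample_ids)) != x.n:
        report.add("duplicate_sample_ids", "sample IDs are not unique")
    if len(set(x.feature_names)) != x.p:
        report.add("duplicate_feature_names", "feature names are not unique")
    if x.n < 2 * cfg.n_folds:
        report.add(
            "too_few_samples",
            f"N={x.n} < 2*n_folds={2 * cfg.n_folds}; folds would lack OOB samples",
        )
    if len(y) != x.n:
        report.add("length_mismatch", f"response length {len(y)} != N={x.n}")
    elif y.sample_ids is not None and y.sample_ids != x.sample_ids:
        report.add("id_mismatch", "response sample IDs are not aligned with the matrix")
    if y.family == "linear":
        if len(y) and float(np.ptp(y.values)) == 0.0:
            report.add("constant_response", "linear response is constant")
    else:
        k = len(y.classes)
        if y.family == "binomial" and k != 2:
            report.add("class_count", f"binomial response must have 2 classes, found {k}")
        if y.family == "multinomial" and k < 2:
            report.add("class_count", f"multinomial response must have >=2 classes, found {k}")
        counts = pd.Series(y.values).value_counts()
        small = counts[counts < cfg.n_folds]
        if len(small):
            report.add(
                "small_class",
                f"classes smaller than n_folds={cfg.n_folds}: {dict(small)}",
            )
    if list(cfg.alphas) != sorted(cfg.alphas):
        report.add("alphas_order", "alphas must be sorted ascending")
    if any(a < 0 or a > 1 for a in cfg.alphas):
        report.add("alphas_range", "alphas must lie in [0, 1]")
    if cfg.n_lambda_ext is not None and cfg.n_lambda_ext <= cfg.n_lambda:
        report.add("lambda_ext", "n_lambda_ext must exceed n_lambda")
    return report
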