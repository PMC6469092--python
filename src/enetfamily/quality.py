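"""Quality functions (QF) comparing out-of-bag predictions to observations.

Every QF maps two aligned vectors to one real number, higher is better.  A QF
whose value is undefined on a given input (zero-variance correlation, empty
denominator in a confusion-matrix ratio, single-class AUC) returns NaN; the
cross-validation engine treats NaN as the worst possible value when choosing
the regularization strength, and model-vs-null comparisons drop undefined
entries with a logged count.

Per-family defaults: linear → correlation (Pearson unless overridden),
binomial → accuracy, multinomial → average accuracy.  Accuracy and average
accuracy are invariant under simultaneous permutations of the class labels;
precision, recall, F-score, specificity and AUC are not, but are offered as
alternatives (macro-averaged one-vs-rest variants for multinomial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

UNDEFINED = float("nan")

COR_METHODS = ("pearson", "spearman", "kendall")


def qf_correlation(pred, obs, method: str = "pearson") -> float:
    """Correlation between predictions and observations (NaN if degenerate)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs):
        raise ValueError("pred and obs must have equal length")
    if len(pred) < 2 or np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return UNDEFINED
    if method == "pearson":
        r = stats.pearsonr(pred, obs).statistic
    elif method == "spearman":
        r = stats.spearmanr(pred, obs).statistic
    elif method == "kendall":
        r = stats.kendalltau(pred, obs).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r)


def qf_accuracy(pred_labels, obs_labels) -> float:
    pred = np.asarray(pred_labels)
    obs = np.asarray(obs_labels)
    if len(pred) != len(obs):
        raise ValueError("pred and obs must have equal length")
    return float(np.mean(pred == obs))


def qf_average_accuracy(pred_labels, obs_labels, classes=None) -> float:
    """Macro-average over classes of the one-vs-rest binary accuracies.

    For each class c the 2x2 table of (label == c) yields a binary accuracy
    (tp + tn) / m; the QF is the mean over classes.  For K = 2 this equals
    plain accuracy.  Invariant under class-label permutations.
    """
    pred = np.asarray(pred_labels)
    obs = np.asarray(obs_labels)
    if len(pred) != len(obs):
        raise ValueError("pred and obs must have equal length")
    if classes is None:
        classes = sorted(set(obs) | set(pred))
    classes = list(classes)
    if not classes:
        raise ValueError("empty class set")
    accs = [float(np.mean((pred == c) == (obs == c))) for c in classes]
    return float(np.mean(accs))


def qf_binary_scores(pred_labels, obs_labels, positive_class) -> dict:
    """Precision, recall, F1 and specificity from the binary confusion matrix.

    Zero denominators yield the NaN sentinel (logged), e.g. precision with no
    predicted positives.
    """
    pred = np.asarray(pred_labels)
    obs = np.asarray(obs_labels)
    if len(pred) != len(obs):
        raise ValueError("pred and obs must have equal length")
    pp = pred == positive_class
    op = obs == positive_class
    tp = float(np.sum(pp & op))
    fp = float(np.sum(pp & ~op))
    fn = float(np.sum(~pp & op))
    tn = float(np.sum(~pp & ~op))
    precision = tp / (tp + fp) if tp + fp > 0 else UNDEFINED
    recall = tp / (tp + fn) if tp + fn > 0 else UNDEFINED
    specificity = tn / (tn + fp) if tn + fp > 0 else UNDEFINED
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        fscore = UNDEFINED
    else:
        fscore = 2 * precision * recall / (precision + recall)
    if np.isnan(precision):
        logger.debug("undefined precision: no predicted positives")
    return {
        "precision": precision,
        "recall": recall,
        "fscore": fscore,
        "specificity": specificity,
    }


def qf_auc(scores, obs_labels, positive_class) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    Probability that a random positive outscores a random negative, with ties
    counted one half (midranks).  NaN if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    obs = np.asarray(obs_labels)
    pos = obs == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return UNDEFINED
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _macro_binary(score_key):
    def fn(pred_labels, obs_labels, classes):
        vals = [qf_binary_scores(pred_labels, obs_labels, c)[score_key] for c in classes]
        vals = np.asarray(vals, dtype=float)
        if np.isnan(vals).all():
            return UNDEFINED
        return float(np.nanmean(vals))

    return fn


@dataclass(frozen=True)
class QualityFunction:
    """A named QF with its applicability and invariance metadata.

    ``scorer_factory(family, classes, cor_method)`` returns the callable the
    engine applies to raw OOB predictions: for the linear family a numeric
    prediction vector, for categorical families an (n, K) class-probability
    matrix, against the integer-encoded observed response.
    """

    name: str
    families: tuple
    label_permutation_invariant: bool
    scorer_factory: object


def predicted_labels(prob: np.ndarray, family: str) -> np.ndarray:
    """Class predictions from an (n, K) probability matrix.

    Binomial: positive class (index 1) iff its probability exceeds 0.5, ties
    going to the first class.  Multinomial: argmax, ties to the lowest index.
    """
    if family == "binomial":
        return (prob[:, 1] > 0.5).astype(int)
    return np.argmax(prob, axis=1)


def _make_scorer(name, family, classes, cor_method):
    k = None if classes is None else len(classes)
    if name == "correlation":
        return lambda pred, obs: qf_correlation(pred, obs, method=cor_method)
    if name == "accuracy":
        return lambda prob, obs: qf_accuracy(predicted_labels(prob, family), obs)
    if name == "average_accuracy":
        return lambda prob, obs: qf_average_accuracy(
            predicted_labels(prob, family), obs, classes=range(k)
        )
    if name in ("precision", "recall", "fscore", "specificity"):
        if family == "binomial":
            return lambda prob, obs: qf_binary_scores(
                predicted_labels(prob, family), obs, positive_class=1
            )[name]
        return lambda prob, obs: _macro_binary(name)(
            predicted_labels(prob, family), obs, range(k)
        )
    if name in ("precision_macro", "recall_macro", "fscore_macro", "specificity_macro"):
        base = name.removesuffix("_macro")
        return lambda prob, obs: _macro_binary(base)(
            predicted_labels(prob, family), obs, range(k)
        )
    if name == "auc":
        return lambda prob, obs: qf_auc(prob[:, 1], obs, positive_class=1)
    raise KeyError(name)


_CATEGORICAL = ("binomial", "multinomial")

QF_REGISTRY: dict[str, QualityFunction] = {}


def _register(name, families, invariant):
    QF_REGISTRY[name] = QualityFunction(
        name=name,
        families=tuple(families),
        label_permutation_invariant=invariant,
        scorer_factory=lambda family, classes, cor_method, _n=name: _make_scorer(
            _n, family, classes, cor_method
        ),
    )


_register("correlation", ("linear",), False)
_register("accuracy", _CATEGORICAL, True)
_register("average_accuracy", _CATEGORICAL, True)
for _m in ("precision", "recall", "fscore", "specificity"):
    _register(_m, _CATEGORICAL, False)
    _register(f"{_m}_macro", ("multinomial",), False)
_register("auc", ("binomial",), False)

DEFAULT_QF = {
    "linear": "correlation",
    "binomial": "accuracy",
    "multinomial": "average_accuracy",
}


def make_scorer(family: str, qf_name: str | None = None, cor_method: str = "pearson",
                classes=None):
    """Resolve a QF name (or user callable) to a scorer for raw OOB output.

    A user-defined QF may be passed as a callable taking (predictions,
    observations) and returning one real; it receives the raw prediction
    object (numeric vector for linear, (n, K) probability matrix otherwise).
    """
    if callable(qf_name):
        return qf_name
    name = qf_name or DEFAULT_QF[family]
    if name not in QF_REGISTRY:
        raise KeyError(f"unknown quality function {name!r}; available: {sorted(QF_REGISTRY)}")
    qf = QF_REGISTRY[name]
    if family not in qf.families:
        raise ValueError(f"quality function {name!r} does not apply to family {family!r}")
    if name == "correlation" and cor_method not in COR_METHODS:
        raise ValueError(f"cor_method must be one of {COR_METHODS}")
    return qf.scorer_factory(family, classes, cor_method)
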