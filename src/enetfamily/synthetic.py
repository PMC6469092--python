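"""Synthetic datasets with controlled feature/response covariance structure.

Designs are multivariate normal with one of three canonical covariance
structures — independent features, equicorrelated blocks (ρ within a block,
0 across), and autoregressive decay (corr(i, j) = ρ^|i−j|) — spanning the
regimes where ridge-like and lasso-like regularization respectively shine.
Responses are generated from sparse linear models: for the linear family
y = Xβ + ε with β carrying ``n_true_features`` entries of ±effect_size
(alternating signs on the leading features) and Gaussian noise; for
categorical families, class labels are drawn from a softmax over K linear
scores, each score driven by a disjoint block of true features, binomial
being the K = 2 case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data import FeatureMatrix, Response

COVARIANCES = ("independent", "block", "decaying")


@dataclass
class SyntheticSpec:
    """Generator settings.

    rho and block_size only apply to the block/decaying covariances; noise_sd
    only to the linear response; n_classes only to categorical responses.
    """

    n_samples: int = 100
    n_features: int = 50
    covariance: str = "independent"
    rho: float = 0.5
    block_size: int = 5
    n_true_features: int = 5
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.covariance not in COVARIANCES:
            raise ValueError(f"covariance must be one of {COVARIANCES}")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.n_true_features > self.n_features:
            raise ValueError("n_true_features exceeds n_features")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _covariance_matrix(spec: SyntheticSpec) -> np.ndarray:
    p = spec.n_features
    if spec.covariance == "independent":
        return np.eye(p)
    if spec.covariance == "block":
        cov = np.eye(p)
        for start in range(0, p, spec.block_size):
            stop = min(start + spec.block_size, p)
            cov[start:stop, start:stop] = spec.rho
            cov[range(start, stop), range(start, stop)] = 1.0
        return cov
    idx = np.arange(p)
    return spec.rho ** np.abs(idx[:, None] - idx[None, :])


def gen_design(spec: SyntheticSpec) -> FeatureMatrix:
    """Multivariate-normal design matrix, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    cov = _covariance_matrix(spec)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("covariance matrix is not positive definite") from exc
    z = rng.standard_normal((spec.n_samples, spec.n_features))
    values = z @ chol.T
    ids = [f"s{i + 1:04d}" for i in range(spec.n_samples)]
    names = [f"f{j + 1:03d}" for j in range(spec.n_features)]
    return FeatureMatrix(values, ids, names)


def linear_coefficients(spec: SyntheticSpec) -> np.ndarray:
    """True β: ±effect_size on the first n_true_features, alternating signs."""
    beta = np.zeros(spec.n_features)
    signs = np.where(np.arange(spec.n_true_features) % 2 == 0, 1.0, -1.0)
    beta[: spec.n_true_features] = signs * spec.effect_size
    return beta


def gen_linear_response(x: FeatureMatrix, spec: SyntheticSpec) -> Response:
    """y = Xβ + ε, ε ~ N(0, noise_sd²); noise stream independent of the design."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 10)))
    beta = linear_coefficients(spec)
    y = x.values @ beta + rng.normal(0.0, spec.noise_sd, size=x.n)
    return Response(y, "linear", sample_ids=x.sample_ids)


def categorical_score_matrix(spec: SyntheticSpec) -> np.ndarray:
    """Per-class score coefficients B (p × K); class k uses the k-th disjoint
    block of n_true_features leading features with weight effect_size."""
    k = spec.n_classes
    if k < 2:
        raise ValueError("n_classes must be at least 2")
    s = spec.n_true_features
    if k * s > spec.n_features:
        raise ValueError("need n_classes * n_true_features <= n_features for disjoint blocks")
    b = np.zeros((spec.n_features, k))
    for c in range(k):
        b[c * s : (c + 1) * s, c] = spec.effect_size
    return b


def gen_categorical_response(x: FeatureMatrix, spec: SyntheticSpec) -> Response:
    """Class labels sampled from softmax(XB); binomial is the K = 2 case."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 11)))
    b = categorical_score_matrix(spec)
    z = x.values @ b
    z = z - z.max(axis=1, keepdims=True)
    prob = np.exp(z)
    prob /= prob.sum(axis=1, keepdims=True)
    cum = np.cumsum(prob, axis=1)
    u = rng.random(x.n)
    labels_idx = (u[:, None] > cum).sum(axis=1)
    labels = [f"c{i + 1}" for i in labels_idx]
    family = "binomial" if spec.n_classes == 2 else "multinomial"
    return Response(labels, family, sample_ids=x.sample_ids)


def make_dataset(spec: SyntheticSpec, family: str = "linear"):
    """Design + response + true-feature indices in one call.

    Returns (FeatureMatrix, Response, true_features) where true_features is a
    sorted index list (linear) or a per-class dict of index lists
    (categorical).
    """
    x = gen_design(spec)
    if family == "linear":
        y = gen_linear_response(x, spec)
        truth = list(range(spec.n_true_features))
    else:
        if family == "binomial" and spec.n_classes != 2:
            raise ValueError("binomial requires n_classes=2")
        y = gen_categorical_response(x, spec)
        s = spec.n_true_features
        truth = {f"c{c + 1}": list(range(c * s, (c + 1) * s)) for c in range(spec.n_classes)}
    return x, y, truth


def write_dataset(spec: SyntheticSpec, family: str, out_dir) -> dict:
    """Write X.csv / y.csv plus a JSON sidecar with the spec and truth."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x, y, truth = make_dataset(spec, family)
    x.write_csv(out / "X.csv")
    import pandas as pd

    pd.DataFrame({"sample_id": x.sample_ids, "value": y.values}).to_csv(
        out / "y.csv", index=False, header=False
    )
    sidecar = {"family": family, "spec": spec.to_dict(), "true_features": truth}
    (out / "dataset.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
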