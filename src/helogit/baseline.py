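"""Plaintext reference trainer, evaluation metrics, CV and synthetic data.

The plaintext trainer runs the exact update the encrypted circuit implements,

    beta <- beta + (alpha/n) * sum_i act(-z_i^T beta) * z_i,   beta_0 = 0,

with the activation either the true sigmoid or a polynomial surrogate, so the
encrypted/unencrypted comparison isolates encryption effects from surrogate
effects.

The synthetic generator stands in for the clinical study tables this package
deliberately does not ship: n samples, d covariates on a bounded box, binary
outcome drawn from a logistic model, and covariates scaled so that every
inner product (1, x)^T beta stays inside [-8, 8] -- the interval on which the
sigmoid surrogates are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ring import ParameterError
from .sigmoid import sigmoid

__all__ = [
    "Dataset",
    "ModelParams",
    "EvalReport",
    "plaintext_gd",
    "predict_and_score",
    "auc_score",
    "param_mse_nmse",
    "kfold_split",
    "generate_synthetic",
    "default_beta",
]


class DataError(ValueError):
    pass


class MetricError(ValueError):
    pass


@dataclass
class Dataset:
    """n x d covariates and labels in {-1, +1}."""

    covariates: np.ndarray
    labels: np.ndarray
    feature_names: list = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        X = np.asarray(self.covariates, dtype=float)
        y = np.asarray(self.labels, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise DataError("covariates must be a non-empty n x d matrix")
        if not np.all(np.isfinite(X)):
            raise DataError("covariates contain missing/non-finite values")
        if y.shape[0] != X.shape[0]:
            raise DataError("label count does not match sample count")
        if set(np.unique(y)) <= {0.0, 1.0}:
            y = 2 * y - 1
        if not set(np.unique(y)) <= {-1.0, 1.0}:
            raise DataError("labels must be in {-1,+1} or {0,1}")
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "labels", y)
        if not self.feature_names:
            object.__setattr__(self, "feature_names",
                               [f"x{j}" for j in range(X.shape[1])])

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def d(self) -> int:
        return self.covariates.shape[1]

    def z_matrix(self) -> np.ndarray:
        """z_i = y_i * (1, x_i), shape (n, d+1)."""
        aug = np.column_stack([np.ones(self.n), self.covariates])
        return aug * self.labels[:, None]

    def subset(self, idx) -> "Dataset":
        return Dataset(self.covariates[idx], self.labels[idx],
                       self.feature_names, self.provenance)


@dataclass
class ModelParams:
    """Regression coefficients, intercept first (length d+1)."""

    beta: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.beta, dtype=float).ravel()
        if not np.all(np.isfinite(b)):
            raise DataError("model parameters must be finite")
        object.__setattr__(self, "beta", b)


@dataclass
class EvalReport:
    accuracy: float          # percent, [0, 100]
    auc: float               # [0, 1]
    mse: float = float("nan")
    nmse: float = float("nan")

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "auc": self.auc,
                "mse": self.mse, "nmse": self.nmse}


def plaintext_gd(ds: Dataset, activation="sigmoid", alpha: float = 1.0,
                 iter_num: int = 20, track_inputs: bool = False):
    """Full-batch gradient ascent on the log-likelihood from beta = 0.

    activation: "sigmoid" or a callable (e.g. an ApproxPoly surrogate).
    With track_inputs=True also returns the largest |z_i^T beta| seen across
    all iterations (to certify the surrogate's fit interval was respected).
    """
    if alpha <= 0:
        raise ParameterError("learning rate must be positive")
    act = sigmoid if activation == "sigmoid" else activation
    Z = ds.z_matrix()
    beta = np.zeros(ds.d + 1)
    max_ip = 0.0
    for _ in range(iter_num):
        ip = Z @ beta
        max_ip = max(max_ip, float(np.max(np.abs(ip))) if ip.size else 0.0)
        beta = beta + (alpha / ds.n) * (act(-ip) @ Z)
    params = ModelParams(beta)
    if track_inputs:
        ip = Z @ beta
        max_ip = max(max_ip, float(np.max(np.abs(ip))))
        return params, max_ip
    return params


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) statistic, ties half-credited."""
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    pos = s[y > 0]
    neg = s[y < 0]
    if pos.size == 0 or neg.size == 0:
        raise MetricError("AUC undefined: only one class present")
    # midranks of the combined sample
    allv = np.concatenate([pos, neg])
    order = np.argsort(allv, kind="mergesort")
    ranks = np.empty(allv.size)
    sorted_v = allv[order]
    i = 0
    while i < allv.size:
        j = i
        while j + 1 < allv.size and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def predict_and_score(ds: Dataset, params: ModelParams) -> EvalReport:
    """Accuracy (% at score threshold 0) and AUC of s_i = (1, x_i)^T beta."""
    beta = params.beta
    if beta.size != ds.d + 1:
        raise DataError(f"beta has length {beta.size}, expected {ds.d + 1}")
    scores = beta[0] + ds.covariates @ beta[1:]
    pred = np.where(scores >= 0, 1.0, -1.0)
    acc = 100.0 * float(np.mean(pred == ds.labels))
    return EvalReport(accuracy=acc, auc=auc_score(ds.labels, scores))


def param_mse_nmse(beta_enc: ModelParams, beta_plain: ModelParams) -> tuple:
    """MSE between coefficient vectors and its normalization by the
    mean square of the plaintext-trained vector."""
    a = beta_enc.beta
    b = beta_plain.beta
    if a.size != b.size:
        raise DataError("coefficient vectors differ in length")
    mse = float(np.mean((a - b) ** 2))
    denom = float(np.mean(b ** 2))
    if denom == 0.0:
        raise MetricError("NMSE undefined: plaintext parameters are all zero")
    return mse, mse / denom


def kfold_split(ds: Dataset, k: int, seed: int) -> list:
    """Random partition into k folds of nearly equal size; returns a list of
    (train_indices, test_indices) pairs covering every sample exactly once."""
    if k < 2:
        raise ParameterError("need k >= 2 folds")
    if k > ds.n:
        raise ParameterError(f"cannot split {ds.n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, test))
    return out


def default_beta(d: int) -> ModelParams:
    """A reference coefficient vector with |beta_0| + ||beta_1:||_1 = 4,
    leaving a factor-2 margin inside the surrogate interval [-8, 8] for the
    excursions of training iterates."""
    signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(d)])
    mags = np.linspace(1.5, 0.5, d)
    body = signs * mags
    body *= 3.0 / np.sum(np.abs(body))
    return ModelParams(np.concatenate([[-1.0], body]))


def generate_synthetic(n: int, d: int, beta_true: ModelParams | None = None,
                       seed: int = 0) -> Dataset:
    """Clinical-style synthetic data from a logistic model.

    Covariates are uniform on [-1, 1]^d, rescaled if necessary so that
    |(1, x)^T beta_true| <= 4 for every sample (the trained iterates then stay
    well inside the surrogate interval [-8, 8]); labels are +1 with
    probability sigma((1, x)^T beta_true).
    """
    if n < 1 or d < 1:
        raise ParameterError("need n >= 1 and d >= 1")
    if beta_true is None:
        beta_true = default_beta(d)
    b = beta_true.beta
    if b.size != d + 1:
        raise ParameterError("beta_true has wrong length")
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.0, 1.0, size=(n, d))
    budget = np.abs(b[0]) + np.sum(np.abs(b[1:]))
    if budget > 4.0:
        X *= (4.0 - np.abs(b[0])) / max(np.sum(np.abs(b[1:])), 1e-12)
    lin = b[0] + X @ b[1:]
    y = np.where(rng.uniform(size=n) < sigmoid(lin), 1.0, -1.0)
    return Dataset(X, y, provenance=f"synthetic(seed={seed}, n={n}, d={d})")
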