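"""Linear models of transcriptional activity from promoter features.

Per species, standardized Z-scored log10 activity (tx_z) is regressed
on the eight promoter features by ordinary least squares.  Model
quality is assessed by repeated random-subsampling cross-validation
(default: 10% train / 90% test, 10 repeats) and by the fraction of
predictions within one log10 unit of the measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LinearModel:
    """OLS fit on standardized features.

    ``coefficients`` are on the standardized-feature scale; ``predict``
    applies the stored standardization, so it accepts raw features.
    """

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    train_fraction: float = 1.0
    r_train: float = float("nan")
    r_test: float = float("nan")
    frac_within_1log: float = float("nan")
    coef_se: Optional[np.ndarray] = None

    def predict(self, X) -> np.ndarray:
        Xa = np.asarray(X, dtype=float)
        Z = (Xa - self.feature_means) / self.feature_sds
        return Z @ self.coefficients + self.intercept

    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "train_fraction": self.train_fraction,
            "r_train": self.r_train,
            "r_test": self.r_test,
            "frac_within_1log": self.frac_within_1log,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=d["feature_names"],
            coefficients=np.array(d["coefficients"]),
            intercept=d["intercept"],
            feature_means=np.array(d["feature_means"]),
            feature_sds=np.array(d["feature_sds"]),
            train_fraction=d.get("train_fraction", 1.0),
            r_train=d.get("r_train", float("nan")),
            r_test=d.get("r_test", float("nan")),
            frac_within_1log=d.get("frac_within_1log", float("nan")),
        )


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y row counts differ")
    if np.isnan(Xa).any() or np.isnan(ya).any():
        raise ValueError("missing values in X or y")
    return Xa, ya, names


def fit_ols(X, y, min_rows: int = 10) -> LinearModel:
    """Ordinary least squares of y on standardized features.

    Solves the normal equations (via lstsq for numerical stability);
    rank-deficient designs fall back to a tiny ridge (lambda = 1e-8)
    with a warning.  Constant features get SD 1 so standardization is
    a no-op for them.
    """
    Xa, ya, names = _as_xy(X, y)
    n, p = Xa.shape
    if n < min_rows:
        raise ValueError(f"need >= {min_rows} rows, got {n}")
    mu = Xa.mean(axis=0)
    sd = Xa.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xa - mu) / sd
    A = np.column_stack([np.ones(n), Z])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        import warnings

        warnings.warn("rank-deficient design; using ridge fallback (lambda=1e-8)")
        lam = 1e-8
        G = A.T @ A + lam * np.eye(p + 1)
        beta = np.linalg.solve(G, A.T @ ya)
    else:
        beta, *_ = np.linalg.lstsq(A, ya, rcond=None)
    pred = A @ beta
    resid = ya - pred
    if n > p + 1 and rank == p + 1:
        sigma2 = float(resid @ resid) / (n - p - 1)
        cov = sigma2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))[1:]
    else:
        se = None
    r = _pearson_or_nan(pred, ya)
    return LinearModel(
        feature_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        feature_means=mu,
        feature_sds=sd,
        r_train=r,
        coef_se=se,
    )


def _pearson_or_nan(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def cross_validate(
    X,
    y,
    train_frac: float = 0.10,
    repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Repeated random-subsampling cross-validation.

    Each repeat draws a random ``train_frac`` split, fits OLS on the
    training rows, and records the Pearson r between predictions and
    observations on the held-out rows.  Returns all ``repeats`` r
    values (reproducible under ``seed``).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    Xa, ya, _ = _as_xy(X, y)
    n = Xa.shape[0]
    n_train = max(int(round(train_frac * n)), 10)
    if n_train >= n:
        raise ValueError("train set would consume all rows")
    rng = np.random.default_rng(seed)
    rs = np.empty(repeats)
    for rep in range(repeats):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_ols(Xa[tr], ya[tr])
        rs[rep] = _pearson_or_nan(model.predict(Xa[te]), ya[te])
    return rs


def frac_within_one_log(
    pred: Sequence[float],
    obs: Sequence[float],
    log_sd: float = 1.0,
    log_mean: float = 0.0,
    tol_logs: float = 1.0,
) -> float:
    """Fraction of predictions within ``tol_logs`` log10 units of obs.

    Inputs on the tx_z scale are converted back to log10 via the
    training-set mean/SD (``log_mean``, ``log_sd``); pass ``log_sd=1,
    log_mean=0`` when the vectors are already log10 activities.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError("prediction/observation length mismatch")
    p_log = p * log_sd + log_mean
    o_log = o * log_sd + log_mean
    return float(np.mean(np.abs(p_log - o_log) <= tol_logs))
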