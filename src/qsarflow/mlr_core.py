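"""Ordinary least-squares activity model: fitting, prediction, effect sizes.

The activity model is a multiple linear regression with intercept,

    pIC50 = b0 + b1 * x1 + ... + bk * xk,

fitted by OLS through a numerically stable orthogonal decomposition
(statsmodels' pinv/QR path), never the normal equations.  Reported fit
statistics follow common QSAR practice: R^2 = 1 - RSS/TSS about the
training mean, RMSE with denominator n, and a residual standard deviation
with denominator n - k - 1 kept separately for studentization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateResponseError,
    SingularDesignError,
    SizeError,
)

__all__ = ["MLRModel", "fit_mlr", "predict", "predict_many", "standardized_coefficients"]


@dataclass
class MLRModel:
    """Fitted (or externally specified) linear activity model.

    ``coefficients`` is an ordered descriptor-name -> slope mapping; fit
    statistics may be None on models built from published coefficients
    rather than data.
    """

    intercept: float
    coefficients: dict[str, float]
    n_train: int | None = None
    r2: float | None = None
    rmse: float | None = None
    residual_sd: float | None = None
    f_stat: float | None = None
    f_pvalue: float | None = None
    standardized_coefficients: dict[str, float] | None = None

    @property
    def k(self) -> int:
        return len(self.coefficients)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)


def _as_matrix(X, names: list[str] | None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise SizeError("X must be a 2-D matrix")
    if names is None:
        names = [f"x{j + 1}" for j in range(arr.shape[1])]
    return arr, list(names)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise SingularDesignError naming columns that add no rank."""
    design = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(design) == design.shape[1]:
        return
    offending = []
    cols = [np.ones(X.shape[0])]
    for j, name in enumerate(names):
        trial = np.column_stack(cols + [X[:, j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            cols.append(X[:, j])
        else:
            offending.append(name)
    raise SingularDesignError(
        f"descriptor matrix is rank-deficient; offending columns: {offending}",
        columns=offending,
    )


def fit_mlr(X, y, names: list[str] | None = None) -> MLRModel:
    """Fit the OLS activity model with intercept.

    Parameters
    ----------
    X
        Training descriptor matrix: DataFrame (column names used) or
        array-like with ``names``.
    y
        Training activities.
    """
    Xm, names = _as_matrix(X, names)
    yv = np.asarray(y, dtype=float).ravel()
    n, k = Xm.shape
    if yv.shape[0] != n:
        raise SizeError(f"X has {n} rows but y has {yv.shape[0]}")
    if n < k + 2:
        raise SizeError(f"need n >= k + 2 training records (n={n}, k={k})")
    _check_rank(Xm, names)

    if np.ptp(yv) == 0.0:
        warnings.warn(
            "constant training response; returning zero slopes with R^2 = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        model = MLRModel(
            intercept=float(yv[0]),
            coefficients={name: 0.0 for name in names},
            n_train=n,
            r2=0.0,
            rmse=0.0,
            residual_sd=0.0,
            f_stat=0.0,
            f_pvalue=1.0,
        )
        model.standardized_coefficients = {name: 0.0 for name in names}
        return model

    res = sm.OLS(yv, sm.add_constant(Xm, has_constant="add")).fit()
    rss = float(res.ssr)
    model = MLRModel(
        intercept=float(res.params[0]),
        coefficients={name: float(b) for name, b in zip(names, res.params[1:])},
        n_train=n,
        r2=float(res.rsquared),
        rmse=float(np.sqrt(rss / n)),
        residual_sd=float(np.sqrt(rss / (n - k - 1))),
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
    )
    model.standardized_coefficients = standardized_coefficients(model, Xm, yv, names)[0]
    return model


def predict(model: MLRModel, descriptors: Mapping[str, float]) -> float:
    """Model prediction for one compound's descriptor mapping.

    Extra keys are ignored; a missing model descriptor raises KeyError
    naming it.  The result does not depend on key order.
    """
    total = model.intercept
    for name, beta in model.coefficients.items():
        if name not in descriptors:
            raise KeyError(f"descriptor {name!r} missing from input")
        total += beta * float(descriptors[name])
    return float(total)


def predict_many(model: MLRModel, X) -> np.ndarray:
    """Vectorized prediction over a DataFrame or record iterable."""
    if isinstance(X, pd.DataFrame):
        missing = [n for n in model.coefficients if n not in X.columns]
        if missing:
            raise KeyError(f"descriptors {missing} missing from input")
        arr = X[model.descriptor_names].to_numpy(dtype=float)
        beta = np.array([model.coefficients[n] for n in model.descriptor_names])
        return model.intercept + arr @ beta
    return np.array([predict(model, row) for row in X])


def standardized_coefficients(
    model: MLRModel, X, y, names: list[str] | None = None
) -> tuple[dict[str, float], list[str]]:
    """Standardized slopes b_j * sd(x_j) / sd(y) and their |.| ranking.

    Standard deviations are population (1/n) ones; for a one-descriptor
    model the standardized slope equals the Pearson correlation r(x, y).

    Returns the name -> standardized-slope mapping (model column order)
    and the descriptor names sorted by decreasing absolute standardized
    slope.
    """
    Xm, names = _as_matrix(X, names)
    yv = np.asarray(y, dtype=float).ravel()
    sd_y = float(np.std(yv))
    if sd_y == 0.0:
        raise DegenerateResponseError("zero-variance response: cannot standardize")
    out = {}
    for j, name in enumerate(names):
        if name not in model.coefficients:
            raise KeyError(f"column {name!r} is not a model descriptor")
        out[name] = model.coefficients[name] * float(np.std(Xm[:, j])) / sd_y
    ordered = {n: out[n] for n in model.coefficients if n in out}
    ranking = sorted(ordered, key=lambda n: abs(ordered[n]), reverse=True)
    return ordered, ranking
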