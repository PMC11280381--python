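"""Leverage-based applicability domain (Williams plot).

The leverage of a compound with descriptor vector x_i against the training
design X is h_i = x_i^T (X^T X)^{-1} x_i, computed here on the
intercept-augmented design so that the training leverages sum to K + 1
(the hat-matrix trace) and the centroid of the training set sits at the
minimum h = 1/n.  The warning threshold is h* = 3 (K + 1) / n; compounds
beyond it are structurally outside the training space, while standardized
residuals beyond +-3 mark response outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import SingularDesignError
from .mlr_core import MLRModel, predict_many

__all__ = [
    "ADReport",
    "leverages",
    "leverage_threshold",
    "standardized_residuals",
    "classify_domain",
    "williams_table",
]


def leverage_threshold(k: int, n: int) -> float:
    """Critical leverage h* = 3 (k + 1) / n.

    k is the number of model descriptors and n the training-set size.
    Values >= 1 are returned as-is with a warning: every training compound
    has h <= 1, so such a threshold excludes nothing.
    """
    if k < 1 or n < 1:
        raise ValueError(f"k and n must be positive integers, got k={k}, n={n}")
    h_star = 3.0 * (k + 1) / n
    if h_star >= 1.0:
        warnings.warn(
            f"h* = {h_star:.3f} >= 1 is vacuous for training compounds",
            RuntimeWarning,
            stacklevel=2,
        )
    return h_star


def _design(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        ids = list(X.index)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        ids = list(range(arr.shape[0]))
    return np.column_stack([np.ones(arr.shape[0]), arr]), ids


def leverages(X_train, X_query=None) -> dict:
    """Hat values h_i of query rows against the training design.

    Uses the R factor of the thin QR decomposition: h_i = ||R^-T d_i||^2
    where d_i is the intercept-augmented query row.  With ``X_query=None``
    the training rows themselves are the queries.
    """
    D_train, _ = _design(X_train)
    if np.linalg.matrix_rank(D_train) < D_train.shape[1]:
        raise SingularDesignError(
            "training design (with intercept) is rank-deficient"
        )
    _, R = np.linalg.qr(D_train)
    D_query, ids = _design(X_train if X_query is None else X_query)
    # solve R^T Z^T = D_query^T  ->  rows of Z are R^-T d_i
    Z = scipy.linalg.solve_triangular(R.T, D_query.T, lower=True).T
    h = np.einsum("ij,ij->i", Z, Z)
    return {cid: float(v) for cid, v in zip(ids, h)}


def standardized_residuals(
    model: MLRModel, X, y, studentized: bool = False
) -> dict:
    """Residuals on the training-fit scale: e_i / residual_sd.

    With ``studentized=True`` each residual is additionally divided by
    sqrt(1 - h_i) (internal studentization).  Test-set compounds use the
    same training residual_sd, so train and test live on one scale.
    """
    if not model.residual_sd or model.residual_sd <= 0:
        raise ValueError("model.residual_sd must be positive to standardize")
    if isinstance(X, pd.DataFrame):
        ids = list(X.index)
        pred = predict_many(model, X)
    else:
        arr = np.asarray(X, dtype=float)
        ids = list(range(arr.shape[0]))
        pred = predict_many(model, pd.DataFrame(arr, columns=model.descriptor_names))
    resid = np.asarray(y, dtype=float).ravel() - pred
    scale = np.full(resid.shape, model.residual_sd)
    if studentized:
        hmap = leverages(X)
        h = np.array([hmap[cid] for cid in ids])
        scale = scale * np.sqrt(1.0 - h)
    return {cid: float(r / s) for cid, r, s in zip(ids, resid, scale)}


CATEGORIES = ("inside", "structural_outlier", "response_outlier", "both")


@dataclass
class ADReport:
    """Williams-plot data: leverages, cutoffs and per-compound category."""

    leverages: dict
    h_star: float
    sdr: dict  # id -> standardized residual; absent for candidates
    residual_limit: float
    category: dict


def classify_domain(
    leverage_map: Mapping,
    sdr: Mapping | None,
    h_star: float,
    residual_limit: float = 3.0,
) -> ADReport:
    """Classify each compound by the two Williams-plot cutoffs.

    Compounds without a residual (candidates: no observed activity) are
    classified on leverage alone — inside or structural_outlier.
    """
    sdr = dict(sdr or {})
    category = {}
    for cid, h in leverage_map.items():
        high_h = h > h_star
        if cid in sdr:
            high_r = abs(sdr[cid]) > residual_limit
        else:
            high_r = False
        if high_h and high_r:
            category[cid] = "both"
        elif high_h:
            category[cid] = "structural_outlier"
        elif high_r:
            category[cid] = "response_outlier"
        else:
            category[cid] = "inside"
    return ADReport(
        leverages=dict(leverage_map),
        h_star=float(h_star),
        sdr=sdr,
        residual_limit=float(residual_limit),
        category=category,
    )


def williams_table(report: ADReport, roles: Mapping | None = None) -> pd.DataFrame:
    """Flat table for plotting: id, role, leverage, sdr, category."""
    roles = dict(roles or {})
    rows = []
    for cid, h in report.leverages.items():
        rows.append(
            {
                "id": cid,
                "role": roles.get(cid, ""),
                "leverage": h,
                "sdr": report.sdr.get(cid, np.nan),
                "category": report.category[cid],
            }
        )
    return pd.DataFrame(rows, columns=["id", "role", "leverage", "sdr", "category"])
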