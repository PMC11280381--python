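"""Model validation: LOO Q^2, external R^2, VIF, y-randomization, gating.

Internal predictivity is the leave-one-out cross-validated coefficient

    Q^2 = 1 - PRESS / TSS,

with TSS about the full-training mean.  PRESS is evaluated both by n
explicit refits and by the hat-matrix shortcut e_i / (1 - h_ii); the two
routes must agree to 1e-10 and the shortcut value is the one returned.

Chance correlation is probed by y-scrambling: the activity vector is
permuted (descriptors untouched), the model refitted, and the scrambled
fits summarized by the correction statistic

    cRp^2 = R * sqrt(R^2 - mean r^2_rand),    R = +sqrt(R^2),

which must exceed 0.5 for a model whose correlation is not accidental.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FoldError,
    SizeError,
    UndefinedCorrelationError,
)
from .mlr_core import MLRModel, _as_matrix, _check_rank, fit_mlr, predict_many

__all__ = [
    "ValidationReport",
    "RandomizationReport",
    "ExternalValidation",
    "GateThresholds",
    "loo_q2",
    "external_r2",
    "vif",
    "y_randomization",
    "crp2",
    "gt_gate",
    "validate_model",
]


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


def _hat_diagonal(design: np.ndarray) -> np.ndarray:
    """Diagonal of H = D (D^T D)^-1 D^T via the thin-QR factor."""
    q, _ = np.linalg.qr(design)
    return np.einsum("ij,ij->i", q, q)


def loo_q2(X, y, names: list[str] | None = None, check_tol: float = 1e-10) -> float:
    """Leave-one-out Q^2 = 1 - PRESS/TSS about the full-training mean.

    PRESS is computed by the hat-matrix shortcut and verified against the
    explicit refit-per-record loop; disagreement beyond ``check_tol``
    raises, so the fast path can never silently diverge from the
    definition.
    """
    Xm, names = _as_matrix(X, names)
    yv = np.asarray(y, dtype=float).ravel()
    n, k = Xm.shape
    if n < k + 3:
        raise SizeError(f"LOO needs n >= k + 3 (n={n}, k={k})")
    _check_rank(Xm, names)

    design = np.column_stack([np.ones(n), Xm])
    coef, _, _, _ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ coef
    h = _hat_diagonal(design)
    if np.any(h >= 1 - 1e-12):
        bad = int(np.argmax(h))
        raise FoldError(f"leaving out record {bad} makes the fold singular (h = {h[bad]:.6f})")
    press_shortcut = float(np.sum((resid / (1.0 - h)) ** 2))

    press_explicit = 0.0
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        ci, _, rank, _ = np.linalg.lstsq(design[mask], yv[mask], rcond=None)
        if rank < design.shape[1]:
            raise FoldError(f"fold with record {i} left out is rank-deficient")
        press_explicit += float((yv[i] - design[i] @ ci) ** 2)

    if abs(press_shortcut - press_explicit) > check_tol * max(1.0, press_explicit):
        raise FoldError(
            "hat-matrix PRESS disagrees with explicit refits: "
            f"{press_shortcut!r} vs {press_explicit!r}"
        )

    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0.0:
        raise UndefinedCorrelationError("constant response: Q^2 undefined")
    return 1.0 - press_shortcut / tss


# ---------------------------------------------------------------------------
# external validation


@dataclass
class ExternalValidation:
    """Held-out test-set performance."""

    r2_test: float  # squared Pearson between observed and predicted
    rmse_test: float
    r2_pred: float  # predictive variant 1 - SS_err / SS about the train mean
    n_ext: int


def external_r2(model: MLRModel, X_test, y_test, y_train_mean: float | None = None) -> ExternalValidation:
    """Test-set R^2 (squared Pearson, primary) plus the predictive variant.

    The predictive variant normalizes squared errors by deviations of the
    test observations from the *training* mean; when ``y_train_mean`` is
    not given the test mean is used.
    """
    yv = np.asarray(y_test, dtype=float).ravel()
    if yv.size == 0:
        raise SizeError("external validation needs a non-empty test set")
    if isinstance(X_test, pd.DataFrame):
        pred = predict_many(model, X_test)
    else:
        pred = predict_many(model, pd.DataFrame(np.asarray(X_test, dtype=float),
                                                columns=model.descriptor_names))
    if np.ptp(pred) == 0.0 or np.ptp(yv) == 0.0:
        raise UndefinedCorrelationError(
            "constant predictions or observations: correlation undefined"
        )
    r = float(np.corrcoef(yv, pred)[0, 1])
    rmse = float(np.sqrt(np.mean((yv - pred) ** 2)))
    ref_mean = float(y_train_mean) if y_train_mean is not None else float(yv.mean())
    denom = float(np.sum((yv - ref_mean) ** 2))
    r2_pred = 1.0 - float(np.sum((yv - pred) ** 2)) / denom if denom > 0 else float("nan")
    return ExternalValidation(r2_test=r * r, rmse_test=rmse, r2_pred=r2_pred, n_ext=yv.size)


# ---------------------------------------------------------------------------
# variance inflation factors


def vif(X, names: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factor per descriptor, VIF_j = 1/(1 - R^2_j).

    R^2_j comes from regressing column j (with intercept) on all other
    columns.  A single-descriptor design returns 1.0 by definition;
    exactly collinear columns get ``inf`` rather than an error.
    """
    Xm, names = _as_matrix(X, names)
    n, k = Xm.shape
    if k == 1:
        return {names[0]: 1.0}
    out: dict[str, float] = {}
    for j in range(k):
        target = Xm[:, j]
        others = np.column_stack(
            [np.ones(n)] + [Xm[:, m] for m in range(k) if m != j]
        )
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = float(np.sum((target - target.mean()) ** 2))
        if tss == 0.0:
            out[names[j]] = float("inf")  # constant column: perfectly "explained"
            continue
        r2_j = 1.0 - float(resid @ resid) / tss
        out[names[j]] = float("inf") if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return out


# ---------------------------------------------------------------------------
# y-randomization


@dataclass
class RandomizationReport:
    """Summary of the y-scrambling trial."""

    n_perm: int
    mean_r2_rand: float
    mean_q2_rand: float
    crp2: float
    seed: int | None
    per_perm_r2: list[float] = field(default_factory=list)
    per_perm_q2: list[float] = field(default_factory=list)


def crp2(r2: float, mean_r2_rand: float) -> float:
    """Randomization correction cRp^2 = R * sqrt(R^2 - mean r^2_rand).

    R is the positive root of the baseline R^2.  If the scrambled models
    fit as well as the real one (mean r^2_rand >= R^2) the correction is
    0 with a warning — the model is indistinguishable from chance.
    """
    if not (0 <= r2 <= 1):
        raise ConfigurationError(f"baseline R^2 must lie in [0, 1], got {r2}")
    if mean_r2_rand >= r2:
        warnings.warn(
            f"mean scrambled r^2 ({mean_r2_rand:.3f}) >= baseline R^2 ({r2:.3f}); "
            "cRp^2 set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.sqrt(r2) * np.sqrt(r2 - mean_r2_rand))


def y_randomization(
    X,
    y,
    n_perm: int = 100,
    seed: int | None = None,
    names: list[str] | None = None,
    baseline_r2: float | None = None,
    permutations=None,
) -> RandomizationReport:
    """Refit the model on permuted activities and summarize the fits.

    For each of ``n_perm`` uniformly drawn permutations of y (the identity
    permutation is rejected and redrawn) the model is refitted on the
    untouched descriptor matrix; the fit R^2 and LOO Q^2 of every
    scrambled model are recorded.  ``permutations`` lets callers supply
    explicit permutations (testing hook); it overrides ``n_perm``/``seed``.
    """
    Xm, names = _as_matrix(X, names)
    yv = np.asarray(y, dtype=float).ravel()
    n = yv.size
    if permutations is None:
        if n_perm < 1:
            raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
        rng = np.random.default_rng(seed)
        identity = np.arange(n)
        permutations = []
        while len(permutations) < n_perm:
            perm = rng.permutation(n)
            if np.array_equal(perm, identity):
                continue
            permutations.append(perm)
    else:
        permutations = [np.asarray(p, dtype=int) for p in permutations]
        n_perm = len(permutations)

    if baseline_r2 is None:
        baseline_r2 = fit_mlr(Xm, yv, names).r2

    r2s, q2s = [], []
    for perm in permutations:
        y_perm = yv[perm]
        r2s.append(fit_mlr(Xm, y_perm, names).r2)
        q2s.append(loo_q2(Xm, y_perm, names))

    mean_r2 = float(np.mean(r2s))
    mean_q2 = float(np.mean(q2s))
    return RandomizationReport(
        n_perm=n_perm,
        mean_r2_rand=mean_r2,
        mean_q2_rand=mean_q2,
        crp2=crp2(baseline_r2, mean_r2),
        seed=seed,
        per_perm_r2=[float(v) for v in r2s],
        per_perm_q2=[float(v) for v in q2s],
    )


# ---------------------------------------------------------------------------
# acceptance gate


@dataclass
class GateThresholds:
    """Minimum requirements for a generally accepted QSAR model."""

    r2_min: float = 0.6
    n_ext_min: int = 5
    r2_minus_q2_max: float = 0.3
    q2_min: float = 0.5
    p_max: float = 0.05


def gt_gate(
    r2: float,
    q2_cv: float,
    n_ext: int,
    f_pvalue: float,
    thresholds: GateThresholds | None = None,
) -> dict[str, bool]:
    """Pass/fail verdict per acceptance criterion plus the conjunction."""
    t = thresholds or GateThresholds()
    verdicts = {
        "r2": r2 >= t.r2_min,
        "n_ext": n_ext >= t.n_ext_min,
        "r2_minus_q2": (r2 - q2_cv) <= t.r2_minus_q2_max,
        "q2_cv": q2_cv > t.q2_min,
        "f_pvalue": f_pvalue < t.p_max,
    }
    verdicts["overall"] = all(verdicts.values())
    return verdicts


# ---------------------------------------------------------------------------
# one-call validation report


@dataclass
class ValidationReport:
    q2_cv: float
    r2_test: float
    rmse_test: float
    r2_pred: float
    n_ext: int
    r2_minus_q2: float
    f_pvalue: float
    gate: dict[str, bool]
    vif: dict[str, float]
    randomization: RandomizationReport | None = None
    thresholds: GateThresholds = field(default_factory=GateThresholds)


def validate_model(
    model: MLRModel,
    X_train,
    y_train,
    X_test,
    y_test,
    n_perm: int = 100,
    seed: int | None = None,
    thresholds: GateThresholds | None = None,
) -> ValidationReport:
    """Full internal/external/randomization/collinearity validation."""
    thresholds = thresholds or GateThresholds()
    q2 = loo_q2(X_train, y_train, names=model.descriptor_names)
    y_train_arr = np.asarray(y_train, dtype=float).ravel()
    ext = external_r2(model, X_test, y_test, y_train_mean=float(y_train_arr.mean()))
    rand = y_randomization(
        X_train, y_train, n_perm=n_perm, seed=seed,
        names=model.descriptor_names, baseline_r2=model.r2,
    )
    vifs = vif(X_train, names=model.descriptor_names)
    gate = gt_gate(model.r2, q2, ext.n_ext, model.f_pvalue, thresholds)
    return ValidationReport(
        q2_cv=q2,
        r2_test=ext.r2_test,
        rmse_test=ext.rmse_test,
        r2_pred=ext.r2_pred,
        n_ext=ext.n_ext,
        r2_minus_q2=model.r2 - q2,
        f_pvalue=model.f_pvalue,
        gate=gate,
        vif=vifs,
        randomization=rand,
        thresholds=thresholds,
    )
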