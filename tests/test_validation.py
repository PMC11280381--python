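"""Internal, external, randomization and collinearity validation."""

import numpy as np
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

from qsarflow import (
    crp2,
    external_r2,
    fit_mlr,
    gt_gate,
    loo_q2,
    validate_model,
    vif,
    y_randomization,
)
from qsarflow.errors import SizeError, UndefinedCorrelationError
from qsarflow.validation import GateThresholds


def _loo_oracle(X, y):
    """Explicit leave-one-out loop with plain lstsq refits."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        c, *_ = np.linalg.lstsq(D[mask], y[mask], rcond=None)
        press += (y[i] - D[i] @ c) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)


def test_loo_q2_is_one_for_noiseless_data(rng):
    X = rng.normal(size=(12, 2))
    y = 1.0 + X @ [2.0, -1.0]
    assert loo_q2(X, y) == pytest.approx(1.0, abs=1e-10)


def test_loo_q2_matches_explicit_refits_on_toy_set(rng):
    X = rng.normal(size=(12, 3))
    y = X @ [1.0, 0.5, -0.25] + rng.normal(size=12)
    assert loo_q2(X, y) == pytest.approx(_loo_oracle(X, y), abs=1e-10)


def test_loo_q2_below_r2(rng):
    """PRESS >= RSS for OLS with intercept, so Q^2 <= R^2."""
    for seed in range(20):
        r = np.random.default_rng(seed)
        X = r.normal(size=(15, 3))
        y = X @ [1.0, -1.0, 0.5] + r.normal(size=15)
        assert loo_q2(X, y) <= fit_mlr(X, y).r2 + 1e-12


def test_loo_q2_null_response_is_negative_on_average():
    """y independent of X: mean LOO Q^2 over replicates is <= 0."""
    rng = np.random.default_rng(99)
    q2s = [
        loo_q2(rng.normal(size=(40, 3)), rng.normal(size=40)) for _ in range(200)
    ]
    assert np.mean(q2s) <= 0.0


def test_loo_q2_needs_enough_records(rng):
    with pytest.raises(SizeError):
        loo_q2(rng.normal(size=(5, 3)), rng.normal(size=5))


def test_external_r2_perfect_predictions(rng):
    from qsarflow import MLRModel

    model = MLRModel(0.0, {"x1": 1.0})
    y = rng.normal(size=8)
    ext = external_r2(model, y[:, None], y)
    assert ext.r2_test == pytest.approx(1.0, abs=1e-12)
    assert ext.rmse_test == pytest.approx(0.0, abs=1e-12)


def test_external_r2_matches_hand_computed_pearson():
    from qsarflow import MLRModel

    model = MLRModel(0.0, {"x": 1.0})  # predicts x itself
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([1.1, 1.9, 3.3, 3.8, 5.2])
    ext = external_r2(model, x[:, None], y)
    r = np.corrcoef(x, y)[0, 1]
    assert ext.r2_test == pytest.approx(r * r, abs=1e-12)
    assert ext.n_ext == 5


def test_external_r2_constant_predictions_error(rng):
    from qsarflow import MLRModel

    model = MLRModel(5.0, {"x": 0.0})
    with pytest.raises(UndefinedCorrelationError):
        external_r2(model, rng.normal(size=(5, 1)), rng.normal(size=5))


def test_vif_orthogonal_columns_are_one():
    n = 8
    X = np.zeros((n, 2))
    X[:4, 0] = [1, -1, 1, -1]
    X[4:, 1] = [1, -1, 1, -1]
    out = vif(X, names=["a", "b"])
    assert out["a"] == pytest.approx(1.0, abs=1e-10)
    assert out["b"] == pytest.approx(1.0, abs=1e-10)


def test_vif_single_descriptor_is_definitional(rng):
    assert vif(rng.normal(size=(10, 1)), names=["x"]) == {"x": 1.0}


def test_vif_near_duplicate_blows_up_and_matches_statsmodels(rng):
    x1 = rng.normal(size=50)
    X = np.column_stack([x1, x1 + 1e-3 * rng.normal(size=50), rng.normal(size=50)])
    out = vif(X, names=["a", "b", "c"])
    assert out["a"] > 10 and out["b"] > 10
    D = np.column_stack([np.ones(50), X])
    for j, name in enumerate(["a", "b", "c"]):
        oracle = variance_inflation_factor(D, j + 1)
        assert out[name] == pytest.approx(oracle, rel=1e-6)


def test_vif_exact_collinearity_is_infinite(rng):
    x = rng.normal(size=20)
    out = vif(np.column_stack([x, 2.0 * x]), names=["a", "b"])
    assert np.isinf(out["a"]) and np.isinf(out["b"])


def test_vif_invariant_under_column_rescaling(rng):
    X = rng.normal(size=(30, 3)) @ np.array([[1, 0.5, 0], [0, 1, 0.3], [0, 0, 1]])
    base = vif(X, names=["a", "b", "c"])
    X2 = X.copy()
    X2[:, 0] *= 1000.0
    scaled = vif(X2, names=["a", "b", "c"])
    for name in base:
        assert scaled[name] == pytest.approx(base[name], rel=1e-9)


# ---------------------------------------------------------------------------
# y-randomization


def test_identity_permutation_reproduces_baseline(rng):
    X = rng.normal(size=(20, 3))
    y = X @ [1.0, 0.5, -0.5] + rng.normal(size=20)
    baseline = fit_mlr(X, y)
    with pytest.warns(RuntimeWarning):  # identity scramble fits as well as baseline
        report = y_randomization(X, y, permutations=[np.arange(20)])
    assert report.per_perm_r2[0] == pytest.approx(baseline.r2, abs=1e-12)


def test_y_randomization_seeded_reproducibility(rng):
    X = rng.normal(size=(25, 3))
    y = X @ [1.0, -0.5, 0.2] + rng.normal(size=25)
    a = y_randomization(X, y, n_perm=20, seed=5)
    b = y_randomization(X, y, n_perm=20, seed=5)
    assert a.per_perm_r2 == b.per_perm_r2
    assert a.crp2 == b.crp2
    assert np.mean(a.per_perm_r2) == pytest.approx(a.mean_r2_rand, abs=1e-12)


def test_scrambled_fits_are_worse_than_baseline(rng):
    X = rng.normal(size=(40, 3))
    y = X @ [1.0, 1.0, 1.0] + 0.5 * rng.normal(size=40)
    report = y_randomization(X, y, n_perm=50, seed=1)
    assert report.mean_r2_rand < fit_mlr(X, y).r2


def test_crp2_published_inputs():
    """Baseline R^2 0.64 and mean scrambled r^2 0.09 give about 0.593."""
    assert crp2(0.64, 0.09) == pytest.approx(0.8 * np.sqrt(0.55), abs=1e-12)
    assert crp2(0.64, 0.09) == pytest.approx(0.593, abs=5e-4)


def test_crp2_edge_identities():
    assert crp2(0.64, 0.0) == pytest.approx(0.64, abs=1e-12)  # R * sqrt(R^2) = R^2
    with pytest.warns(RuntimeWarning):
        assert crp2(0.64, 0.64) == 0.0
    with pytest.warns(RuntimeWarning):
        assert crp2(0.5, 0.7) == 0.0


def test_null_mean_scrambled_r2_matches_k_over_n_minus_1():
    """Under independence E[R^2] = k/(n-1); 100 scrambles at n=40, k=3."""
    rng = np.random.default_rng(17)
    X = rng.normal(size=(40, 3))
    y = rng.normal(size=40)
    report = y_randomization(X, y, n_perm=100, seed=23)
    expected = 3 / 39
    # Beta(k/2, (n-k-1)/2) sd ~ 0.059; 3 MC standard errors over 100 draws
    assert report.mean_r2_rand == pytest.approx(expected, abs=3 * 0.059 / 10)
    assert report.mean_q2_rand < 0


# ---------------------------------------------------------------------------
# acceptance gate


def test_gate_passes_on_published_statistics():
    verdicts = gt_gate(r2=0.64, q2_cv=0.56, n_ext=10, f_pvalue=1e-4)
    assert verdicts == {
        "r2": True,
        "n_ext": True,
        "r2_minus_q2": True,
        "q2_cv": True,
        "f_pvalue": True,
        "overall": True,
    }


@pytest.mark.parametrize(
    "kwargs,failing",
    [
        (dict(r2=0.59, q2_cv=0.56, n_ext=10, f_pvalue=1e-4), "r2"),
        (dict(r2=0.9, q2_cv=0.59, n_ext=10, f_pvalue=1e-4), "r2_minus_q2"),
        (dict(r2=0.64, q2_cv=0.45, n_ext=10, f_pvalue=1e-4), "q2_cv"),
        (dict(r2=0.64, q2_cv=0.56, n_ext=4, f_pvalue=1e-4), "n_ext"),
        (dict(r2=0.64, q2_cv=0.56, n_ext=10, f_pvalue=0.2), "f_pvalue"),
    ],
)
def test_gate_fails_exactly_one_criterion(kwargs, failing):
    verdicts = gt_gate(**kwargs)
    assert not verdicts[failing]
    assert not verdicts["overall"]
    others = [k for k in verdicts if k not in (failing, "overall")]
    assert all(verdicts[k] for k in others)


def test_validate_model_report_is_coherent(rng):
    X = rng.normal(size=(40, 3))
    y = X @ [1.0, 0.6, -0.4] + 0.8 * rng.normal(size=40)
    Xt = rng.normal(size=(10, 3))
    yt = Xt @ [1.0, 0.6, -0.4] + 0.8 * rng.normal(size=10)
    model = fit_mlr(X, y, names=["a", "b", "c"])
    report = validate_model(model, X, y, Xt, yt, n_perm=20, seed=3)
    assert report.q2_cv <= model.r2
    assert report.n_ext == 10
    assert set(report.vif) == {"a", "b", "c"}
    assert all(v >= 1.0 for v in report.vif.values())
    assert report.r2_minus_q2 == pytest.approx(model.r2 - report.q2_cv, abs=1e-12)
    assert report.randomization.n_perm == 20
    assert isinstance(report.gate["overall"], bool)
    assert isinstance(report.thresholds, GateThresholds)
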