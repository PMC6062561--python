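"""Nuisance correction: OLS on controls, exact-zero control means, recovery."""

import numpy as np
import pandas as pd
import pytest

from admorph.features import FeatureMatrix
from admorph.nuisance import apply_correction, fit_nuisance_model
from admorph.synthetic import generate_cohort


def _matrix(age, gender, size, features):
    data = pd.DataFrame(features)
    data["Age"] = age
    data["Gender"] = gender
    data["Brain"] = size
    data.index = pd.Index([f"s{i}" for i in range(len(data))], name="subject")
    return FeatureMatrix(data)


def test_exact_collinear_feature_recovers_slope():
    """F = 2 * size exactly: c_size=2, all other coefficients 0."""
    rng = np.random.default_rng(0)
    size = rng.uniform(1e6, 1.4e6, 20)
    fm = _matrix(rng.uniform(55, 90, 20), rng.integers(0, 2, 20), size, {"F": 2 * size})
    model = fit_nuisance_model(fm, fm.data.index, features=["F"])
    c = model.coefficients.loc["F"]
    assert c["c_size"] == pytest.approx(2.0, abs=1e-9)
    assert c["c_age"] == pytest.approx(0.0, abs=1e-6)
    assert c["c_gender"] == pytest.approx(0.0, abs=1e-3)
    assert c["b"] == pytest.approx(0.0, abs=1e-3)


def test_six_subject_cohort_matches_normal_equations_oracle():
    age = np.array([60.0, 65.0, 70.0, 75.0, 80.0, 85.0])
    gender = np.array([0, 1, 0, 1, 0, 1])
    size = np.array([1.1e6, 1.2e6, 1.15e6, 1.3e6, 1.05e6, 1.25e6])
    f = np.array([3000.0, 3300.0, 2900.0, 3500.0, 2700.0, 3400.0])
    fm = _matrix(age, gender, size, {"F": f})
    model = fit_nuisance_model(fm, fm.data.index, features=["F"])
    # independent closed-form normal-equations solution
    X = np.column_stack([age, gender, size, np.ones(6)])
    beta = np.linalg.solve(X.T @ X, X.T @ f)
    assert np.allclose(model.coefficients.loc["F"].to_numpy(), beta, rtol=1e-8)


def test_parameter_recovery_on_generated_controls(hc_ad_cohort):
    """Fitting on generated HC data recovers the generating coefficients.

    The fit uses the generating head-size column as the size covariate; the
    sum-of-structures approximation is deliberately not exact for recovery.
    """
    from admorph.synthetic import CohortSpec, StructureParams

    sp = StructureParams(
        name="F", b=1000.0, c_age=-8.0, c_gender=50.0, c_size=2e-3,
        offsets={"HC": 0.0}, sds={"HC": 120.0},
    )
    spec = CohortSpec([sp], {"HC": 1000}, seed=7, intervals=())
    subjects, baseline, _ = generate_cohort(spec)
    fm = _matrix(
        subjects["age"].to_numpy(), subjects["gender"].to_numpy(),
        subjects["head_size"].to_numpy(), {"F": baseline["F"].to_numpy()},
    )
    model = fit_nuisance_model(fm, fm.data.index, features=["F"])
    est = model.coefficients.loc["F"]
    # standard errors from the OLS covariance
    X = np.column_stack([
        subjects["age"], subjects["gender"], subjects["head_size"], np.ones(1000)
    ])
    resid = fm.data["F"].to_numpy() - X @ est[["c_age", "c_gender", "c_size", "b"]].to_numpy()
    sigma2 = resid @ resid / (1000 - 4)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    truth = np.array([sp.c_age, sp.c_gender, sp.c_size, sp.b])
    z = np.abs(est.to_numpy() - truth) / se
    assert (z < 3).all(), f"recovery z-scores {z}"


def test_corrected_control_mean_is_exactly_zero(hc_ad_cohort, table):
    from admorph.features import build_feature_matrix

    _, subjects, baseline, _ = hc_ad_cohort
    fm = _matrix(
        subjects["age"].to_numpy(), subjects["gender"].to_numpy(),
        baseline.sum(axis=1).to_numpy(),
        {"Hippo": baseline["Hippo"].to_numpy(), "Vent": baseline["Vent"].to_numpy()},
    )
    controls = fm.data.index[(subjects["diagnosis"] == "HC").to_numpy()]
    model = fit_nuisance_model(fm, controls)
    corrected = apply_correction(fm, model)
    assert corrected.status == "corrected"
    for feat in ("Hippo", "Vent"):
        assert corrected.data.loc[controls, feat].mean() == pytest.approx(
            0.0, abs=1e-9 * fm.data[feat].abs().max()
        )


def test_idempotence_on_controls(hc_ad_cohort):
    _, subjects, baseline, _ = hc_ad_cohort
    fm = _matrix(
        subjects["age"].to_numpy(), subjects["gender"].to_numpy(),
        baseline.sum(axis=1).to_numpy(), {"Hippo": baseline["Hippo"].to_numpy()},
    )
    controls = fm.data.index[(subjects["diagnosis"] == "HC").to_numpy()]
    model = fit_nuisance_model(fm, controls)
    once = apply_correction(fm, model)
    refit = fit_nuisance_model(once, controls, size=fm.data["Brain"])
    twice = apply_correction(once, refit, size=fm.data["Brain"])
    assert np.allclose(once.data["Hippo"], twice.data["Hippo"], atol=1e-6)


def test_all_zero_model_is_identity(hc_ad_cohort):
    _, subjects, baseline, _ = hc_ad_cohort
    fm = _matrix(
        subjects["age"].to_numpy(), subjects["gender"].to_numpy(),
        baseline.sum(axis=1).to_numpy(), {"Hippo": baseline["Hippo"].to_numpy()},
    )
    model = fit_nuisance_model(fm, fm.data.index)
    model.coefficients.loc[:, :] = 0.0
    corrected = apply_correction(fm, model)
    pd.testing.assert_series_equal(corrected.data["Hippo"], fm.data["Hippo"])


def test_exempt_features_pass_through(hc_ad_cohort):
    _, subjects, baseline, _ = hc_ad_cohort
    size = baseline.sum(axis=1).to_numpy()
    fm = _matrix(
        subjects["age"].to_numpy(), subjects["gender"].to_numpy(), size,
        {"Hippo": baseline["Hippo"].to_numpy()},
    )
    controls = fm.data.index[(subjects["diagnosis"] == "HC").to_numpy()]
    model = fit_nuisance_model(fm, controls)
    corrected = apply_correction(fm, model)
    # Brain (the size covariate), Age, Gender keep raw values
    for col in ("Brain", "Age", "Gender"):
        pd.testing.assert_series_equal(corrected.data[col], fm.data[col])


def test_too_few_controls_rejected():
    fm = _matrix([70.0, 71, 72], [0, 1, 0], [1e6, 1.1e6, 1.2e6], {"F": [1.0, 2, 3]})
    with pytest.raises(ValueError, match="at least 4 controls"):
        fit_nuisance_model(fm, fm.data.index)


def test_collinear_covariates_named():
    n = 10
    rng = np.random.default_rng(3)
    age = rng.uniform(55, 90, n)
    fm = _matrix(age, rng.integers(0, 2, n), 1000.0 * age, {"F": rng.normal(0, 1, n)})
    with pytest.raises(ValueError, match="age and size"):
        fit_nuisance_model(fm, fm.data.index)


def test_constant_covariate_rejected():
    n = 10
    rng = np.random.default_rng(4)
    fm = _matrix(
        np.full(n, 70.0), rng.integers(0, 2, n), rng.uniform(1e6, 1.3e6, n),
        {"F": rng.normal(0, 1, n)},
    )
    with pytest.raises(ValueError, match="age is constant"):
        fit_nuisance_model(fm, fm.data.index)


def test_unmodelled_feature_rejected(hc_ad_cohort):
    _, subjects, baseline, _ = hc_ad_cohort
    fm = _matrix(
        subjects["age"].to_numpy(), subjects["gender"].to_numpy(),
        baseline.sum(axis=1).to_numpy(),
        {"Hippo": baseline["Hippo"].to_numpy(), "Vent": baseline["Vent"].to_numpy()},
    )
    model = fit_nuisance_model(fm, fm.data.index, features=["Hippo"])
    with pytest.raises(ValueError, match="Vent"):
        apply_correction(fm, model)
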