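"""Control-fitted nuisance correction for age, gender and head size.

For each feature m a separate ordinary-least-squares regressor

    F^m = c_age^m * age + c_gender^m * gender + c_size^m * size + b^m + eps

is fitted on healthy controls only, and the *full* predicted component
(including the intercept) is subtracted from every subject's feature value.
Corrected values are therefore deviations from the healthy-control norm of
matched age, gender and head size, not volumes; the control mean of every
corrected feature is exactly zero.  Head size is approximated by total
brain volume (the ``Brain`` feature, sum of all structures), which is why
``Brain`` itself, ``Age`` and ``Gender`` are exempt from correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import COVARIATE_FEATURES, FeatureMatrix

COVARIATE_ORDER = ["c_age", "c_gender", "c_size", "b"]
DEFAULT_EXEMPT = frozenset({"Brain"}) | frozenset(COVARIATE_FEATURES)
SIZE_FEATURE = "Brain"


@dataclass
class NuisanceModel:
    """Per-feature regression coefficients fitted on controls."""

    coefficients: pd.DataFrame  # index: feature, columns: c_age, c_gender, c_size, b
    n_controls: int
    size_feature: str = SIZE_FEATURE
    coding: dict = field(
        default_factory=lambda: {"gender": "0=female,1=male", "age": "years"}
    )

    def predict(self, age, gender, size) -> pd.DataFrame:
        """Predicted nuisance component per feature for given covariates."""
        X = np.column_stack(
            [np.asarray(age, float), np.asarray(gender, float), np.asarray(size, float),
             np.ones(len(np.asarray(age)))]
        )
        beta = self.coefficients[COVARIATE_ORDER].to_numpy().T  # 4 x M
        return pd.DataFrame(X @ beta, columns=self.coefficients.index)

    def write_csv(self, path: str | Path) -> None:
        out = self.coefficients.copy()
        out.index.name = "feature"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, n_controls: int = 0) -> "NuisanceModel":
        df = pd.read_csv(path, index_col="feature")
        return cls(df[COVARIATE_ORDER], n_controls=n_controls)


def _design_matrix(fm: FeatureMatrix, subjects_index, size_values) -> np.ndarray:
    age = fm.data.loc[subjects_index, "Age"].to_numpy(float)
    gender = fm.data.loc[subjects_index, "Gender"].to_numpy(float)
    size = np.asarray(size_values, float)
    return np.column_stack([age, gender, size, np.ones(len(age))])


def _check_collinearity(X: np.ndarray) -> None:
    names = ["age", "gender", "size", "intercept"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name an offending pair via pairwise correlation / constancy
        for j, name in enumerate(names[:3]):
            if np.allclose(X[:, j], X[0, j]):
                raise ValueError(
                    f"collinear covariates: {name} is constant (collinear with intercept)"
                )
        corr = np.corrcoef(X[:, :3].T)
        for a in range(3):
            for b in range(a + 1, 3):
                if abs(corr[a, b]) > 1 - 1e-10:
                    raise ValueError(
                        f"collinear covariates: {names[a]} and {names[b]}"
                    )
        raise ValueError("collinear covariates in nuisance design matrix")


def fit_nuisance_model(
    fm: FeatureMatrix,
    control_ids,
    size: pd.Series | None = None,
    features: list[str] | None = None,
    covariates: tuple[str, ...] = ("age", "gender", "size"),
) -> NuisanceModel:
    """Fit the per-feature OLS nuisance model on healthy controls.

    Parameters
    ----------
    fm
        Feature matrix containing ``Age`` and ``Gender`` columns.
    control_ids
        Subject ids of the healthy controls used for fitting.
    size
        Head-size covariate per subject; defaults to the ``Brain`` feature
        (total brain volume as intracranial-volume approximation).
    features
        Features to model; defaults to all volumetric features.
    covariates
        Subset of ``("age", "gender", "size")`` to regress on (always with
        intercept); slopes of omitted covariates are zero in the model.
        Useful for ablating individual corrections.
    """
    control_ids = [s for s in control_ids if s in fm.data.index]
    if len(control_ids) < 4:
        raise ValueError(
            f"need at least 4 controls to fit 4 parameters, got {len(control_ids)}"
        )
    if features is None:
        features = fm.volumetric_features
    missing = [f for f in features if f not in fm.data.columns]
    if missing:
        raise ValueError(f"features not in matrix: {missing}")
    if size is None:
        size = fm.data[SIZE_FEATURE]
        size_name = SIZE_FEATURE
    else:
        size_name = getattr(size, "name", None) or "size"
    bad_cov = set(covariates) - {"age", "gender", "size"}
    if bad_cov:
        raise ValueError(f"unknown covariates: {sorted(bad_cov)}")
    X_full = _design_matrix(fm, control_ids, pd.Series(size).loc[control_ids])
    col_of = {"age": 0, "gender": 1, "size": 2}
    keep = [col_of[c] for c in ("age", "gender", "size") if c in covariates]
    X = X_full[:, keep + [3]]
    if set(covariates) == {"age", "gender", "size"}:
        _check_collinearity(X_full)
    Y = fm.data.loc[control_ids, features].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    coef = pd.DataFrame(
        0.0, index=pd.Index(features, name="feature"), columns=COVARIATE_ORDER
    )
    for j, col in enumerate(keep):
        coef.iloc[:, col] = beta[j]
    coef["b"] = beta[-1]
    return NuisanceModel(coef, n_controls=len(control_ids), size_feature=size_name)


def apply_correction(
    fm: FeatureMatrix,
    model: NuisanceModel,
    exempt: set[str] | frozenset[str] = DEFAULT_EXEMPT,
    size: pd.Series | None = None,
) -> FeatureMatrix:
    """Subtract the fitted nuisance component from every non-exempt feature.

    The covariates ``Age`` and ``Gender`` and the head-size feature are
    never corrected.  Features present in the matrix but absent from the
    model and not exempt raise ``ValueError``.
    """
    exempt = set(exempt) | set(COVARIATE_FEATURES)
    to_correct = [c for c in fm.data.columns if c not in exempt]
    unmodelled = [c for c in to_correct if c not in model.coefficients.index]
    if unmodelled:
        raise ValueError(f"features missing from nuisance model: {unmodelled}")
    if size is None:
        size_vals = fm.data[model.size_feature] if model.size_feature in fm.data.columns else None
        if size_vals is None:
            raise ValueError(
                f"size feature {model.size_feature!r} not in matrix; pass size="
            )
    else:
        size_vals = pd.Series(size).loc[fm.data.index]
    pred = model.predict(
        fm.data["Age"], fm.data["Gender"], np.asarray(size_vals, float)
    )
    pred.index = fm.data.index
    corrected = fm.data.copy()
    corrected[to_correct] = corrected[to_correct] - pred[to_correct]
    out = FeatureMatrix(corrected, status="corrected", visit=fm.visit, meta=dict(fm.meta))
    out.meta["exempt"] = sorted(exempt)
    return out
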