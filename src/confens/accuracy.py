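"""RMSD-accuracy regression: predicting ensemble accuracy from size and flexibility.

The ensemble-accuracy metric (minimum heavy-atom RMSD to the bioactive
conformation) is remarkably linear in the non-hydrogen atom count N_NHA and
the effective rotor count N_ER, so it can be predicted by ordinary least
squares:

    RMSD_pred = b0 + b_nha * N_NHA + b_er * N_ER

Adding one residual standard deviation to the prediction yields a sampling
threshold designed so that roughly 90% of ensembles have an actual accuracy
at or below it.  Published coefficient sets are shipped as immutable
presets:

====== =========== ========= ======== ============ ===== ===============================
preset intercept   b_nha     b_er     residual SD  R^2   domain
====== =========== ========= ======== ============ ===== ===============================
eq4     0.029      0.0099    0.040    0.19         0.65  all molecules
eq6     0.046      0.0063    0.050    0.17         0.52  N_ER <= 10 and N_NHA <= 35
eq7    -0.101      0.0155    0.035    0.29         0.33  N_ER > 10 or N_NHA > 35
====== =========== ========= ======== ============ ===== ===============================

Scheme ``"eq5"`` is eq4 with the +1 SD margin; scheme ``"eq8_9"`` dispatches
between eq6 and eq7 (with their margins) on the partition predicate.

The estimator is scikit-learn compatible (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
composes with sklearn model selection; refitting never mutates the presets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "LinearAccuracyModel",
    "AccuracyModel",
    "RmsdAccuracyModel",
    "preset_model",
    "predict_rmsd",
    "sampling_threshold",
    "fit_accuracy_model",
    "coverage_fraction",
    "partition_mask",
]


@dataclass(frozen=True)
class LinearAccuracyModel:
    """One linear RMSD predictor: intercept + coef_nha * N_NHA + coef_er * N_ER."""

    intercept: float
    coef_nha: float
    coef_er: float
    residual_sd: float
    r_squared: float | None = None

    def predict(self, n_nha, n_er, with_sd_margin: bool = False):
        n_nha = np.asarray(n_nha, dtype=float)
        n_er = np.asarray(n_er, dtype=float)
        out = self.intercept + self.coef_nha * n_nha + self.coef_er * n_er
        if with_sd_margin:
            out = out + self.residual_sd
        return out if out.ndim else float(out)


def partition_mask(n_nha, n_er, er_cut: float = 10.0, nha_cut: float = 35.0):
    """True where the low-flexibility/small partition applies (N_ER <= 10 and N_NHA <= 35)."""
    return (np.asarray(n_er, dtype=float) <= er_cut) & (
        np.asarray(n_nha, dtype=float) <= nha_cut
    )


# Published coefficient sets (immutable presets).
_EQ4 = LinearAccuracyModel(0.029, 0.0099, 0.040, residual_sd=0.19, r_squared=0.65)
_EQ6 = LinearAccuracyModel(0.046, 0.0063, 0.050, residual_sd=0.17, r_squared=0.52)
_EQ7 = LinearAccuracyModel(-0.101, 0.0155, 0.035, residual_sd=0.29, r_squared=0.33)


class RmsdAccuracyModel(BaseEstimator, RegressorMixin):
    """OLS predictor of ensemble RMSD accuracy from (N_NHA, N_ER).

    Parameters
    ----------
    partition:
        If True, fit/predict two independent OLS models split at
        N_ER <= 10 and N_NHA <= 35 (the complement gets the second model).
    with_sd_margin:
        If True, ``predict`` adds one residual standard deviation to the
        linear prediction, turning it into a sampling threshold with ~90%
        one-sided coverage.

    Fitted attributes (single model): ``model_`` plus the convenience
    scalars ``intercept_``, ``coef_nha_``, ``coef_er_``, ``residual_sd_``,
    ``r_squared_`` and standard errors ``se_``.  Partitioned fits expose
    ``models_ = (low, high)``.
    """

    def __init__(self, partition: bool = False, with_sd_margin: bool = False):
        self.partition = partition
        self.with_sd_margin = with_sd_margin

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns N_NHA, N_ER")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if self.partition:
            mask = partition_mask(X[:, 0], X[:, 1])
            low, low_se = self._fit_single(X[mask], y[mask])
            high, high_se = self._fit_single(X[~mask], y[~mask])
            self.models_ = (low, high)
            self.se_ = (low_se, high_se)
        else:
            model, se = self._fit_single(X, y)
            self.model_ = model
            self.se_ = se
            self.intercept_ = model.intercept
            self.coef_nha_ = model.coef_nha
            self.coef_er_ = model.coef_er
            self.residual_sd_ = model.residual_sd
            self.r_squared_ = model.r_squared
        self.n_samples_ = X.shape[0]
        return self

    @staticmethod
    def _fit_single(X: np.ndarray, y: np.ndarray) -> tuple[LinearAccuracyModel, np.ndarray]:
        if X.shape[0] < 10:
            raise ValueError(
                f"need at least 10 points per fitted partition, got {X.shape[0]}"
            )
        design = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError("design matrix is rank deficient")
        res = sm.OLS(y, design).fit()
        model = LinearAccuracyModel(
            intercept=float(res.params[0]),
            coef_nha=float(res.params[1]),
            coef_er=float(res.params[2]),
            residual_sd=float(np.sqrt(res.mse_resid)),  # SS_res / (n - 3)
            r_squared=float(res.rsquared),
        )
        return model, np.asarray(res.bse)

    # -- prediction --------------------------------------------------------
    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n_nha, n_er = X[:, 0], X[:, 1]
        margin = self.with_sd_margin
        if hasattr(self, "models_"):
            mask = partition_mask(n_nha, n_er)
            out = np.where(
                mask,
                self.models_[0].predict(n_nha, n_er, margin),
                self.models_[1].predict(n_nha, n_er, margin),
            )
            return out
        return np.asarray(self.model_.predict(n_nha, n_er, margin), dtype=float).reshape(-1)

    # -- presets -----------------------------------------------------------
    @classmethod
    def from_published(cls, scheme: str) -> "RmsdAccuracyModel":
        """Pre-fitted model from the published coefficient sets.

        ``"eq4"``/``"eq5"``: single model without/with the +1 SD margin;
        ``"eq6_7"``/``"eq8_9"``: partitioned pair without/with margins.
        """
        scheme = scheme.lower()
        if scheme in ("eq4", "eq5"):
            est = cls(partition=False, with_sd_margin=(scheme == "eq5"))
            est.model_ = _EQ4
            est.intercept_ = _EQ4.intercept
            est.coef_nha_ = _EQ4.coef_nha
            est.coef_er_ = _EQ4.coef_er
            est.residual_sd_ = _EQ4.residual_sd
            est.r_squared_ = _EQ4.r_squared
        elif scheme in ("eq6_7", "eq8_9"):
            est = cls(partition=True, with_sd_margin=(scheme == "eq8_9"))
            est.models_ = (_EQ6, _EQ7)
        else:
            raise ValueError(f"unknown preset scheme {scheme!r}")
        est.n_samples_ = 25_972
        return est

    def to_dict(self) -> dict:
        """JSON-ready representation of the fitted model."""
        def one(m: LinearAccuracyModel) -> dict:
            return {
                "intercept": m.intercept,
                "coef_nha": m.coef_nha,
                "coef_er": m.coef_er,
                "residual_sd": m.residual_sd,
                "r_squared": m.r_squared,
            }

        if hasattr(self, "models_"):
            return {
                "partition": {"er_max": 10, "nha_max": 35},
                "low": one(self.models_[0]),
                "high": one(self.models_[1]),
            }
        return {"partition": None, **one(self.model_)}


#: Alias under the domain name used in reports and docs.
AccuracyModel = RmsdAccuracyModel


def preset_model(scheme: str) -> RmsdAccuracyModel:
    """Shorthand for :meth:`RmsdAccuracyModel.from_published`."""
    return RmsdAccuracyModel.from_published(scheme)


def predict_rmsd(n_nha, n_er, model: RmsdAccuracyModel, with_sd_margin: bool = False):
    """Predicted ensemble RMSD (Å) at the given descriptors.

    ``with_sd_margin`` adds one residual SD on top of whatever margin the
    model itself carries (presets "eq5"/"eq8_9" already include it).
    """
    scalar = np.isscalar(n_nha) and np.isscalar(n_er)
    X = np.column_stack(
        [np.atleast_1d(np.asarray(n_nha, float)), np.atleast_1d(np.asarray(n_er, float))]
    )
    out = model.predict(X)
    if with_sd_margin and not model.with_sd_margin:
        if hasattr(model, "models_"):
            mask = partition_mask(X[:, 0], X[:, 1])
            out = out + np.where(
                mask, model.models_[0].residual_sd, model.models_[1].residual_sd
            )
        else:
            out = out + model.model_.residual_sd
    return float(out[0]) if scalar else out


def sampling_threshold(n_nha, n_er, scheme: str = "eq5"):
    """Minimum-RMSD conformer-sampling threshold (Å) for a molecule.

    Linear prediction plus one residual SD, intended to preserve >= 90%
    ensemble coverage when used as the RMSD-separation value during
    sampling.  ``scheme`` is ``"eq5"`` (single model) or ``"eq8_9"``
    (partitioned).
    """
    if scheme not in ("eq5", "eq8_9"):
        raise ValueError("scheme must be 'eq5' or 'eq8_9'")
    return predict_rmsd(n_nha, n_er, preset_model(scheme))


def fit_accuracy_model(data, partition: bool = False) -> RmsdAccuracyModel:
    """OLS refit from records of (n_nha, n_er, rmsd_actual).

    ``data`` is a DataFrame with columns ``n_nha``, ``n_er``,
    ``rmsd_actual`` or an iterable of such triples.
    """
    if isinstance(data, pd.DataFrame):
        X = data[["n_nha", "n_er"]].to_numpy(float)
        y = data["rmsd_actual"].to_numpy(float)
    else:
        arr = np.asarray(list(data), dtype=float)
        X, y = arr[:, :2], arr[:, 2]
    return RmsdAccuracyModel(partition=partition).fit(X, y)


def coverage_fraction(data, model: RmsdAccuracyModel, with_sd_margin: bool = False) -> float:
    """Fraction of records whose prediction is >= the actual RMSD."""
    if isinstance(data, pd.DataFrame):
        n_nha = data["n_nha"].to_numpy(float)
        n_er = data["n_er"].to_numpy(float)
        y = data["rmsd_actual"].to_numpy(float)
    else:
        arr = np.asarray(list(data), dtype=float)
        n_nha, n_er, y = arr[:, 0], arr[:, 1], arr[:, 2]
    if len(y) == 0:
        raise ValueError("no records")
    pred = predict_rmsd(n_nha, n_er, model, with_sd_margin=with_sd_margin)
    return float(np.mean(pred >= y))
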