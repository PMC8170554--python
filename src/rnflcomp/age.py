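"""Phase 1: circularly smooth per-point age-slope field.

Thickness declines with age roughly multiplicatively, so the model works
in log-thickness: for eye n at point i,

    log y_{n,i} ≈ μ_i − ρ_i (a_n − a_ref)

with ρ_i the relative loss rate per year at angular position i.  The ρ
field is estimated by penalized least squares,

    min_ρ Σ_n Σ_i (log y_{n,i} + ρ_i(a_n − a_ref) − μ_i)²
          + λ Σ_i (ρ_{i−1} − 2ρ_i + ρ_{i+1})²            (circular),

encoding that neighbouring points on the scan circle share their ageing
behaviour.  With μ profiled out, the stationarity conditions are a
circulant linear system (S_aa·I + λ·DᵀD)ρ = −S_al solved exactly in the
Fourier domain.  Compensation multiplies by exp(ρ_i (age − a_ref)),
moving every profile to the reference age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ContractError
from .profiles import profile_columns

__all__ = ["AgeModel", "AgeCompensator", "fit_age_model", "apply_age_compensation"]

LOG_FLOOR = 1.0  # µm; 0 µm is legal input, the log transform floors here


@dataclass
class AgeModel:
    """Fitted Phase-1 parameters."""

    slopes: np.ndarray          # relative loss rate per year, length P
    reference_age: float
    smoothing_lambda: float
    point_means: np.ndarray     # per-point mean log-thickness at reference age

    @property
    def P(self) -> int:
        return self.slopes.size


def _circulant_penalty_eigenvalues(P: int) -> np.ndarray:
    """Eigenvalues of DᵀD for the circular second-difference operator D."""
    omega = 2.0 * np.pi * np.arange(P // 2 + 1) / P
    return (2.0 - 2.0 * np.cos(omega)) ** 2


def _solve_slope_field(
    log_y: np.ndarray, ages: np.ndarray, reference_age: float, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact minimiser of the penalized objective; returns (ρ, μ)."""
    a = ages - reference_age
    a_c = a - a.mean()
    s_aa = float(a_c @ a_c)
    if s_aa < 1e-10:
        raise ContractError(
            "all training ages are (numerically) identical: the age slope "
            "is not identified"
        )
    l_mean = log_y.mean(axis=0)
    s_al = a_c @ (log_y - l_mean)          # length P
    P = log_y.shape[1]
    rhs = np.fft.rfft(-s_al)
    denom = s_aa + lam * _circulant_penalty_eigenvalues(P)
    rho = np.fft.irfft(rhs / denom, n=P)
    mu = l_mean + rho * a.mean()
    return rho, mu


class AgeCompensator(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer implementing the Phase-1 age fit.

    Parameters
    ----------
    reference_age : float or None
        Age every profile is normalized to; None uses the training mean.
    smoothing_lambda : float or None
        Weight of the circular second-difference penalty; None uses 10·n.
    check_labels : bool
        If True (default) and X carries a ``label`` column, refuse to fit
        on anything but normal eyes (normative training design).

    The feature matrix X is a DataFrame with profile columns ``p0..`` and
    an ``age`` column; extra columns pass through ``transform`` untouched.
    """

    def __init__(
        self,
        reference_age: float | None = None,
        smoothing_lambda: float | None = None,
        check_labels: bool = True,
    ):
        self.reference_age = reference_age
        self.smoothing_lambda = smoothing_lambda
        self.check_labels = check_labels

    # -- helpers ---------------------------------------------------------
    @staticmethod
    def _split(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
        if not isinstance(X, pd.DataFrame):
            raise ContractError("X must be a DataFrame with p0.. and covariate columns")
        P = sum(1 for c in X.columns if c.startswith("p") and c[1:].isdigit())
        if P == 0 or "age" not in X.columns:
            raise ContractError("X must contain profile columns p0.. and an age column")
        Y = X[profile_columns(P)].to_numpy(dtype=float)
        ages = X["age"].to_numpy(dtype=float)
        return Y, ages, P

    # -- estimator API ---------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "AgeCompensator":
        Y, ages, P = self._split(X)
        if self.check_labels and "label" in X.columns:
            bad = set(X["label"]) - {"normal"}
            if bad:
                raise ContractError(
                    f"Phase-1 training requires normal eyes only, found {sorted(bad)}"
                )
        if np.unique(ages).size < 3:
            raise ContractError("need at least 3 distinct ages to fit the slope field")
        ref = float(np.mean(ages)) if self.reference_age is None else float(self.reference_age)
        if ref <= 0:
            raise ContractError("reference_age must be > 0")
        lam = 10.0 * len(ages) if self.smoothing_lambda is None else float(self.smoothing_lambda)
        log_y = np.log(np.maximum(Y, LOG_FLOOR))
        rho, mu = _solve_slope_field(log_y, ages, ref, lam)
        self.model_ = AgeModel(
            slopes=rho, reference_age=ref, smoothing_lambda=lam, point_means=mu
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "model_")
        Y, ages, P = self._split(X)
        if P != self.model_.P:
            raise ContractError(f"profile length {P} != fitted P={self.model_.P}")
        comp = apply_age_compensation(Y, ages, self.model_)
        out = X.copy()
        out[profile_columns(P)] = comp
        return out


def fit_age_model(
    cohort_frame: pd.DataFrame,
    reference_age: float | None = None,
    smoothing_lambda: float | None = None,
) -> AgeModel:
    """Functional wrapper around :class:`AgeCompensator`."""
    est = AgeCompensator(reference_age=reference_age, smoothing_lambda=smoothing_lambda)
    return est.fit(cohort_frame).model_


def apply_age_compensation(values, age, model: AgeModel) -> np.ndarray:
    """Vertically rescale profile(s) to the reference age.

    Accepts a single profile (P,) or a matrix (n, P) with matching ages.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    if values.shape[-1] != model.P:
        raise ContractError(f"profile length {values.shape[-1]} != model P={model.P}")
    delta = age - model.reference_age
    if values.ndim == 1:
        return values * np.exp(model.slopes * delta)
    return values * np.exp(np.outer(delta, model.slopes))
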