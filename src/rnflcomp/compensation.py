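"""Phase 2: covariate-driven scale/shift removal and smooth residual fit.

Two stages act on age-compensated profiles:

* A small fully connected network (FCN) maps the standardized
  covariates (axial length, disc-fovea distance, disc-fovea angle,
  gender) to a global log vertical scale s and a global horizontal
  circular shift δ (index units).  Compensation applies the inverse
  deformation, exp(−s)·y(i+δ), with circular linear interpolation.
  Training minimizes the across-subject per-point variance of the
  compensated profiles plus a mean-zero penalty on (s, δ) that pins the
  cohort mean profile in place.

* A radial basis function network (RBFN) with a built-in spatial
  smoothness: Gaussian kernels over covariate space (k-means centers)
  tensored with circular Gaussian kernels over angular position.  Its
  coefficients solve a ridge least-squares problem in closed form, and
  the predicted field r̂(x, i) — the residual covariate-correlated
  structure — is subtracted from the profiles.

Axial elongation changes the peak geometry nonlinearly, which is why a
global scale/shift alone is not enough; the RBFN stage absorbs what the
rigid transform cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .age import AgeCompensator
from .exceptions import ContractError, DivergenceError
from .profiles import GENDER_CODES, NETWORK_COVARIATES, profile_columns

__all__ = [
    "apply_scale_shift",
    "ScaleShiftCompensator",
    "ResidualCompensator",
    "ProfileCompensator",
    "total_pointwise_variance",
    "rbfn_design",
]


def total_pointwise_variance(Y: np.ndarray) -> float:
    """Σ_i Var_n(y_{n,i}) — the objective all training stages drive down."""
    Y = np.asarray(Y, dtype=float)
    return float(Y.var(axis=0).sum())


# ---------------------------------------------------------------------------
# circular scale/shift primitive
# ---------------------------------------------------------------------------

def apply_scale_shift(values: np.ndarray, s, delta) -> np.ndarray:
    """Remove a deformation (log-scale s, circular shift δ) from profile(s).

    Returns ``exp(−s) · y((i + δ) mod P)`` with circular linear
    interpolation at fractional positions.  ``values`` may be one
    profile (P,) with scalar s, δ, or a matrix (n, P) with per-row
    vectors.  The identity (s=0, δ=0) is bit-exact.
    """
    values = np.asarray(values, dtype=float)
    single = values.ndim == 1
    Y = values[None, :] if single else values
    n, P = Y.shape
    s = np.broadcast_to(np.asarray(s, dtype=float), (n,))
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (n,))
    pos = (np.arange(P)[None, :] + delta[:, None]) % P
    j = np.floor(pos).astype(np.int64) % P
    f = pos - np.floor(pos)
    j1 = (j + 1) % P
    rows = np.arange(n)[:, None]
    g = (1.0 - f) * Y[rows, j] + f * Y[rows, j1]
    out = np.exp(-s)[:, None] * g
    return out[0] if single else out


def _shift_slopes(Y: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """∂/∂δ of the interpolated values (piecewise-linear slope at i+δ)."""
    n, P = Y.shape
    pos = (np.arange(P)[None, :] + delta[:, None]) % P
    j = np.floor(pos).astype(np.int64) % P
    j1 = (j + 1) % P
    rows = np.arange(n)[:, None]
    return Y[rows, j1] - Y[rows, j]


# ---------------------------------------------------------------------------
# covariate design shared by both stages
# ---------------------------------------------------------------------------

def _covariate_matrix(X: pd.DataFrame) -> np.ndarray:
    missing = [c for c in NETWORK_COVARIATES + ["gender"] if c not in X.columns]
    if missing:
        raise ContractError(f"missing covariate column(s): {missing}")
    cont = X[NETWORK_COVARIATES].to_numpy(dtype=float)
    gender = X["gender"].map(GENDER_CODES)
    if gender.isna().any():
        raise ContractError("gender must be 'M' or 'F'")
    return np.column_stack([cont, gender.to_numpy(dtype=float)])


def _split_profiles(X: pd.DataFrame) -> tuple[np.ndarray, int]:
    if not isinstance(X, pd.DataFrame):
        raise ContractError("X must be a DataFrame with p0.. and covariate columns")
    P = sum(1 for c in X.columns if c.startswith("p") and c[1:].isdigit())
    if P == 0:
        raise ContractError("X contains no profile columns p0..")
    return X[profile_columns(P)].to_numpy(dtype=float), P


class _Standardizer:
    """Z-scores the continuous covariates, passes the gender code through.

    Prediction clamps each z-score to the range seen in training: the
    compensation is a normative model and is undefined outside the
    covariate support of the healthy reference cohort, where the
    networks would extrapolate arbitrarily.
    """

    def fit(self, C: np.ndarray) -> "_Standardizer":
        self.mean_ = C[:, :-1].mean(axis=0)
        sd = C[:, :-1].std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (C[:, :-1] - self.mean_) / self.scale_
        self.z_min_ = Z.min(axis=0)
        self.z_max_ = Z.max(axis=0)
        return self

    def transform(self, C: np.ndarray) -> np.ndarray:
        Z = (C[:, :-1] - self.mean_) / self.scale_
        Z = np.clip(Z, self.z_min_, self.z_max_)
        return np.column_stack([Z, C[:, -1]])


# ---------------------------------------------------------------------------
# FCN stage
# ---------------------------------------------------------------------------

class ScaleShiftCompensator(BaseEstimator, TransformerMixin):
    """FCN predicting a global vertical scale and horizontal shift.

    Architecture: 4 → hidden_layer_sizes → 2 with tanh hidden units; the
    two linear outputs pass through bounded activations, s = s_max·tanh(·)
    and δ = delta_max·tanh(·) (delta_max defaults to P/8), which rules out
    the degenerate scale→∞ solution.  Trained by deterministic full-batch
    Adam on

        L = Σ_i Var_n(c_{n,i}) + γ [(mean_n s_n)² + (mean_n δ_n)²]

    with analytic gradients through the piecewise-linear interpolation.

    Identifiability: uniformly down-scaling every profile reduces
    across-subject variance, so the variance loss alone would push the
    mean of s toward the clamp.  The applied deformations are therefore
    the network outputs minus their training means (exact mean-zero
    projection; the stored offsets are part of the model), which pins the
    cohort mean profile in place; the soft penalty γ acts on the raw
    network means and keeps the offsets themselves small.

    The output layer starts at zero, so iteration 0 is exactly the
    identity transform and the best-loss iterate can never do worse than
    leaving the profiles alone.

    Fitted attributes: ``coefs_``, ``intercepts_``, ``loss_curve_``,
    ``scaler_``, ``s_offset_``, ``delta_offset_``, ``s_``, ``delta_``
    (training-set deformations).
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (16, 16),
        learning_rate: float = 1e-2,
        max_iter: int = 2000,
        mean_penalty: float = 10.0,
        weight_decay: float = 0.01,
        s_max: float = 1.0,
        delta_max: float | None = None,
        tol: float = 1e-8,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.mean_penalty = mean_penalty
        self.weight_decay = weight_decay
        self.s_max = s_max
        self.delta_max = delta_max
        self.tol = tol
        self.random_state = random_state

    # -- network ---------------------------------------------------------
    def _init_params(self, rng: np.random.Generator):
        sizes = [4, *self.hidden_layer_sizes, 2]
        W, b = [], []
        for k in range(len(sizes) - 1):
            fan_in, fan_out = sizes[k], sizes[k + 1]
            if k == len(sizes) - 2:
                w = np.zeros((fan_in, fan_out))  # start at the identity transform
            else:
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
            W.append(w)
            b.append(np.zeros(fan_out))
        return W, b

    def _forward(self, Z: np.ndarray, W, b, dmax: float):
        acts = [Z]
        h = Z
        for k in range(len(W) - 1):
            h = np.tanh(h @ W[k] + b[k])
            acts.append(h)
        O = h @ W[-1] + b[-1]
        s = self.s_max * np.tanh(O[:, 0])
        delta = dmax * np.tanh(O[:, 1])
        return s, delta, O, acts

    # -- estimator API ---------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "ScaleShiftCompensator":
        Y, P = _split_profiles(X)
        n = Y.shape[0]
        C = _covariate_matrix(X)
        self.scaler_ = _Standardizer().fit(C)
        Z = self.scaler_.transform(C)
        dmax = P / 8.0 if self.delta_max is None else float(self.delta_max)
        rng = np.random.default_rng(self.random_state)
        W, b = self._init_params(rng)
        gamma = self.mean_penalty

        # Adam state
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(x) for x in b]
        vb = [np.zeros_like(x) for x in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate

        idx = np.arange(P)[None, :]
        rows = np.arange(n)[:, None]
        losses = []
        best_loss = np.inf
        best = None
        prev_loss = None
        for it in range(self.max_iter + 1):
            s_raw, d_raw, O, acts = self._forward(Z, W, b, dmax)
            s = s_raw - s_raw.mean()
            delta = d_raw - d_raw.mean()
            # fused circular linear interpolation (shared with the gradient)
            pos = (idx + delta[:, None]) % P
            jf = np.floor(pos)
            j = jf.astype(np.int64) % P
            f = pos - jf
            j1 = (j + 1) % P
            Yj = Y[rows, j]
            Yj1 = Y[rows, j1]
            exps = np.exp(-s)
            c = exps[:, None] * ((1.0 - f) * Yj + f * Yj1)
            var_term = float(c.var(axis=0).sum())
            if it == 0:
                # identity-transform variance; makes weight decay dimensionless
                self._decay_scale_ = max(var_term, 1e-12)
            pen = gamma * (float(s_raw.mean()) ** 2 + float(d_raw.mean()) ** 2)
            wd = self.weight_decay * self._decay_scale_
            if wd > 0:
                pen += 0.5 * wd * sum(float(np.sum(w**2)) for w in W)
            loss = var_term + pen
            if not np.isfinite(loss):
                raise DivergenceError(it, lr)
            losses.append(loss)
            if loss < best_loss:
                best_loss = loss
                best = ([w.copy() for w in W], [x.copy() for x in b])
            if prev_loss is not None and abs(prev_loss - loss) <= self.tol * max(
                abs(prev_loss), 1e-300
            ):
                break
            prev_loss = loss
            if it == self.max_iter:
                break

            # gradients (through the mean-zero centering)
            G = (2.0 / n) * (c - c.mean(axis=0))
            dL_ds = -(G * c).sum(axis=1)
            dL_ddelta = (G * exps[:, None] * (Yj1 - Yj)).sum(axis=1)
            dL_ds = dL_ds - dL_ds.mean() + 2.0 * gamma * s_raw.mean() / n
            dL_ddelta = dL_ddelta - dL_ddelta.mean() + 2.0 * gamma * d_raw.mean() / n
            dO = np.empty_like(O)
            dO[:, 0] = dL_ds * self.s_max * (1.0 - (s_raw / self.s_max) ** 2)
            dO[:, 1] = dL_ddelta * dmax * (1.0 - (d_raw / dmax) ** 2)

            grads_W, grads_b = [None] * len(W), [None] * len(b)
            delta_back = dO
            for k in range(len(W) - 1, -1, -1):
                grads_W[k] = acts[k].T @ delta_back
                if wd > 0:
                    grads_W[k] = grads_W[k] + wd * W[k]
                grads_b[k] = delta_back.sum(axis=0)
                if k > 0:
                    delta_back = (delta_back @ W[k].T) * (1.0 - acts[k] ** 2)

            t = it + 1
            for k in range(len(W)):
                mW[k] = beta1 * mW[k] + (1 - beta1) * grads_W[k]
                vW[k] = beta2 * vW[k] + (1 - beta2) * grads_W[k] ** 2
                mb[k] = beta1 * mb[k] + (1 - beta1) * grads_b[k]
                vb[k] = beta2 * vb[k] + (1 - beta2) * grads_b[k] ** 2
                mW_hat = mW[k] / (1 - beta1**t)
                vW_hat = vW[k] / (1 - beta2**t)
                mb_hat = mb[k] / (1 - beta1**t)
                vb_hat = vb[k] / (1 - beta2**t)
                W[k] -= lr * mW_hat / (np.sqrt(vW_hat) + eps)
                b[k] -= lr * mb_hat / (np.sqrt(vb_hat) + eps)

        self.coefs_, self.intercepts_ = best
        self.loss_curve_ = np.asarray(losses)
        self.delta_max_ = dmax
        self.P_ = P
        s_raw, d_raw, _, _ = self._forward(Z, self.coefs_, self.intercepts_, dmax)
        self.s_offset_ = float(s_raw.mean())
        self.delta_offset_ = float(d_raw.mean())
        self.s_ = s_raw - self.s_offset_
        self.delta_ = d_raw - self.delta_offset_
        return self

    def predict_deformation(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Predicted (log-scale, shift) deformation per eye."""
        check_is_fitted(self, "coefs_")
        Z = self.scaler_.transform(_covariate_matrix(X))
        s, delta, _, _ = self._forward(Z, self.coefs_, self.intercepts_, self.delta_max_)
        return s - self.s_offset_, delta - self.delta_offset_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "coefs_")
        Y, P = _split_profiles(X)
        if P != self.P_:
            raise ContractError(f"profile length {P} != fitted P={self.P_}")
        s, delta = self.predict_deformation(X)
        out = X.copy()
        out[profile_columns(P)] = apply_scale_shift(Y, s, delta)
        return out


# ---------------------------------------------------------------------------
# RBFN stage
# ---------------------------------------------------------------------------

def _angular_basis(P: int, M: int, width_factor: float) -> np.ndarray:
    """(P, M) circular Gaussian bases at equally spaced angular centers."""
    spacing = P / M
    width = width_factor * spacing
    centers = spacing * np.arange(M)
    d = np.abs(np.arange(P)[:, None] - centers[None, :])
    d = np.minimum(d, P - d)
    return np.exp(-0.5 * (d / width) ** 2)


def rbfn_design(Z: np.ndarray, centers: np.ndarray, bandwidth: float) -> np.ndarray:
    """(n, K) Gaussian kernel responses of covariate points to the centers."""
    d2 = cdist(np.atleast_2d(Z), centers, metric="sqeuclidean")
    return np.exp(-0.5 * d2 / bandwidth**2)


class ResidualCompensator(BaseEstimator, TransformerMixin):
    """RBFN removing residual covariate-correlated structure.

    The predicted field is r̂(x, i) = Σ_k Σ_m v_{k,m} φ_k(x) ψ_m(i) with
    φ Gaussian in (standardized) covariate space and ψ circular Gaussian
    in angle — smooth in i by construction.  Coefficients solve

        min_v ‖R − Φ V Ψᵀ‖² + α ‖V‖²,   R = profiles − per-point mean,

    in closed form via the eigendecompositions of ΦᵀΦ and ΨᵀΨ.

    Fitted attributes: ``centers_``, ``bandwidth_``, ``coefficients_``
    (K×M), ``point_means_``, ``scaler_``.
    """

    def __init__(
        self,
        n_covariate_centers: int = 12,
        n_angular_centers: int = 24,
        angular_width_factor: float = 1.5,
        ridge: float | None = None,
        random_state: int = 0,
    ):
        self.n_covariate_centers = n_covariate_centers
        self.n_angular_centers = n_angular_centers
        self.angular_width_factor = angular_width_factor
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "ResidualCompensator":
        Y, P = _split_profiles(X)
        n = Y.shape[0]
        if self.n_covariate_centers < 1 or self.n_angular_centers < 1:
            raise ContractError("need at least one center in each space")
        C = _covariate_matrix(X)
        self.scaler_ = _Standardizer().fit(C)
        Z = self.scaler_.transform(C)
        K = min(self.n_covariate_centers, n)
        km = KMeans(n_clusters=K, n_init=10, random_state=self.random_state)
        km.fit(Z)
        self.centers_ = km.cluster_centers_
        if K > 1:
            self.bandwidth_ = float(np.median(pdist(self.centers_)))
        if K == 1 or self.bandwidth_ <= 0:
            self.bandwidth_ = 1.0

        Phi = rbfn_design(Z, self.centers_, self.bandwidth_)       # (n, K)
        Psi = _angular_basis(P, self.n_angular_centers, self.angular_width_factor)
        self.point_means_ = Y.mean(axis=0)
        R = Y - self.point_means_
        alpha = 1e-3 * n if self.ridge is None else float(self.ridge)

        A = Phi.T @ Phi                      # (K, K)
        B = Psi.T @ Psi                      # (M, M)
        Ct = Phi.T @ R @ Psi                 # (K, M)
        ea, Ua = np.linalg.eigh(A)
        eb, Ub = np.linalg.eigh(B)
        denom = np.outer(ea, eb) + alpha
        if np.any(np.abs(denom) < 1e-12):
            raise ContractError(
                "normal equations are singular at ridge=0; use a nonzero ridge"
            )
        V = Ua @ ((Ua.T @ Ct @ Ub) / denom) @ Ub.T
        self.coefficients_ = V
        self.Psi_ = Psi
        self.P_ = P
        return self

    def predict_field(self, X: pd.DataFrame) -> np.ndarray:
        """The fitted residual field r̂(x, i) for each row of X, (n, P)."""
        check_is_fitted(self, "coefficients_")
        Z = self.scaler_.transform(_covariate_matrix(X))
        Phi = rbfn_design(Z, self.centers_, self.bandwidth_)
        return Phi @ self.coefficients_ @ self.Psi_.T

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "coefficients_")
        Y, P = _split_profiles(X)
        if P != self.P_:
            raise ContractError(f"profile length {P} != fitted P={self.P_}")
        out = X.copy()
        out[profile_columns(P)] = np.clip(Y - self.predict_field(X), 0.0, None)
        return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

class ProfileCompensator(BaseEstimator, TransformerMixin):
    """Age → scale/shift → residual compensation, trained sequentially.

    Each stage is fit on the output of the previous one (all on the
    normative training cohort); ``variance_trajectory_`` records the
    summed per-point variance before training and after each stage.
    """

    def __init__(
        self,
        age: AgeCompensator | None = None,
        scale_shift: ScaleShiftCompensator | None = None,
        residual: ResidualCompensator | None = None,
        random_state: int = 0,
    ):
        self.age = age
        self.scale_shift = scale_shift
        self.residual = residual
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "ProfileCompensator":
        self.age_ = clone(self.age) if self.age is not None else AgeCompensator()
        self.scale_shift_ = (
            clone(self.scale_shift)
            if self.scale_shift is not None
            else ScaleShiftCompensator(random_state=self.random_state)
        )
        self.residual_ = (
            clone(self.residual)
            if self.residual is not None
            else ResidualCompensator(random_state=self.random_state)
        )
        Y0, P = _split_profiles(X)
        traj = [total_pointwise_variance(Y0)]
        X1 = self.age_.fit(X).transform(X)
        traj.append(total_pointwise_variance(_split_profiles(X1)[0]))
        X2 = self.scale_shift_.fit(X1).transform(X1)
        traj.append(total_pointwise_variance(_split_profiles(X2)[0]))
        X3 = self.residual_.fit(X2).transform(X2)
        traj.append(total_pointwise_variance(_split_profiles(X3)[0]))
        self.variance_trajectory_ = traj
        self.P_ = P
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "variance_trajectory_")
        for col in ["age", "gender", *NETWORK_COVARIATES]:
            if col not in X.columns:
                raise ContractError(f"missing covariate column: {col!r}")
        if X[["age", "gender", *NETWORK_COVARIATES]].isna().any().any():
            bad = (
                X[["age", "gender", *NETWORK_COVARIATES]]
                .isna()
                .any(axis=0)
            )
            raise ContractError(
                f"missing covariate value(s) in column(s): {list(bad[bad].index)}"
            )
        return self.residual_.transform(self.scale_shift_.transform(self.age_.transform(X)))


def compensate(cohort, compensator: ProfileCompensator):
    """Apply a trained compensator to a :class:`~rnflcomp.profiles.Cohort`."""
    out = compensator.transform(cohort.to_frame())
    return cohort.with_profiles(out[profile_columns(cohort.P)].to_numpy(dtype=float))
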