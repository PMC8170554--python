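"""JSON artifacts for trained compensator models.

One artifact holds everything needed to reproduce a compensation:
Phase-1 slope field, FCN weights, RBFN centers/coefficients, the
covariate standardization constants, the training variance trajectory
and an echo of the configuration.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from .age import AgeCompensator, AgeModel
from .compensation import (
    ProfileCompensator,
    ResidualCompensator,
    ScaleShiftCompensator,
    _Standardizer,
)
from .exceptions import ContractError

__all__ = ["save_compensator", "load_compensator"]


def _pkg_version() -> str:
    try:
        return version("rnflcomp")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _arr(a) -> list:
    return np.asarray(a).tolist()


def _scaler_dict(sc: _Standardizer) -> dict:
    return {
        "mean": _arr(sc.mean_),
        "scale": _arr(sc.scale_),
        "z_min": _arr(sc.z_min_),
        "z_max": _arr(sc.z_max_),
    }


def _scaler_from(d: dict) -> _Standardizer:
    sc = _Standardizer()
    sc.mean_ = np.asarray(d["mean"], dtype=float)
    sc.scale_ = np.asarray(d["scale"], dtype=float)
    sc.z_min_ = np.asarray(d["z_min"], dtype=float)
    sc.z_max_ = np.asarray(d["z_max"], dtype=float)
    return sc


def compensator_to_dict(model: ProfileCompensator, config_echo: dict | None = None) -> dict:
    if not hasattr(model, "variance_trajectory_"):
        raise ContractError("compensator is not fitted")
    age = model.age_.model_
    fcn = model.scale_shift_
    rbf = model.residual_
    return {
        "format": "rnflcomp-compensator",
        "package_version": _pkg_version(),
        "config": config_echo or {},
        "P": model.P_,
        "variance_trajectory": _arr(model.variance_trajectory_),
        "age": {
            "slopes": _arr(age.slopes),
            "reference_age": age.reference_age,
            "smoothing_lambda": age.smoothing_lambda,
            "point_means": _arr(age.point_means),
        },
        "fcn": {
            "params": fcn.get_params(),
            "coefs": [_arr(w) for w in fcn.coefs_],
            "intercepts": [_arr(b) for b in fcn.intercepts_],
            "delta_max": fcn.delta_max_,
            "s_offset": fcn.s_offset_,
            "delta_offset": fcn.delta_offset_,
            "scaler": _scaler_dict(fcn.scaler_),
            "loss_curve": _arr(fcn.loss_curve_),
        },
        "rbfn": {
            "params": rbf.get_params(),
            "centers": _arr(rbf.centers_),
            "bandwidth": rbf.bandwidth_,
            "coefficients": _arr(rbf.coefficients_),
            "point_means": _arr(rbf.point_means_),
            "scaler": _scaler_dict(rbf.scaler_),
        },
    }


def compensator_from_dict(d: dict) -> ProfileCompensator:
    if d.get("format") != "rnflcomp-compensator":
        raise ContractError("not a compensator artifact")
    P = int(d["P"])

    age_est = AgeCompensator()
    a = d["age"]
    age_est.model_ = AgeModel(
        slopes=np.asarray(a["slopes"], dtype=float),
        reference_age=float(a["reference_age"]),
        smoothing_lambda=float(a["smoothing_lambda"]),
        point_means=np.asarray(a["point_means"], dtype=float),
    )

    f = d["fcn"]
    params = dict(f["params"])
    if isinstance(params.get("hidden_layer_sizes"), list):
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
    fcn = ScaleShiftCompensator(**params)
    fcn.coefs_ = [np.asarray(w, dtype=float) for w in f["coefs"]]
    fcn.intercepts_ = [np.asarray(b, dtype=float) for b in f["intercepts"]]
    fcn.delta_max_ = float(f["delta_max"])
    fcn.s_offset_ = float(f["s_offset"])
    fcn.delta_offset_ = float(f["delta_offset"])
    fcn.scaler_ = _scaler_from(f["scaler"])
    fcn.loss_curve_ = np.asarray(f["loss_curve"], dtype=float)
    fcn.P_ = P

    r = d["rbfn"]
    rbf = ResidualCompensator(**r["params"])
    rbf.centers_ = np.asarray(r["centers"], dtype=float)
    rbf.bandwidth_ = float(r["bandwidth"])
    rbf.coefficients_ = np.asarray(r["coefficients"], dtype=float)
    rbf.point_means_ = np.asarray(r["point_means"], dtype=float)
    rbf.scaler_ = _scaler_from(r["scaler"])
    from .compensation import _angular_basis

    rbf.Psi_ = _angular_basis(
        P, rbf.n_angular_centers, rbf.angular_width_factor
    )
    rbf.P_ = P

    model = ProfileCompensator(age=age_est, scale_shift=fcn, residual=rbf)
    model.age_, model.scale_shift_, model.residual_ = age_est, fcn, rbf
    model.variance_trajectory_ = list(d["variance_trajectory"])
    model.P_ = P
    return model


def save_compensator(model: ProfileCompensator, path, config_echo: dict | None = None) -> None:
    Path(path).write_text(
        json.dumps(compensator_to_dict(model, config_echo)), encoding="utf-8"
    )


def load_compensator(path) -> ProfileCompensator:
    return compensator_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
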