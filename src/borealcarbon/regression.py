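"""Polynomial regression of carbon pools on the wetness index.

The model family is ordinary least squares of (optionally log-transformed)
stock on a degree-1 or degree-2 polynomial in the modelled wetness
probability x in [0, 1]. Log-scale models are back-transformed with Duan's
nonparametric smearing estimator (the mean of exponentiated residuals), and
out-of-sample error is measured by leave-one-out cross-validation with the
smearing factor recomputed inside every fold.

For numerical stability the fit is carried out in an orthonormal basis of
the observed design (QR factorisation); coefficients are reported both in
that basis and on the raw power basis, and the two produce identical fitted
values.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InvalidArgumentError


def smearing_factor(log_residuals: Sequence[float]) -> float:
    """Duan's smearing estimator: mean of exp(residual).

    For residuals of an OLS fit with intercept the residual mean is zero, so
    by Jensen's inequality the factor is always >= 1.
    """
    r = np.asarray(log_residuals, dtype=float)
    if r.size == 0:
        raise InvalidArgumentError("smearing factor of an empty residual set")
    return float(np.mean(np.exp(r)))


def _as_x(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2:
        if x.shape[1] != 1:
            raise InvalidArgumentError("wetness design must be a single column")
        x = x[:, 0]
    return x


def _vander(x: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(x, degree + 1, increasing=True)


class WetnessCarbonRegressor(RegressorMixin, BaseEstimator):
    """Carbon stock as a polynomial in the wetness index.

    Parameters
    ----------
    degree : 1 or 2
        Polynomial degree in wetness.
    log_scale : bool
        Fit on log(stock); predictions are back-transformed with the
        smearing factor.

    Attributes (after ``fit``)
    --------------------------
    coefficients_ : raw power-basis coefficients (constant first).
    coefficients_orthogonal_ : the same fit in the orthonormal basis.
    standard_errors_ : OLS standard errors of the raw coefficients.
    smearing_factor_ : Duan factor (1.0 for linear-scale models).
    residuals_ : fit-scale residuals.
    r2_, f_stat_, p_value_ : overall-regression diagnostics.
    n_ : number of observations.
    """

    def __init__(self, degree: int = 2, log_scale: bool = True):
        self.degree = degree
        self.log_scale = log_scale

    def fit(self, X, y, plot_ids: Optional[Sequence] = None):
        if self.degree not in (1, 2):
            raise InvalidArgumentError(f"degree must be 1 or 2, got {self.degree}")
        x = _as_x(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise InvalidArgumentError("x and y must have equal length")
        n = x.size
        if n <= self.degree + 1:
            raise InvalidArgumentError(f"need more than {self.degree + 1} observations")
        if self.log_scale and np.any(y <= 0):
            bad = np.flatnonzero(y <= 0)
            ids = [plot_ids[i] for i in bad] if plot_ids is not None else bad.tolist()
            raise InvalidArgumentError(
                f"log-scale fit requires positive stocks; offending plots: {ids}"
            )
        z = np.log(y) if self.log_scale else y
        V = _vander(x, self.degree)
        Q, R = np.linalg.qr(V)
        beta_orth, *_ = np.linalg.lstsq(Q, z, rcond=None)
        beta = np.linalg.solve(R, beta_orth)
        fitted = Q @ beta_orth
        resid = z - fitted

        sse = float(resid @ resid)
        sst = float(np.sum((z - z.mean()) ** 2))
        p = self.degree  # slope terms
        dof = n - p - 1
        self.r2_ = 1.0 - sse / sst if sst > 0 else 1.0
        if sse > 0 and dof > 0:
            self.f_stat_ = (sst - sse) / p / (sse / dof)
            self.p_value_ = float(stats.f.sf(self.f_stat_, p, dof))
        else:
            self.f_stat_ = math.inf
            self.p_value_ = 0.0
        sigma2 = sse / dof if dof > 0 else 0.0
        Rinv = np.linalg.inv(R)
        cov = sigma2 * (Rinv @ Rinv.T)
        self.standard_errors_ = np.sqrt(np.diag(cov))
        self.coefficients_ = beta
        self.coefficients_orthogonal_ = beta_orth
        self.residuals_ = resid
        self.smearing_factor_ = smearing_factor(resid) if self.log_scale else 1.0
        self.n_ = n
        self.x_range_ = (float(x.min()), float(x.max()))
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted stock on the response scale, Mg C ha^-1.

        Wetness outside [0, 1] is refused (extrapolation beyond the index's
        domain is meaningless)."""
        x = _as_x(X)
        if np.any(x < 0) or np.any(x > 1):
            raise InvalidArgumentError("wetness must lie in [0, 1]")
        eta = _vander(x, self.degree) @ self.coefficients_
        if self.log_scale:
            return np.exp(eta) * self.smearing_factor_
        return eta

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "log_scale": self.log_scale,
            "coefficients": self.coefficients_.tolist(),
            "coefficients_orthogonal": self.coefficients_orthogonal_.tolist(),
            "standard_errors": self.standard_errors_.tolist(),
            "smearing_factor": self.smearing_factor_,
            "r2": self.r2_,
            "f_stat": self.f_stat_,
            "p_value": self.p_value_,
            "n": self.n_,
            "rmse_loocv": getattr(self, "rmse_loocv_", None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WetnessCarbonRegressor":
        model = cls(degree=d["degree"], log_scale=d["log_scale"])
        model.coefficients_ = np.asarray(d["coefficients"], dtype=float)
        model.coefficients_orthogonal_ = np.asarray(d["coefficients_orthogonal"], dtype=float)
        model.standard_errors_ = np.asarray(d["standard_errors"], dtype=float)
        model.smearing_factor_ = d["smearing_factor"]
        model.r2_ = d["r2"]
        model.f_stat_ = d["f_stat"]
        model.p_value_ = d["p_value"]
        model.n_ = d["n"]
        if d.get("rmse_loocv") is not None:
            model.rmse_loocv_ = d["rmse_loocv"]
        return model


def fit_moisture_model(x, y, degree: int = 2, log_scale: bool = True, plot_ids=None):
    """Thin functional wrapper over :class:`WetnessCarbonRegressor`."""
    return WetnessCarbonRegressor(degree=degree, log_scale=log_scale).fit(x, y, plot_ids=plot_ids)


def loocv(x, y, degree: int = 2, log_scale: bool = True) -> Tuple[float, float]:
    """Leave-one-out cross-validation on the response scale.

    Each fold refits the model without observation i and predicts y_i on the
    back-transformed scale using that fold's own smearing factor (no
    information leaks from the held-out point). Returns (RMSE, cross-
    validated R^2), both on the stock scale.
    """
    x = _as_x(x)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < degree + 3:
        raise InvalidArgumentError("too few observations for leave-one-out validation")
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        xi, yi = x[mask], y[mask]
        if np.ptp(xi) == 0:
            raise InvalidArgumentError("degenerate fold: constant wetness")
        model = WetnessCarbonRegressor(degree=degree, log_scale=log_scale).fit(xi, yi)
        preds[i] = model.predict([x[i]])[0]
        mask[i] = True
    err = y - preds
    rmse = float(np.sqrt(np.mean(err**2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_cv = 1.0 - float(err @ err) / sst if sst > 0 else 1.0
    return rmse, r2_cv


def loocv_linear(design: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Leave-one-out RMSE / R^2 for a plain linear design matrix (used by the
    ALS area-based model, where no retransformation is involved).

    Uses the exact hat-matrix identity e_i / (1 - h_ii), equivalent to
    refitting without each observation."""
    F = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    beta, *_ = np.linalg.lstsq(F, y, rcond=None)
    resid = y - F @ beta
    G = np.linalg.pinv(F.T @ F)
    h = np.einsum("ij,jk,ik->i", F, G, F)
    loo = resid / (1.0 - h)
    rmse = float(np.sqrt(np.mean(loo**2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_cv = 1.0 - float(loo @ loo) / sst if sst > 0 else 1.0
    return rmse, r2_cv
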