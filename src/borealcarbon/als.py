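"""Area-based ALS mapping of the tree carbon pool.

Per 12.5 m cell, the normalized point heights are summarized by three
metrics: P95 (95th height percentile, linear interpolation between order
statistics), HSD (standard deviation of heights, n-1 denominator) and VR
(vegetation ratio: fraction of returns above a canopy threshold, default
1.5 m). Survey plots whose field-measured Lorey's mean height disagrees with
P95 by more than 5 m are excluded as georeferencing / land-use-change
suspects. The remaining plots calibrate the model

    tree C = c0 + c1 * (P95 * VR)^1.2 - c3 * HSD   [Mg C ha^-1]

which is linear in the coefficients given the fixed exponent and is applied
wall-to-wall on the metric rasters, with negative predictions clamped to 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InvalidArgumentError, InvalidStateError
from .rasters import RasterGrid
from .records import TreeRecord
from .regression import loocv_linear

DEFAULT_CANOPY_THRESHOLD = 1.5  # m
DEFAULT_EXCLUSION_LIMIT = 5.0  # m


@dataclass
class AlsCellMetrics:
    """Height metrics of one raster cell (or plot footprint)."""

    cell_id: str
    p95: float
    hsd: float
    vr: float
    n_points: int

    def __post_init__(self):
        if self.n_points > 0:
            if self.p95 < 0 or self.hsd < 0 or not 0 <= self.vr <= 1:
                raise InvalidArgumentError(f"cell {self.cell_id}: invalid metrics")


def cell_metrics(
    heights: Sequence[float],
    canopy_threshold: float = DEFAULT_CANOPY_THRESHOLD,
    cell_id: str = "",
) -> AlsCellMetrics:
    """P95 / HSD / VR for one cell's normalized point heights.

    An empty cell yields a nodata record (``n_points == 0`` and NaN metrics).
    """
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        return AlsCellMetrics(cell_id, math.nan, math.nan, math.nan, 0)
    if np.any(h < 0):
        raise InvalidArgumentError("normalized heights must be >= 0")
    p95 = float(np.percentile(h, 95))  # linear interpolation between order stats
    hsd = float(np.std(h, ddof=1)) if h.size > 1 else 0.0
    vr = float(np.mean(h > canopy_threshold))
    return AlsCellMetrics(cell_id, p95, hsd, vr, int(h.size))


def lorey_height(trees: Sequence[TreeRecord]) -> float:
    """Basal-area-weighted mean tree height (weights proportional to DBH^2)."""
    withh = [t for t in trees if t.height is not None]
    if not withh:
        raise InvalidArgumentError("Lorey's height needs at least one tree with height")
    w = np.array([t.dbh**2 for t in withh])
    h = np.array([t.height for t in withh])
    return float((w * h).sum() / w.sum())


def exclusion_filter(
    plots: pd.DataFrame, limit: float = DEFAULT_EXCLUSION_LIMIT
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split plots into kept and excluded by the |Lorey - P95| <= limit rule.

    ``plots`` must carry columns ``plot_id``, ``lorey`` and ``p95``. Returns
    (kept, exclusion log); the log records each excluded plot id with its
    discrepancy. Applying the filter twice is a no-op.
    """
    if limit <= 0:
        raise InvalidArgumentError("exclusion limit must be positive")
    disc = (plots["lorey"] - plots["p95"]).abs()
    keep = disc <= limit
    log = plots.loc[~keep, ["plot_id"]].copy()
    log["discrepancy_m"] = disc[~keep]
    return plots.loc[keep].copy(), log.reset_index(drop=True)


class AlsCarbonRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of the fixed-exponent area-based tree-C model.

    The design is ``[1, (P95*VR)^exponent, -HSD]`` so the fit is linear;
    fitted attributes expose the conventional signs (``c3_`` multiplies
    ``-HSD`` in the model).
    """

    def __init__(self, exponent: float = 1.2):
        self.exponent = exponent

    @staticmethod
    def _columns(X) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            return X["p95"].to_numpy(float), X["hsd"].to_numpy(float), X["vr"].to_numpy(float)
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[1] != 3:
            raise InvalidArgumentError("X must have columns [p95, hsd, vr]")
        return A[:, 0], A[:, 1], A[:, 2]

    def _design(self, X) -> np.ndarray:
        if self.exponent <= 0:
            raise InvalidArgumentError("exponent must be positive")
        p95, hsd, vr = self._columns(X)
        return np.column_stack([np.ones_like(p95), (p95 * vr) ** self.exponent, -hsd])

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        F = self._design(X)
        if F.shape[0] < 10:
            raise InvalidArgumentError("need at least 10 plots after exclusion")
        canopy_dead = not np.any(F[:, 1])
        if canopy_dead:
            # all (P95*VR) zero: the canopy term vanishes identically and the
            # model degenerates to intercept - c3*HSD
            Fr = F[:, [0, 2]]
            if np.linalg.matrix_rank(Fr) < 2:
                raise InvalidStateError("rank-deficient ALS design (constant metrics)")
            beta2, *_ = np.linalg.lstsq(Fr, y, rcond=None)
            beta = np.array([beta2[0], 0.0, beta2[1]])
        else:
            if np.linalg.matrix_rank(F) < F.shape[1]:
                raise InvalidStateError("rank-deficient ALS design (e.g. constant metrics)")
            beta, *_ = np.linalg.lstsq(F, y, rcond=None)
        self.c0_, self.c1_, self.c3_ = float(beta[0]), float(beta[1]), float(beta[2])
        fitted = F @ beta
        resid = y - fitted
        sst = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
        self.rmse_loocv_, self.r2_loocv_ = loocv_linear(F, y)
        self.n_ = int(y.size)
        return self

    def predict(self, X) -> np.ndarray:
        return self._design(X) @ np.array([self.c0_, self.c1_, self.c3_])

    def to_dict(self) -> dict:
        return {
            "exponent": self.exponent,
            "c0": self.c0_,
            "c1": self.c1_,
            "c3": self.c3_,
            "r2": self.r2_,
            "rmse_loocv": self.rmse_loocv_,
            "n": self.n_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlsCarbonRegressor":
        model = cls(exponent=d["exponent"])
        model.c0_, model.c1_, model.c3_ = d["c0"], d["c1"], d["c3"]
        model.r2_ = d.get("r2")
        model.rmse_loocv_ = d.get("rmse_loocv")
        model.n_ = d.get("n")
        return model


def fit_als_model(metrics, tree_c, exponent: float = 1.2) -> AlsCarbonRegressor:
    """Thin functional wrapper over :class:`AlsCarbonRegressor`."""
    return AlsCarbonRegressor(exponent=exponent).fit(metrics, tree_c)


def predict_raster(
    model: AlsCarbonRegressor,
    p95: RasterGrid,
    hsd: RasterGrid,
    vr: RasterGrid,
) -> Tuple[RasterGrid, int]:
    """Wall-to-wall tree-C prediction on aligned metric rasters.

    Nodata propagates; negative predictions are clamped to 0 and counted.
    Returns (prediction raster, number of clamped cells).
    """
    for other in (hsd, vr):
        if not p95.aligned_with(other):
            raise InvalidArgumentError("metric rasters are not aligned")
    valid = p95.mask & hsd.mask & vr.mask
    pred = np.full(p95.values.shape, p95.nodata, dtype=float)
    if valid.any():
        X = np.column_stack(
            [p95.values[valid], hsd.values[valid], vr.values[valid]]
        )
        vals = model.predict(X)
        clamped = int(np.sum(vals < 0))
        pred[valid] = np.maximum(vals, 0.0)
    else:
        clamped = 0
    out = RasterGrid(
        values=pred,
        origin=p95.origin,
        cell_size=p95.cell_size,
        nodata=p95.nodata,
        crs=p95.crs,
    )
    return out, clamped
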