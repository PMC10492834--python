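"""Descriptive statistics, landscape partitioning and wall-to-wall SOC maps.

Pool summaries mirror inventory reporting (N / mean / SD / median / min /
max / SE per pool and peat case). The partition report expresses each pool
as a share of the landscape's grand total (soil + tree), the belowground
share of tree C, and the peat plots' share of the soil C stock; shares are
rounded to integer percent for display while full precision is retained.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .rasters import RasterGrid
from .regression import WetnessCarbonRegressor

PEAT_CASES = ("including_peat", "excluding_peat", "only_peat")
POOL_COLUMNS = ("total_soc", "organic", "mineral", "tree_total", "tree_above", "tree_below")


@dataclass
class PoolSummary:
    pool: str
    case: str
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    se: float
    sd_defined: bool = True


@dataclass
class PartitionReport:
    """Landscape C partitioning; shares in percent, stocks in Mg C ha^-1."""

    soc_share: float
    tree_share: float
    organic_share: float
    mineral_share: float
    tree_below_share: float
    peat_plot_fraction: float
    peat_soc_share: float
    grand_total_mean: float
    excluding_peat_mean: float

    def rounded(self) -> Dict[str, float]:
        """Display view: integer percent, integer Mg C ha^-1."""
        return {k: round(v) for k, v in asdict(self).items()}

    def to_dict(self) -> dict:
        return asdict(self)


def _summary_row(pool: str, case: str, values: np.ndarray) -> PoolSummary:
    n = values.size
    sd_defined = n > 1
    sd = float(np.std(values, ddof=1)) if sd_defined else 0.0
    return PoolSummary(
        pool=pool,
        case=case,
        n=int(n),
        mean=float(values.mean()),
        sd=sd,
        median=float(np.median(values)),
        min=float(values.min()),
        max=float(values.max()),
        se=sd / math.sqrt(n) if sd_defined else 0.0,
        sd_defined=sd_defined,
    )


def summarize_pools(pools: pd.DataFrame) -> List[PoolSummary]:
    """Per-pool descriptive statistics for the three peat cases.

    ``pools`` needs an ``is_peat`` column plus any of the stock columns
    (``total_soc``, ``organic``, ``mineral``, ``tree_total``, ...). Empty
    cases are omitted.
    """
    if "is_peat" not in pools.columns:
        raise InvalidArgumentError("pools table needs an is_peat column")
    peat = pools["is_peat"].astype(bool)
    cases = {
        "including_peat": np.ones(len(pools), dtype=bool),
        "excluding_peat": ~peat.to_numpy(),
        "only_peat": peat.to_numpy(),
    }
    out: List[PoolSummary] = []
    for pool in POOL_COLUMNS:
        if pool not in pools.columns:
            continue
        col = pools[pool].to_numpy(float)
        for case, mask in cases.items():
            if not mask.any():
                continue
            out.append(_summary_row(pool, case, col[mask]))
    return out


def summaries_frame(summaries: Sequence[PoolSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def partition_report_from_means(
    mean_total_soc: float,
    mean_organic: float,
    mean_mineral: float,
    mean_tree: float,
    mean_tree_below: float,
    n_all: int,
    n_peat: int,
    mean_peat_soc: float,
) -> PartitionReport:
    """Partitioning arithmetic from case means and counts.

    All shares are percentages of the same grand total (mean soil + mean
    tree stock); the peat share of soil C weights the peat-case mean by its
    plot count; the excluding-peat mean follows from weighted-mean
    consistency ``n_all * mean_all = n_peat * mean_peat + n_rest * mean_rest``.
    """
    grand = mean_total_soc + mean_tree
    if grand <= 0:
        raise InvalidArgumentError("grand total stock is zero; shares undefined")
    n_rest = n_all - n_peat
    excluding = (
        (n_all * mean_total_soc - n_peat * mean_peat_soc) / n_rest if n_rest > 0 else math.nan
    )
    return PartitionReport(
        soc_share=100.0 * mean_total_soc / grand,
        tree_share=100.0 * mean_tree / grand,
        organic_share=100.0 * mean_organic / grand,
        mineral_share=100.0 * mean_mineral / grand,
        tree_below_share=100.0 * mean_tree_below / mean_tree if mean_tree > 0 else 0.0,
        peat_plot_fraction=100.0 * n_peat / n_all,
        peat_soc_share=100.0 * (n_peat * mean_peat_soc) / (n_all * mean_total_soc),
        grand_total_mean=grand,
        excluding_peat_mean=excluding,
    )


def partition_report(summaries: Sequence[PoolSummary]) -> PartitionReport:
    """Partition report from :func:`summarize_pools` output."""
    idx = {(s.pool, s.case): s for s in summaries}

    def get(pool, case="including_peat"):
        if (pool, case) not in idx:
            raise InvalidArgumentError(f"missing summary for {pool} / {case}")
        return idx[(pool, case)]

    soc = get("total_soc")
    peat = idx.get(("total_soc", "only_peat"))
    n_peat = peat.n if peat else 0
    mean_peat = peat.mean if peat else 0.0
    return partition_report_from_means(
        mean_total_soc=soc.mean,
        mean_organic=get("organic").mean,
        mean_mineral=get("mineral").mean,
        mean_tree=get("tree_total").mean,
        mean_tree_below=get("tree_below").mean,
        n_all=soc.n,
        n_peat=n_peat,
        mean_peat_soc=mean_peat,
    )


def soc_raster(model: WetnessCarbonRegressor, wetness: RasterGrid) -> RasterGrid:
    """Cellwise SOC prediction (with smearing) on the wetness raster.

    Nodata propagates; wetness outside [0, 1] is set to nodata and counted
    in the returned grid's ``out_of_range`` attribute."""
    w = wetness.values
    valid = wetness.mask & (w >= 0) & (w <= 1)
    out_of_range = int(np.sum(wetness.mask & ~((w >= 0) & (w <= 1))))
    pred = np.full(w.shape, wetness.nodata, dtype=float)
    if valid.any():
        pred[valid] = model.predict(w[valid])
    grid = RasterGrid(
        values=pred,
        origin=wetness.origin,
        cell_size=wetness.cell_size,
        nodata=wetness.nodata,
        crs=wetness.crs,
    )
    grid.out_of_range = out_of_range
    return grid


def tree_fraction_by_class(pools: pd.DataFrame) -> Dict:
    """Tree share of the total C stock per field moisture class.

    ``pools`` needs ``moisture_class``, ``tree_total`` and ``total_soc``
    columns. Returns per-class mean/median tree shares (percent) and the
    overall fraction of plots whose soil share exceeds 50 %.
    """
    df = pools.copy()
    grand = df["tree_total"] + df["total_soc"]
    share = np.where(grand > 0, 100.0 * df["tree_total"] / grand, 0.0)
    df["tree_share"] = share
    by_class = {
        int(cls): {
            "n": int(len(grp)),
            "mean_tree_share": float(grp["tree_share"].mean()),
            "median_tree_share": float(grp["tree_share"].median()),
        }
        for cls, grp in df.groupby("moisture_class")
    }
    soil_majority = float(np.mean(share < 50.0) * 100.0)
    return {"by_class": by_class, "soil_majority_pct": soil_majority}
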