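"""Soil organic carbon accounting: organic-layer, mineral-soil and total SOC
stocks per plot.

The accounting follows fixed-depth forest-soil-inventory practice:

* organic-layer stock from volumetric cores (C concentration x dry mass /
  sampled area), extrapolated by constant density below 30 cm on peat plots
  and capped at 1 m below the organic surface;
* mineral-layer stocks ``(c/100) * rho_b * thickness * (100 - stone_vol)/100``
  with the pedotransfer bulk density
  ``rho_b = 1.5463 * exp(-0.3130 * sqrt(c)) + 0.0027 * depth``;
* stoniness from the 12-point penetration-rod index through a linear clamped
  transfer;
* mineral soil accounted over 0-50 cm, with the 55-65 cm sample standing in
  for 20-50 cm (weight 3), truncated pro rata where a thick organic layer
  displaces the mineral column.

Stocks are returned in Mg C ha^-1. The g cm^-2 -> Mg ha^-1 factor (x100) is
applied exactly once, in the two stock constructors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError, InvalidStateError, MissingDataError
from .records import (
    DEPTH_CAP_CM,
    MINERAL_ACCOUNT_DEPTH_CM,
    MINERAL_SAMPLED_LAYERS,
    PEAT_THICKNESS_CM,
    CarbonPools,
    SoilProfileRecord,
)

#: g cm^-2 -> Mg ha^-1
GCM2_TO_MGHA = 100.0


@dataclass(frozen=True)
class StoninessTransfer:
    """Linear clamped transfer from mean penetration depth (cm) to stone
    volume percent: ``v = clip(a - b * mean_depth, 0, 100)``.

    The default constants follow the published Swedish penetration-rod
    calibration; both are configuration-exposed.
    """

    a: float = 44.3
    b: float = 1.44

    def __call__(self, mean_depth: float) -> float:
        return float(np.clip(self.a - self.b * mean_depth, 0.0, 100.0))


DEFAULT_STONINESS = StoninessTransfer()


def bulk_density(carbon_conc: float, depth: float) -> float:
    """Pedotransfer bulk density of mineral soil, g cm^-3.

    Parameters
    ----------
    carbon_conc : mass % C of the fine fraction.
    depth : representative depth of the layer, cm.
    """
    if carbon_conc < 0 or depth < 0:
        raise InvalidArgumentError("carbon concentration and depth must be >= 0")
    return 1.5463 * math.exp(-0.3130 * math.sqrt(carbon_conc)) + 0.0027 * depth


def stone_volume(
    penetration_depths: Sequence[float], transfer: StoninessTransfer = DEFAULT_STONINESS
) -> float:
    """Stone and boulder volume percent from the 12 rod penetration depths."""
    depths = np.asarray(penetration_depths, dtype=float)
    if depths.size == 0:
        raise InvalidArgumentError("at least one penetration depth is required")
    if np.any(depths < 0) or np.any(depths > 30):
        raise InvalidArgumentError("penetration depths must lie in [0, 30] cm")
    return transfer(float(depths.mean()))


def mineral_layer_stock(
    c_conc: float, bulk_density: float, thickness: float, stone_vol: float
) -> float:
    """Carbon stock of one mineral layer, Mg C ha^-1."""
    if min(c_conc, bulk_density, thickness, stone_vol) < 0:
        raise InvalidArgumentError("all inputs must be >= 0")
    if stone_vol > 100:
        raise InvalidArgumentError(f"stone volume {stone_vol} % exceeds 100 %")
    g_cm2 = (c_conc / 100.0) * bulk_density * thickness * (100.0 - stone_vol) / 100.0
    return g_cm2 * GCM2_TO_MGHA


def organic_layer_stock(core_dry_mass: float, c_conc: float, sampled_area: float) -> float:
    """Organic-layer stock from the pooled volumetric cores, Mg C ha^-1."""
    if sampled_area <= 0:
        raise InvalidArgumentError("sampled area must be positive")
    if core_dry_mass < 0 or not 0 <= c_conc <= 100:
        raise InvalidArgumentError("invalid core mass or C concentration")
    g_cm2 = (c_conc / 100.0) * core_dry_mass / sampled_area
    return g_cm2 * GCM2_TO_MGHA


def peat_extrapolated_stock(profile: SoilProfileRecord) -> float:
    """Organic stock of a peat plot: the measured 0-30 cm core density
    extrapolated by constant density to the full organic thickness, capped at
    1 m below the organic surface."""
    if not profile.is_peat:
        raise InvalidStateError(
            f"plot {profile.plot_id}: peat extrapolation requires organic thickness > "
            f"{PEAT_THICKNESS_CM:g} cm"
        )
    core = organic_layer_stock(
        profile.organic_core_dry_mass,
        profile.organic_core_c_conc,
        profile.organic_sampled_area,
    )
    depth = min(profile.organic_thickness, DEPTH_CAP_CM)
    return core * depth / PEAT_THICKNESS_CM


def organic_profile_stock(profile: SoilProfileRecord) -> float:
    """Organic-layer stock for any profile (core stock, or the peat
    extrapolation when the 30 cm threshold is exceeded)."""
    if profile.is_peat:
        return peat_extrapolated_stock(profile)
    return organic_layer_stock(
        profile.organic_core_dry_mass,
        profile.organic_core_c_conc,
        profile.organic_sampled_area,
    )


def _layer_overlap(top: float, bottom: float, limit: float) -> float:
    """Fraction of layer [top, bottom) lying above the truncation limit."""
    if limit <= top:
        return 0.0
    return (min(bottom, limit) - top) / (bottom - top)


def mineral_profile_stock(
    profile: SoilProfileRecord,
    transfer: StoninessTransfer = DEFAULT_STONINESS,
    deep_layer_weight: float = 3.0,
    account_depth: float = MINERAL_ACCOUNT_DEPTH_CM,
) -> float:
    """Mineral-soil carbon stock over the accounted column, Mg C ha^-1.

    The sampled 0-10 and 10-20 cm layers enter directly; the 55-65 cm sample
    stands in for the unsampled 20-50 cm interval with weight
    ``deep_layer_weight`` (default 3, i.e. three 10 cm layers). The accounted
    column is ``min(account_depth, max(0, 100 - organic_thickness))`` so that
    deep organic layers displace mineral soil, truncating the deepest
    interval pro rata.
    """
    layers = {(t, b): c for t, b, c in profile.mineral_layers}
    missing = [lay for lay in MINERAL_SAMPLED_LAYERS if lay not in layers]
    if missing:
        raise MissingDataError(
            f"plot {profile.plot_id}: missing mineral layer(s) {missing}",
            plot_id=profile.plot_id,
        )
    available = max(0.0, DEPTH_CAP_CM - profile.organic_thickness)
    limit = min(account_depth, available)
    if limit <= 0:
        return 0.0
    sv = stone_volume(profile.penetration_depths, transfer)

    def layer(top, bottom, c):
        mid = 0.5 * (top + bottom)
        return mineral_layer_stock(c, bulk_density(c, mid), bottom - top, sv)

    s1 = layer(0.0, 10.0, layers[(0.0, 10.0)])
    s2 = layer(10.0, 20.0, layers[(10.0, 20.0)])
    s3 = layer(55.0, 65.0, layers[(55.0, 65.0)])
    # accounted intervals: [0,10], [10,20], and 20-(20+10*weight) as copies
    # of the deep sample; each truncated by its overlap with [0, limit]
    f1 = _layer_overlap(0.0, 10.0, limit)
    f2 = _layer_overlap(10.0, 20.0, limit)
    deep_bottom = 20.0 + 10.0 * deep_layer_weight
    f3 = _layer_overlap(20.0, deep_bottom, limit)
    return s1 * f1 + s2 * f2 + deep_layer_weight * s3 * f3


def total_soc(
    profile: SoilProfileRecord,
    transfer: StoninessTransfer = DEFAULT_STONINESS,
    deep_layer_weight: float = 3.0,
    account_depth: float = MINERAL_ACCOUNT_DEPTH_CM,
) -> CarbonPools:
    """Full soil accounting for one profile: organic + mineral pools."""
    organic = organic_profile_stock(profile)
    mineral = mineral_profile_stock(
        profile, transfer=transfer, deep_layer_weight=deep_layer_weight, account_depth=account_depth
    )
    return CarbonPools(
        plot_id=profile.plot_id, organic=organic, mineral=mineral, is_peat=profile.is_peat
    )
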