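"""Tree carbon accounting: height imputation, allometric stem biomass and
per-plot aggregation.

Aboveground biomass is the sum of log-linear component equations
``ln(m_kg) = b0 + b1 ln(DBH_cm) + b2 ln(h_m)`` over stump, stem, bark, living
branches, dead branches and foliage; belowground biomass uses a DBH-only
equation ``ln(m_kg) = b0 + b1 ln(DBH_cm)``. The shipped default coefficient
table is a synthetic stand-in of that standard national-equation form (the
national coefficient sets are not redistributed here), tuned so stem-level
magnitudes and the ~24 % belowground share are realistic for boreal pine /
spruce / birch stands. Lodgepole pine resolves to the pine equations and
other deciduous species to the birch equations.

Plot stocks assume a 50 % carbon fraction of dry biomass and are expressed
in Mg C ha^-1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidArgumentError, InvalidStateError
from .records import CarbonPools, TreeRecord

ABOVE_COMPONENTS = ("stump", "stem", "bark", "branches_living", "branches_dead", "foliage")

#: species aliases: every recorded label resolves to an equation set
SPECIES_ALIASES = {"contorta": "pine", "other-deciduous": "birch"}

_DEFAULT_COEFFS = {
    "pine": {
        "stump": (-3.8, 2.1, 0.0),
        "stem": (-2.9, 1.9, 0.9),
        "bark": (-4.0, 1.9, 0.3),
        "branches_living": (-3.0, 2.4, -0.3),
        "branches_dead": (-5.0, 2.0, 0.2),
        "foliage": (-3.5, 1.9, -0.4),
        "belowground": (-2.2, 2.2),
    },
    "spruce": {
        "stump": (-3.6, 2.05, 0.0),
        "stem": (-2.8, 1.75, 1.0),
        "bark": (-3.8, 1.9, 0.3),
        "branches_living": (-2.7, 2.3, -0.3),
        "branches_dead": (-4.8, 2.0, 0.2),
        "foliage": (-2.6, 1.9, -0.4),
        "belowground": (-2.2, 2.15),
    },
    "birch": {
        "stump": (-3.9, 2.1, 0.0),
        "stem": (-3.0, 1.85, 1.0),
        "bark": (-4.1, 2.0, 0.3),
        "branches_living": (-3.2, 2.35, -0.3),
        "branches_dead": (-5.1, 2.0, 0.2),
        "foliage": (-3.9, 1.8, -0.3),
        "belowground": (-2.1, 2.15),
    },
}


@dataclass
class AllometryTable:
    """Per-species, per-component coefficients of the log-linear form."""

    coefficients: Dict[str, Dict[str, tuple]] = field(
        default_factory=lambda: {sp: dict(comps) for sp, comps in _DEFAULT_COEFFS.items()}
    )
    aliases: Dict[str, str] = field(default_factory=lambda: dict(SPECIES_ALIASES))

    def resolve(self, species: str) -> str:
        sp = self.aliases.get(species, species)
        if sp not in self.coefficients:
            raise InvalidArgumentError(f"unknown species label {species!r}")
        return sp

    @classmethod
    def from_dict(cls, data: dict) -> "AllometryTable":
        coeffs = {
            sp: {comp: tuple(v) for comp, v in comps.items()}
            for sp, comps in data.get("coefficients", data).items()
        }
        aliases = dict(data.get("aliases", SPECIES_ALIASES))
        return cls(coefficients=coeffs, aliases=aliases)

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                sp: {comp: list(v) for comp, v in comps.items()}
                for sp, comps in self.coefficients.items()
            },
            "aliases": dict(self.aliases),
        }


DEFAULT_ALLOMETRY = AllometryTable()


def tree_biomass(tree: TreeRecord, table: AllometryTable = DEFAULT_ALLOMETRY) -> Tuple[float, float]:
    """(aboveground, belowground) dry biomass of one stem, kg."""
    if tree.height is None:
        raise InvalidArgumentError(
            f"plot {tree.plot_id}: tree height missing; run impute_heights first"
        )
    comps = table.coefficients[table.resolve(tree.species)]
    ld, lh = math.log(tree.dbh), math.log(tree.height)
    above = 0.0
    for name in ABOVE_COMPONENTS:
        b0, b1, b2 = comps[name]
        above += math.exp(b0 + b1 * ld + b2 * lh)
    b0, b1 = comps["belowground"]
    below = math.exp(b0 + b1 * ld)
    return above, below


def plot_tree_carbon(
    trees: Sequence[TreeRecord],
    plot_radius: float,
    table: AllometryTable = DEFAULT_ALLOMETRY,
    c_fraction: float = 0.5,
    plot_id: str = "",
) -> CarbonPools:
    """Aggregate stem biomasses to per-plot tree carbon stocks, Mg C ha^-1.

    An empty tree list is valid (clear-cuts exist) and yields zero pools.
    """
    if plot_radius <= 0:
        raise InvalidArgumentError("plot radius must be positive")
    if trees and not plot_id:
        plot_id = trees[0].plot_id
    per_ha = 10_000.0 / (math.pi * plot_radius**2)
    above_kg = below_kg = 0.0
    for tree in trees:
        a, b = tree_biomass(tree, table)
        above_kg += a
        below_kg += b
    # kg dry mass -> Mg C, then per hectare
    return CarbonPools(
        plot_id=plot_id,
        tree_above=above_kg * c_fraction * 1e-3 * per_ha,
        tree_below=below_kg * c_fraction * 1e-3 * per_ha,
    )


@dataclass(frozen=True)
class HeightCurve:
    """Two-parameter height-diameter curve ``h = 1.3 + (d / (a + b d))^2``."""

    a: float
    b: float

    def __call__(self, dbh) -> np.ndarray:
        d = np.asarray(dbh, dtype=float)
        return 1.3 + (d / (self.a + self.b * d)) ** 2


def fit_height_curve(dbh: Sequence[float], height: Sequence[float]) -> HeightCurve:
    """Least-squares fit of the height-diameter curve.

    The curve linearises as ``d / sqrt(h - 1.3) = a + b d``, so the fit is an
    ordinary regression of that transform on DBH; for data lying exactly on a
    curve the parameters are recovered exactly.
    """
    d = np.asarray(dbh, dtype=float)
    h = np.asarray(height, dtype=float)
    if d.size < 2:
        raise InvalidArgumentError("height-curve fit needs at least two measured trees")
    if np.any(h <= 1.3):
        raise InvalidArgumentError("measured heights must exceed 1.3 m")
    y = d / np.sqrt(h - 1.3)
    X = np.column_stack([np.ones_like(d), d])
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    if a + b * d.min() <= 0:
        raise InvalidStateError("degenerate height-diameter fit")
    return HeightCurve(float(a), float(b))


def impute_heights(
    trees: Sequence[TreeRecord],
    min_species_sample: int = 3,
    calibration_bounds: Tuple[float, float] = (0.3, 3.0),
) -> List[TreeRecord]:
    """Fill unmeasured heights from species-level height-diameter curves with
    a per-plot multiplicative calibration.

    A curve is fitted per species over all measured stems in the survey
    (falling back to a pooled curve when a species has fewer than
    ``min_species_sample`` measurements). Within each plot, the ratio of
    measured ``h - 1.3`` to the curve prediction rescales the curve, so plots
    with taller-than-typical trees impute taller heights. Measured heights
    are never altered; imputed heights always exceed 1.3 m.
    """
    measured = [t for t in trees if t.height_measured and t.height is not None]
    if any(t.height is None and not t.height_measured for t in trees) and not measured:
        raise InvalidStateError("no measured heights available for imputation")

    pooled = None
    if measured:
        pooled = fit_height_curve([t.dbh for t in measured], [t.height for t in measured])
    curves: Dict[str, HeightCurve] = {}
    by_species: Dict[str, list] = {}
    for t in measured:
        by_species.setdefault(t.species, []).append(t)
    for sp, group in by_species.items():
        if len(group) >= min_species_sample:
            curves[sp] = fit_height_curve([t.dbh for t in group], [t.height for t in group])
        else:
            curves[sp] = pooled

    # plot-level multiplicative calibration on (h - 1.3)
    plot_factor: Dict[str, float] = {}
    by_plot: Dict[str, list] = {}
    for t in measured:
        by_plot.setdefault(t.plot_id, []).append(t)
    for pid, group in by_plot.items():
        obs = sum(t.height - 1.3 for t in group)
        pred = sum(float(curves[t.species](t.dbh)) - 1.3 for t in group)
        if pred > 0:
            lo, hi = calibration_bounds
            plot_factor[pid] = float(np.clip(obs / pred, lo, hi))

    out: List[TreeRecord] = []
    for t in trees:
        if t.height is not None:
            out.append(t)
            continue
        curve = curves.get(t.species, pooled)
        kappa = plot_factor.get(t.plot_id, 1.0)
        h = 1.3 + kappa * (float(curve(t.dbh)) - 1.3)
        out.append(TreeRecord(t.plot_id, t.species, t.dbh, height=max(h, 1.3 + 1e-9)))
    return out
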