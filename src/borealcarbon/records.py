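"""Core record types of the survey: plots, soil profiles, trees, carbon pools.

All carbon stocks are expressed in Mg C ha^-1 throughout the package; the
single g cm^-2 -> Mg ha^-1 conversion (factor 100) lives in the two stock
constructors in :mod:`borealcarbon.soil`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import InvalidArgumentError

#: Organic layers thicker than this (cm) classify the profile as peat.
PEAT_THICKNESS_CM = 30.0
#: Accounting never extends deeper than this below the organic-layer surface.
DEPTH_CAP_CM = 100.0
#: Mineral soil is accounted down to this depth below the mineral surface.
MINERAL_ACCOUNT_DEPTH_CM = 50.0

#: Mineral sampling scheme: fixed intervals (top, bottom) in cm.
MINERAL_SAMPLED_LAYERS = ((0.0, 10.0), (10.0, 20.0), (55.0, 65.0))


@dataclass(frozen=True)
class PlotSurvey:
    """One surveyed plot: position, geometry and field classifications."""

    plot_id: str
    x: float
    y: float
    radius: float = 10.0  # m; 5 m in dense regenerating stands
    moisture_class: Optional[int] = None  # 1 dry .. 5 wet
    stand_age: Optional[float] = None  # years
    wetness: Optional[float] = None  # modelled probability of wetness, 0-1

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidArgumentError(f"plot radius must be positive, got {self.radius}")
        if self.moisture_class is not None and self.moisture_class not in (1, 2, 3, 4, 5):
            raise InvalidArgumentError(f"moisture class must be 1..5, got {self.moisture_class}")

    @property
    def area_m2(self) -> float:
        import math

        return math.pi * self.radius**2


@dataclass
class SoilProfileRecord:
    """Soil measurements for one plot.

    ``organic_*`` fields describe the volumetric O-horizon cores (pooled over
    the subplot sampling points); ``mineral_layers`` holds the fixed-interval
    samples; ``penetration_depths`` are the 12 stoniness-rod readings.
    """

    plot_id: str
    organic_thickness: float  # cm, full O-horizon depth
    organic_core_dry_mass: float  # g, pooled dry mass of the 0-30 cm cores
    organic_core_c_conc: float  # mass % of the dry fine fraction
    organic_sampled_area: float  # cm^2, total core footprint
    mineral_layers: Sequence[tuple]  # (top cm, bottom cm, c_conc %)
    penetration_depths: Sequence[float] = field(default_factory=tuple)  # cm, 12 values

    def __post_init__(self):
        if self.organic_thickness < 0:
            raise InvalidArgumentError(
                f"plot {self.plot_id}: organic thickness must be >= 0"
            )
        if not 0.0 <= self.organic_core_c_conc <= 100.0:
            raise InvalidArgumentError(
                f"plot {self.plot_id}: organic C concentration outside [0, 100] %"
            )
        for top, bottom, c in self.mineral_layers:
            if top >= bottom:
                raise InvalidArgumentError(
                    f"plot {self.plot_id}: mineral layer top {top} >= bottom {bottom}"
                )
            if not 0.0 <= c <= 100.0:
                raise InvalidArgumentError(
                    f"plot {self.plot_id}: mineral C concentration outside [0, 100] %"
                )
        for p in self.penetration_depths:
            if not 0.0 <= p <= 30.0:
                raise InvalidArgumentError(
                    f"plot {self.plot_id}: penetration depth {p} outside [0, 30] cm"
                )

    @property
    def is_peat(self) -> bool:
        """True when the organic layer exceeds the 30 cm peat threshold."""
        return self.organic_thickness > PEAT_THICKNESS_CM


@dataclass(frozen=True)
class TreeRecord:
    """One stem: species label, DBH and (possibly imputed) height."""

    plot_id: str
    species: str  # pine | spruce | birch | contorta | other-deciduous
    dbh: float  # cm, diameter at breast height (1.3 m)
    height: Optional[float] = None  # m
    height_measured: bool = False

    def __post_init__(self):
        if self.dbh <= 0:
            raise InvalidArgumentError(f"plot {self.plot_id}: DBH must be positive")
        if self.height is not None and self.height <= 1.3:
            raise InvalidArgumentError(
                f"plot {self.plot_id}: tree height must exceed breast height (1.3 m)"
            )


@dataclass
class CarbonPools:
    """Per-plot carbon stocks, Mg C ha^-1."""

    plot_id: str = ""
    organic: float = 0.0
    mineral: float = 0.0
    tree_above: float = 0.0
    tree_below: float = 0.0
    is_peat: bool = False

    @property
    def total_soc(self) -> float:
        return self.organic + self.mineral

    @property
    def tree_total(self) -> float:
        return self.tree_above + self.tree_below

    @property
    def grand_total(self) -> float:
        return self.total_soc + self.tree_total
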