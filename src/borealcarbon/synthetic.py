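"""Synthetic catchment survey generator.

The generator emits a self-consistent survey with the statistical structure
the downstream accounting and modelling assume:

* a spatially autocorrelated wetness-probability raster (smoothed Gaussian
  field squashed through a Beta quantile transform to [0, 1], concentrated
  at low wetness where the raw-basis log-quadratic stock curve is sane);
* per-plot soil profiles whose accounted total SOC sits, by construction,
  exactly on ``exp(b0 + b1 x + b2 x^2 + eps)`` — the organic core mass and
  the top mineral C concentration are solved *through the actual accounting
  pipeline*, so with all residual sds at zero the generating curve is
  recovered to numerical precision by refitting;
* tree lists whose plot carbon (through the same allometry table) follows a
  quadratic in wetness, unimodal at intermediate wetness, scaled by stand
  age and calibrated exactly via a DBH scale factor;
* per-cell ALS point heights: a ground/canopy return mixture whose canopy
  fraction grows with stand density.

All randomness flows from a single seed through named substreams, so any
generated catchment is bit-reproducible from (config, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special
from scipy.ndimage import gaussian_filter

from .config import GeneratorConfig
from .errors import InvalidArgumentError
from .rasters import RasterGrid
from .records import PlotSurvey, SoilProfileRecord, TreeRecord
from .soil import mineral_profile_stock, total_soc
from .trees import AllometryTable, DEFAULT_ALLOMETRY, HeightCurve, plot_tree_carbon

# fixed organic-core sampling constants (three 10 cm diameter cores)
ORGANIC_CORE_AREA_CM2 = 3 * math.pi * 5.0**2
ORGANIC_C_CONC = 45.0  # mass %
MINERAL_DECAY = (1.0, 0.6, 0.25)  # C concentration ratios of the three layers
MAX_MINERAL_CONC = 30.0  # mass %, upper bound when inverting the mineral stock

#: Naslund height-curve parameters per species (a, b)
HEIGHT_CURVES = {
    "pine": HeightCurve(1.1, 0.22),
    "spruce": HeightCurve(1.3, 0.20),
    "birch": HeightCurve(1.4, 0.24),
}
SPECIES = ("pine", "spruce", "birch")

# substream labels so each module draws from an independent stream
_STREAMS = {"wetness": 1, "soil": 2, "trees": 3, "als": 4, "age": 5}


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream], index)))


# ---------------------------------------------------------------------------
# wetness surface


def generate_wetness_surface(
    extent: Tuple[int, int],
    cell_size: float,
    correlation_length: float,
    seed: int,
    beta_params: Tuple[float, float] = (1.0, 14.0),
    origin: Optional[Tuple[float, float]] = None,
) -> RasterGrid:
    """Spatially autocorrelated wetness-probability field on [0, 1].

    An iid Gaussian grid is smoothed with a Gaussian kernel of scale
    ``correlation_length`` (circular boundary), standardized, and squashed
    through the Beta(a, b) quantile transform — a monotone map, so spatial
    rank structure is preserved. Identical (seed, parameters) give a bitwise
    identical raster.
    """
    nrows, ncols = int(extent[0]), int(extent[1])
    if nrows <= 0 or ncols <= 0:
        raise InvalidArgumentError("raster extent must be positive")
    if correlation_length <= 0:
        raise InvalidArgumentError("correlation length must be positive")
    rng = _rng(seed, "wetness")
    z = rng.standard_normal((nrows, ncols))
    sigma = correlation_length / cell_size
    if sigma >= 0.05:
        z = gaussian_filter(z, sigma=sigma, mode="wrap")
    z = (z - z.mean()) / z.std()
    a, b = beta_params
    w = special.betaincinv(a, b, special.ndtr(z))
    w = np.clip(w, 0.0, 1.0)
    if origin is None:
        origin = (0.0, nrows * cell_size)
    return RasterGrid(values=w, origin=origin, cell_size=cell_size, nodata=-9999.0)


def sample_wetness(
    n: int, seed: int, beta_params: Tuple[float, float] = (1.0, 14.0)
) -> np.ndarray:
    """Direct draws from the wetness marginal (the Beta squashing target);
    the fast path for fitting studies that need no raster."""
    rng = _rng(seed, "wetness", 1)
    a, b = beta_params
    return rng.beta(a, b, size=n)


# ---------------------------------------------------------------------------
# field moisture classes


def quantile_thresholds(
    wetness: Sequence[float], props: Sequence[float] = (0.07, 0.73, 0.11, 0.07, 0.02)
) -> np.ndarray:
    """Empirical wetness quantiles at the cumulative class proportions, so
    that classifying by them reproduces the configured class frequencies."""
    props = np.asarray(props, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError("class proportions must sum to 1")
    cum = np.cumsum(props)[:-1]
    return np.quantile(np.asarray(wetness, dtype=float), cum)


def assign_moisture_class(wetness, thresholds) -> np.ndarray:
    """Field moisture class 1 (dry) .. 5 (wet).

    The class is the index of the first threshold strictly exceeding the
    wetness value; 5 when none does.
    """
    w = np.asarray(wetness, dtype=float)
    scalar = w.ndim == 0
    w = np.atleast_1d(w)
    if np.any((w < 0) | (w > 1)):
        raise InvalidArgumentError("wetness must lie in [0, 1]")
    t = np.asarray(thresholds, dtype=float)
    if t.size != 4 or np.any(np.diff(t) < 0) or t[0] <= 0 or t[-1] >= 1:
        raise InvalidArgumentError("thresholds must be 4 ascending cut points in (0, 1)")
    cls = 1 + np.searchsorted(t, w, side="right")
    cls = np.minimum(cls, 5).astype(int)
    return int(cls[0]) if scalar else cls


# ---------------------------------------------------------------------------
# soil profiles


def peat_wetness_threshold(config: GeneratorConfig) -> float:
    """Wetness above which the deterministic thickness crosses 30 cm; set at
    the marginal (1 - peat fraction) quantile so P(peat) hits the target."""
    a, b = config.wetness_beta
    return float(special.betaincinv(a, b, 1.0 - config.peat_target_fraction))


def _thickness_deterministic(w: float, config: GeneratorConfig) -> float:
    wp = peat_wetness_threshold(config)
    t_dry = config.thickness_dry_cm
    if w <= wp:
        return t_dry + (30.0 - t_dry) * (w / wp) ** 1.5
    return 30.0 + 170.0 * ((w - wp) / (1.0 - wp)) ** 1.2


def generate_soil_profile(
    wetness: float,
    seed: int,
    config: Optional[GeneratorConfig] = None,
    plot_id: str = "p0",
    rng: Optional[np.random.Generator] = None,
) -> SoilProfileRecord:
    """One plot's soil profile, consistent with the generating SOC curve.

    The organic-layer thickness grows with wetness and crosses the 30 cm
    peat threshold at the marginal quantile matching the configured peat
    fraction. The total accounted SOC (organic + mineral through
    :mod:`borealcarbon.soil`) equals ``exp(soc_curve(wetness) + eps)``
    exactly: the mineral stock is realized by root-solving the top-layer C
    concentration through the accounting, and the organic core mass absorbs
    the remainder in closed form.
    """
    if not 0.0 <= wetness <= 1.0:
        raise InvalidArgumentError("wetness must lie in [0, 1]")
    config = (config or GeneratorConfig()).validate()
    if rng is None:
        rng = _rng(seed, "soil")

    # organic thickness: deterministic curve with multiplicative lognormal noise
    t_det = _thickness_deterministic(wetness, config)
    if config.thickness_log_sd > 0:
        t_det *= math.exp(config.thickness_log_sd * rng.standard_normal())
    thickness = float(min(t_det, 250.0))

    # penetration depths (stoniness) are wetness-independent survey noise
    depths = np.clip(30.0 * rng.beta(4.0, 1.2, size=12), 0.0, 30.0)

    # generating total SOC
    b0, b1, b2 = config.soc_curve
    eps = config.soc_log_sd * rng.standard_normal() if config.soc_log_sd > 0 else 0.0
    target_total = math.exp(b0 + b1 * wetness + b2 * wetness**2 + eps)

    # organic share of the target, forced to 1 when the organic column
    # displaces all accountable mineral soil
    share = 0.35 + 0.60 * (1.0 - math.exp(-5.0 * wetness))
    if thickness >= 100.0:
        share = 1.0
    target_mineral = (1.0 - share) * target_total

    def profile_with(c1: float) -> SoilProfileRecord:
        layers = [
            (0.0, 10.0, c1 * MINERAL_DECAY[0]),
            (10.0, 20.0, c1 * MINERAL_DECAY[1]),
            (55.0, 65.0, c1 * MINERAL_DECAY[2]),
        ]
        return SoilProfileRecord(
            plot_id=plot_id,
            organic_thickness=thickness,
            organic_core_dry_mass=1.0,
            organic_core_c_conc=ORGANIC_C_CONC,
            organic_sampled_area=ORGANIC_CORE_AREA_CM2,
            mineral_layers=layers,
            penetration_depths=tuple(depths),
        )

    def mineral_at(c1: float) -> float:
        return mineral_profile_stock(profile_with(c1))

    upper = mineral_at(MAX_MINERAL_CONC)
    if target_mineral <= 0 or upper <= 0:
        c1 = 0.0
        realized_mineral = mineral_at(0.0)
    elif target_mineral >= upper:
        c1 = MAX_MINERAL_CONC
        realized_mineral = upper
    else:
        c1 = optimize.brentq(
            lambda c: mineral_at(c) - target_mineral, 0.0, MAX_MINERAL_CONC, xtol=1e-12
        )
        realized_mineral = mineral_at(c1)

    # organic pool absorbs the remainder so the accounted total is exact
    target_organic = target_total - realized_mineral
    core_stock = target_organic
    if thickness > 30.0:
        core_stock = target_organic * 30.0 / min(thickness, 100.0)
    dry_mass = core_stock * ORGANIC_CORE_AREA_CM2 / ORGANIC_C_CONC

    prof = profile_with(c1)
    prof.organic_core_dry_mass = dry_mass
    return prof


# ---------------------------------------------------------------------------
# tree lists


def _age_factor(stand_age: float) -> float:
    return min(stand_age / 80.0, 1.0)


def _plot_carbon_of(dbhs, species, plot_radius, allometry) -> float:
    trees = [
        TreeRecord("tmp", sp, d, height=float(HEIGHT_CURVES[sp](d)))
        for d, sp in zip(dbhs, species)
    ]
    return plot_tree_carbon(trees, plot_radius, allometry).tree_total


def generate_tree_list(
    wetness: float,
    stand_age: float,
    plot_radius: float = 10.0,
    seed: int = 0,
    config: Optional[GeneratorConfig] = None,
    allometry: AllometryTable = DEFAULT_ALLOMETRY,
    plot_id: str = "p0",
    rng: Optional[np.random.Generator] = None,
) -> List[TreeRecord]:
    """Tree list whose plot carbon follows the configured quadratic.

    Stem count and DBH scale with stand age; heights sit on species
    height-diameter curves. After drawing stems, a single DBH scale factor
    is root-solved through the allometric aggregation so the plot's tree C
    equals the target ``max(0, tree_curve(wetness)) * min(age/80, 1) + eps``
    exactly. At least three stems per present species are flagged as
    height-measured (with optional measurement noise); recorded stems always
    have DBH > 4 cm.
    """
    if stand_age < 0:
        raise InvalidArgumentError("stand age must be >= 0")
    config = (config or GeneratorConfig()).validate()
    if rng is None:
        rng = _rng(seed, "trees")
    a0, a1, a2 = config.tree_curve
    target = max(0.0, a0 + a1 * wetness + a2 * wetness**2) * _age_factor(stand_age)
    if config.tree_sd > 0:
        target = max(0.0, target + config.tree_sd * rng.standard_normal())
    if stand_age <= 0 or target < 0.5:
        return []

    mean_dbh = 6.0 + 0.15 * min(stand_age, 120.0)
    shape = 1.0 / 0.35**2  # gamma with cv 0.35
    probe = _plot_carbon_of([mean_dbh], ["pine"], plot_radius, allometry)
    n_guess = max(1, int(round(target / probe)))

    def draw_stems(n):
        d = np.maximum(rng.gamma(shape, mean_dbh / shape, size=n), 4.05)
        sp = rng.choice(SPECIES, size=n, p=config.species_probs)
        return list(d), list(sp)

    dbhs, species = draw_stems(rng.poisson(n_guess) + 1)

    def carbon(gamma: float) -> float:
        scaled = [max(4.05, gamma * d) for d in dbhs]
        return _plot_carbon_of(scaled, species, plot_radius, allometry)

    lo, hi = 0.25, 4.0
    # grow / shrink the stem list until the target is bracketed
    for _ in range(200):
        if carbon(hi) < target:
            d, sp = draw_stems(max(1, len(dbhs) // 2))
            dbhs += d
            species += sp
        elif carbon(lo) > target and len(dbhs) > 1:
            dbhs.pop()
            species.pop()
        else:
            break
    if carbon(lo) >= target:
        gamma = lo  # tiny target, single minimal stem: accept overshoot
    elif carbon(hi) <= target:
        gamma = hi
    else:
        gamma = optimize.brentq(lambda g: carbon(g) - target, lo, hi, xtol=1e-13)

    dbhs = [max(4.05, gamma * d) for d in dbhs]
    order = np.argsort(dbhs)[::-1]  # measure the dominant stems first
    measured: Dict[str, int] = {sp: 0 for sp in SPECIES}
    records: List[Optional[TreeRecord]] = [None] * len(dbhs)
    for i in order:
        sp, d = species[i], dbhs[i]
        h_true = float(HEIGHT_CURVES[sp](d))
        if measured[sp] < 3:
            measured[sp] += 1
            h_obs = h_true
            if config.height_noise_sd > 0:
                h_obs = max(1.35, h_true + config.height_noise_sd * rng.standard_normal())
            records[i] = TreeRecord(plot_id, sp, d, height=h_obs, height_measured=True)
        else:
            records[i] = TreeRecord(plot_id, sp, d, height=h_true, height_measured=False)
    return [r for r in records if r is not None]


# ---------------------------------------------------------------------------
# ALS returns


def generate_als_points(
    trees: Sequence[TreeRecord],
    cell_area_m2: float = 156.25,
    density: float = 20.0,
    seed: int = 0,
    stand_area_m2: float = math.pi * 10.0**2,
    canopy_height_shift: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Normalized above-ground return heights for one 12.5 m cell.

    The return count is Poisson(density x area). Returns are a mixture of
    ground hits (height 0) and canopy hits: the canopy fraction is the
    stand's crown cover ``1 - exp(-sum(crown areas)/stand area)``, so denser
    stands reflect more returns; canopy heights are drawn per crown below
    the tree top. ``canopy_height_shift`` displaces canopy returns (used to
    emulate field/canopy georeferencing mismatch)."""
    if density <= 0:
        raise InvalidArgumentError("point density must be positive")
    if rng is None:
        rng = _rng(seed, "als")
    n = int(rng.poisson(density * cell_area_m2))
    if n == 0:
        return np.empty(0)
    trees = [t for t in trees if t.height is not None]
    if not trees:
        return np.zeros(n)
    crown_r = np.array([0.6 + 0.06 * t.dbh for t in trees])
    crown_area = math.pi * crown_r**2
    heights = np.array([t.height for t in trees])
    cover = 1.0 - math.exp(-crown_area.sum() / stand_area_m2)
    canopy = rng.random(n) < cover
    out = np.zeros(n)
    k = int(canopy.sum())
    if k:
        pick = rng.choice(len(trees), size=k, p=crown_area / crown_area.sum())
        depth = rng.beta(1.2, 3.0, size=k)  # relative depth into the crown
        h = heights[pick] * (1.0 - 0.3 * depth) + canopy_height_shift
        out[canopy] = np.maximum(h, 0.0)
    return out


# ---------------------------------------------------------------------------
# whole catchment


@dataclass
class SyntheticCatchment:
    """A generated survey: plots, profiles, trees, wetness raster and per-cell
    ALS returns, plus the generating configuration ("truth")."""

    plots: List[PlotSurvey]
    profiles: List[SoilProfileRecord]
    trees: List[TreeRecord]
    wetness: RasterGrid
    als_points: Dict[str, np.ndarray]
    class_thresholds: np.ndarray
    truth: GeneratorConfig

    def trees_of(self, plot_id: str) -> List[TreeRecord]:
        return [t for t in self.trees if t.plot_id == plot_id]


def _stand_ages(n: int, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.stand_age_range
    uniform_mean = 0.5 * (lo + hi)
    young_mean = 64.0
    lam = (config.stand_age_mean - young_mean) / (uniform_mean - young_mean)
    lam = float(np.clip(lam, 0.0, 1.0))
    use_uniform = rng.random(n) < lam
    ages = np.where(
        use_uniform,
        rng.uniform(lo, hi, size=n),
        np.clip(rng.gamma(4.0, young_mean / 4.0, size=n), lo, hi),
    )
    return ages


def generate_catchment(
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
    allometry: AllometryTable = DEFAULT_ALLOMETRY,
) -> SyntheticCatchment:
    """Generate the full synthetic survey from (config, seed)."""
    config = (config or GeneratorConfig()).validate()
    if seed is None:
        seed = config.seed

    ncols_p = int(math.ceil(math.sqrt(config.n_plots)))
    nrows_p = int(math.ceil(config.n_plots / ncols_p))
    extent_x = ncols_p * config.grid_spacing
    extent_y = nrows_p * config.grid_spacing
    cell = config.wetness_cell_size
    shape = (int(math.ceil(extent_y / cell)), int(math.ceil(extent_x / cell)))
    wetness = generate_wetness_surface(
        shape, cell, config.correlation_length, seed, beta_params=config.wetness_beta
    )

    age_rng = _rng(seed, "age")
    ages = _stand_ages(config.n_plots, config, age_rng)

    plots: List[PlotSurvey] = []
    profiles: List[SoilProfileRecord] = []
    trees: List[TreeRecord] = []
    als_points: Dict[str, np.ndarray] = {}
    w_values = []
    for i in range(config.n_plots):
        r_p, c_p = divmod(i, ncols_p)
        x = (c_p + 0.5) * config.grid_spacing
        y = wetness.origin[1] - (r_p + 0.5) * config.grid_spacing
        w = float(wetness.value_at(x, y))
        w_values.append(w)
        pid = f"p{i:04d}"
        soil_rng = _rng(seed, "soil", i)
        profiles.append(
            generate_soil_profile(w, seed, config=config, plot_id=pid, rng=soil_rng)
        )
        tree_rng = _rng(seed, "trees", i)
        plot_trees = generate_tree_list(
            w,
            float(ages[i]),
            plot_radius=config.plot_radius,
            config=config,
            allometry=allometry,
            plot_id=pid,
            rng=tree_rng,
        )
        trees.extend(plot_trees)
        als_rng = _rng(seed, "als", i)
        als_points[pid] = generate_als_points(
            plot_trees,
            cell_area_m2=config.als_cell_size**2,
            density=config.als_points_per_m2,
            stand_area_m2=math.pi * config.plot_radius**2,
            rng=als_rng,
        )
        plots.append(
            PlotSurvey(
                plot_id=pid,
                x=x,
                y=y,
                radius=config.plot_radius,
                stand_age=float(ages[i]),
                wetness=w,
            )
        )

    thresholds = quantile_thresholds(w_values, config.moisture_class_props)
    classes = assign_moisture_class(np.asarray(w_values), thresholds)
    plots = [
        PlotSurvey(
            plot_id=p.plot_id,
            x=p.x,
            y=p.y,
            radius=p.radius,
            moisture_class=int(c),
            stand_age=p.stand_age,
            wetness=p.wetness,
        )
        for p, c in zip(plots, classes)
    ]
    return SyntheticCatchment(
        plots=plots,
        profiles=profiles,
        trees=trees,
        wetness=wetness,
        als_points=als_points,
        class_thresholds=thresholds,
        truth=config,
    )
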