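"""Generator and pipeline configuration."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .errors import InvalidArgumentError


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic catchment.

    The defaults encode the survey conditions the downstream analysis
    assumes: 430 plots of 10 m radius on a 350 m grid, field moisture-class
    proportions 7/73/11/7/2 %, an 11 % peat-plot fraction, a log-quadratic
    total-SOC curve in the wetness index with residual sd 0.24 on the log
    scale, a unimodal tree-C curve peaking at intermediate wetness, and an
    ALS return density of 20 points per m^2.
    """

    n_plots: int = 430
    grid_spacing: float = 350.0  # m between adjacent plots
    plot_radius: float = 10.0  # m
    moisture_class_props: Tuple[float, ...] = (0.07, 0.73, 0.11, 0.07, 0.02)
    peat_target_fraction: float = 0.11

    # log-scale polynomial log(SOC) = b0 + b1 x + b2 x^2, residual sd on log scale
    soc_curve: Tuple[float, float, float] = (4.23, 8.51, 3.35)
    soc_log_sd: float = 0.24

    # tree C quadratic (Mg C ha^-1) a0 + a1 x + a2 x^2, truncated at 0
    tree_curve: Tuple[float, float, float] = (44.0, 170.0, -200.0)
    tree_sd: float = 18.0  # Mg C ha^-1, additive residual
    species_probs: Tuple[float, float, float] = (0.63, 0.26, 0.11)  # pine/spruce/birch
    height_noise_sd: float = 0.5  # m, measurement noise on field heights

    als_points_per_m2: float = 20.0
    als_cell_size: float = 12.5  # m

    # wetness field: squashing of a smoothed Gaussian field through a Beta
    # quantile transform (marginal concentrated at low wetness, where the
    # raw-basis log-quadratic is numerically sane)
    wetness_beta: Tuple[float, float] = (1.0, 14.0)
    correlation_length: float = 50.0  # m
    wetness_cell_size: float = 2.0  # m

    # organic layer thickness model
    thickness_dry_cm: float = 4.0  # dry-end minimum
    thickness_log_sd: float = 0.15  # multiplicative lognormal noise

    # stand age: uniform(0, 272) mixed toward a younger component so the
    # marginal mean lands near 79 years
    stand_age_range: Tuple[float, float] = (0.0, 272.0)
    stand_age_mean: float = 79.0

    densified_inner_grid: bool = False  # 175 m inner grid, off by default
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_plots < 10:
            raise InvalidArgumentError("n_plots must be >= 10")
        if abs(sum(self.moisture_class_props) - 1.0) > 1e-9:
            raise InvalidArgumentError("moisture class proportions must sum to 1")
        for name in ("soc_log_sd", "tree_sd", "thickness_log_sd", "height_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.als_points_per_m2 <= 0 or self.grid_spacing <= 0:
            raise InvalidArgumentError("densities and spacings must be positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {}
        for k, v in data.items():
            if k not in known:
                raise InvalidArgumentError(f"unknown generator option {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs).validate()

    def noiseless(self) -> "GeneratorConfig":
        """Copy with every residual sd set to zero (round-trip conditions)."""
        return replace(
            self, soc_log_sd=0.0, tree_sd=0.0, thickness_log_sd=0.0, height_noise_sd=0.0
        )


@dataclass
class PipelineConfig:
    """End-to-end run configuration: generator, thresholds, output paths."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    canopy_threshold: float = 1.5  # m, VR cutoff
    exclusion_limit: float = 5.0  # m, |Lorey - P95| rule
    als_exponent: float = 1.2
    soc_degree: int = 2
    soc_log_scale: bool = True
    allometry_path: Optional[str] = None  # YAML table; None -> built-in defaults
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.canopy_threshold < 0 or self.exclusion_limit <= 0:
            raise InvalidArgumentError("thresholds must be positive")
        self.generator.validate()
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        gen = data.pop("generator", {})
        cfg = cls(generator=GeneratorConfig.from_dict(gen), **data)
        return cfg.validate()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
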