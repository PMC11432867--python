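"""Run configuration, validation, and the end-to-end pipeline runner.

A run is described by a YAML file (or an in-memory :class:`RunConfig`)
naming the input rasters and tables, the reference-species traits, model
parameters and preprocessing widths. ``run_pipeline`` executes
simulate (optional) -> prepare -> both models -> compare -> summarize and
writes the 8-raster bundle, summary CSVs and a manifest recording every
effective parameter.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .biophysical import SpeciesTraits, load_biophysical_table
from .compare import Dataset, ExperimentBundle, run_comparison_experiment
from .estimap import EstimapParams
from .grids import ValidationError, load_class_table, load_raster
from .invest import InvestParams
from .preprocess import derive_forest_edges, derive_riparian_zones
from .synthetic import LandscapeConfig, generate_biophysical, paired_landscapes

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    When ``simulate`` is true the two datasets are generated from
    ``landscape`` (detailed vs generalized pair) instead of being read
    from ``dataset_a``/``dataset_b`` paths.
    """

    output_dir: str = "pollimap_out"
    simulate: bool = True
    seed: int = 42
    landscape: dict = field(default_factory=dict)
    min_patch_cells: int = 250
    # file-based inputs (used when simulate is false); each entry:
    # {lulc: path, class_table: path, biophysical: path}
    dataset_a: dict = field(default_factory=dict)
    dataset_b: dict = field(default_factory=dict)
    # preprocessing (applied to file-based inputs)
    apply_preprocess: bool = False
    forest_edge_m: float = 15.0
    riparian_m: float = 4.0
    # reference species
    flight_distance_m: float = 680.0
    nest_pref_cavity: float = 1.0
    nest_pref_ground: float = 1.0
    activity_spring: float = 1.0
    activity_summer: float = 1.0
    relative_abundance: float = 1.0
    # model parameters
    estimap: dict = field(default_factory=dict)
    invest: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def species(self) -> SpeciesTraits:
        return SpeciesTraits(
            flight_distance_m=self.flight_distance_m,
            nest_pref_cavity=self.nest_pref_cavity,
            nest_pref_ground=self.nest_pref_ground,
            activity_spring=self.activity_spring,
            activity_summer=self.activity_summer,
            relative_abundance=self.relative_abundance,
        )

    def estimap_params(self) -> EstimapParams:
        return EstimapParams(**self.estimap)

    def invest_params(self) -> InvestParams:
        return InvestParams(**self.invest)

    def landscape_config(self) -> LandscapeConfig:
        kwargs = dict(self.landscape)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("forest_edge_m", self.forest_edge_m)
        kwargs.setdefault("riparian_m", self.riparian_m)
        if "patch_radius_range" in kwargs:
            kwargs["patch_radius_range"] = tuple(kwargs["patch_radius_range"])
        if "seminatural_radius_range" in kwargs:
            kwargs["seminatural_radius_range"] = tuple(kwargs["seminatural_radius_range"])
        if "lake_radius_range" in kwargs:
            kwargs["lake_radius_range"] = tuple(kwargs["lake_radius_range"])
        return LandscapeConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def validate_config(config: RunConfig | str | Path) -> list[str]:
    """List every violated constraint; an empty report means runnable."""
    if not isinstance(config, RunConfig):
        try:
            config = load_config(config)
        except ValidationError as e:
            return [str(e)]
    problems: list[str] = []
    if config.flight_distance_m <= 0:
        problems.append(f"flight_distance_m must be > 0, got {config.flight_distance_m}")
    if config.activity_spring + config.activity_summer <= 0:
        problems.append("activity_spring + activity_summer must be > 0")
    if max(config.nest_pref_cavity, config.nest_pref_ground) <= 0:
        problems.append("at least one nesting preference must be > 0")
    if config.forest_edge_m < 0:
        problems.append("forest_edge_m must be >= 0")
    if config.riparian_m < 0:
        problems.append("riparian_m must be >= 0")
    if config.min_patch_cells < 1:
        problems.append("min_patch_cells must be >= 1")
    for maker, label in (
        (config.estimap_params, "estimap"),
        (config.invest_params, "invest"),
        (config.landscape_config, "landscape"),
    ):
        try:
            maker()
        except (ValidationError, TypeError, ValueError) as e:
            problems.append(f"{label}: {e}")
    if not config.simulate:
        for name, ds in (("dataset_a", config.dataset_a), ("dataset_b", config.dataset_b)):
            for key in ("lulc", "class_table", "biophysical"):
                p = ds.get(key)
                if not p:
                    problems.append(f"{name}: missing {key} path")
                elif not Path(p).exists():
                    problems.append(f"{name}: {key} path {p} does not exist")
    return problems


def _load_dataset(entry: dict, name: str, cfg: RunConfig) -> Dataset:
    lulc = load_raster(entry["lulc"], kind="integer")
    table = load_class_table(entry["class_table"])
    if cfg.apply_preprocess:
        lulc, table = derive_forest_edges(lulc, table, cfg.forest_edge_m)
        lulc, table = derive_riparian_zones(lulc, table, cfg.riparian_m)
    bio = load_biophysical_table(entry["biophysical"])
    bio.check_against(table)
    return Dataset(lulc=lulc, table=table, bio=bio, name=name)


def run_pipeline(config: RunConfig | str | Path) -> ExperimentBundle:
    """Execute the full experiment described by ``config`` and write the
    bundle to ``config.output_dir``."""
    if not isinstance(config, RunConfig):
        config = load_config(config)
    problems = validate_config(config)
    if problems:
        raise ValidationError("invalid config: " + "; ".join(problems))

    t0 = time.perf_counter()
    if config.simulate:
        log.info("stage simulate: generating paired landscapes (seed %d)", config.seed)
        (lulc_a, table_a), (lulc_b, table_b) = paired_landscapes(
            config.landscape_config(), min_patch_cells=config.min_patch_cells
        )
        bio_a, _survey = generate_biophysical(table_a, mode="expert", seed=config.seed)
        bio_b = generate_biophysical(table_b, mode="literature")
        dataset_a = Dataset(lulc_a, table_a, bio_a, name="detailed (expert values)")
        dataset_b = Dataset(lulc_b, table_b, bio_b, name="generalized (literature values)")
    else:
        log.info("stage prepare: loading datasets from disk")
        dataset_a = _load_dataset(config.dataset_a, "dataset_a", config)
        dataset_b = _load_dataset(config.dataset_b, "dataset_b", config)
    log.info("stage prepare done in %.2f s", time.perf_counter() - t0)

    t1 = time.perf_counter()
    bundle = run_comparison_experiment(
        dataset_a,
        dataset_b,
        config.species(),
        config.estimap_params(),
        config.invest_params(),
    )
    log.info("stage model+compare done in %.2f s", time.perf_counter() - t1)

    bundle.manifest["config"] = _jsonable(asdict(config))
    out = bundle.save(config.output_dir)
    log.info("bundle written to %s", out)
    return bundle


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))
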