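"""End-to-end seeded pipeline: generate/load data -> train surrogates ->
sensitivity -> multi-objective optimization -> recommendation.

Every run is driven by a single :class:`RunConfig` (serializable to YAML),
every stage derives its seed from the global seed, and every artifact written
to the run directory is listed in a manifest with its SHA-256 hash, so a
fixed config reproduces bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .catalog import GROUPS, DesignPoint
from .datagen import GenerationConfig, generate_dataset, read_dataset, write_dataset
from .encoding import aggregate_replicates
from .moo import (
    DEFAULT_OBJECTIVES,
    GAConfig,
    ParetoFront,
    enumerate_front,
    ga_front,
)
from .sensitivity import aggregate_by_factor, yoon_ri
from .surrogate import (
    FitReport,
    MLPSurrogate,
    TopologySearchConfig,
    save_model,
    topology_search,
)

#: paper-scale restart budget reachable via the --paper-scale CLI flag
PAPER_SCALE_RESTARTS = 100_000


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of one pipeline run."""

    # data source: path to a measured CSV, or synthetic generation settings
    dataset_path: str | None = None
    replicates_per_condition: int = 3
    noise_sd_fraction: float = 0.03
    flaxseed_ala_multiplier: float = 10.0
    planted_optimum: tuple[str, str, int] | None = None
    # topology search
    hidden_range: tuple[int, int] = (7, 12)
    activations: tuple[str, ...] = ("identity", "logistic", "tanh")
    restarts: int = 10
    validation_fraction: float = 0.15
    test_fraction: float = 0.15
    max_bfgs_iterations: int = 500
    # sensitivity
    ri_denominator: str = "abs"
    # GA
    ga_population: int = 20
    ga_generations: int = 50
    ga_crossover_rate: float = 0.9
    ga_mutation_rate: float = 1.0 / 3.0
    # global
    seed: int = 0

    def generation_config(self) -> GenerationConfig:
        planted = (
            DesignPoint(*self.planted_optimum) if self.planted_optimum else None
        )
        return GenerationConfig(
            replicates_per_condition=self.replicates_per_condition,
            noise_sd_fraction=self.noise_sd_fraction,
            flaxseed_ala_multiplier=self.flaxseed_ala_multiplier,
            seed=self.seed,
            planted_optimum=planted,
        )

    def topology_config(self, group_index: int) -> TopologySearchConfig:
        return TopologySearchConfig(
            hidden_range=tuple(self.hidden_range),
            activations=tuple(self.activations),
            restarts=self.restarts,
            validation_fraction=self.validation_fraction,
            test_fraction=self.test_fraction,
            seed=self.seed * 1000 + group_index,
            max_bfgs_iterations=self.max_bfgs_iterations,
        )

    def ga_config(self) -> GAConfig:
        return GAConfig(
            population=self.ga_population,
            generations=self.ga_generations,
            crossover_rate=self.ga_crossover_rate,
            mutation_rate=self.ga_mutation_rate,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_range"] = list(self.hidden_range)
        d["activations"] = list(self.activations)
        if self.planted_optimum:
            d["planted_optimum"] = list(self.planted_optimum)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "hidden_range" in d:
            d["hidden_range"] = tuple(d["hidden_range"])
        if "activations" in d:
            d["activations"] = tuple(d["activations"])
        if d.get("planted_optimum"):
            sp, sub, t = d["planted_optimum"]
            d["planted_optimum"] = (sp, sub, int(t))
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: pd.DataFrame
    mean_table: pd.DataFrame
    models: dict[str, MLPSurrogate]
    reports: dict[str, FitReport]
    ri: dict[str, pd.DataFrame]
    front_enumeration: ParetoFront
    front_ga: ParetoFront
    recommended: DesignPoint

    def summary(self) -> dict:
        rec_values = {}
        for point, values in self.front_enumeration.members:
            if point == self.recommended:
                rec_values = {k: float(values[k]) for k in values.index}
        return {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "recommended": {
                "species": self.recommended.species,
                "substrate": self.recommended.substrate,
                "harvest_days": self.recommended.harvest_days,
            },
            "recommended_predictions": rec_values,
            "front_size_enumeration": len(self.front_enumeration.members),
            "front_size_ga": len(self.front_ga.members),
            "fronts_agree": self.front_enumeration.member_points
            == self.front_ga.member_points,
            "models": {
                g: {
                    "topology": self.reports[g].topology_label,
                    "hidden_activation": self.reports[g].hidden_activation,
                    "parameters": self.models[g].parameter_count,
                    "train_sos": self.reports[g].sos,
                    "r2_overall_train": self.reports[g].r2_overall,
                    "selection_score": self.reports[g].selection_score,
                }
                for g in GROUPS
            },
        }


def load_or_generate(config: RunConfig) -> pd.DataFrame:
    if config.dataset_path:
        return read_dataset(config.dataset_path)
    return generate_dataset(config.generation_config())


def train_all(config: RunConfig, mean_table: pd.DataFrame):
    """Topology-search one surrogate per response group."""
    models: dict[str, MLPSurrogate] = {}
    reports: dict[str, FitReport] = {}
    for gi, group in enumerate(GROUPS):
        models[group], reports[group] = topology_search(
            mean_table, group, config.topology_config(gi)
        )
    return models, reports


def run_all(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage; optionally write all artifacts plus a hashed
    manifest and a summary to ``outdir``."""
    dataset = load_or_generate(config)
    mean_table = aggregate_replicates(dataset)
    models, reports = train_all(config, mean_table)
    ri = {
        g: yoon_ri(models[g], denominator=config.ri_denominator).ri for g in GROUPS
    }
    front_enum = enumerate_front(list(models.values()), DEFAULT_OBJECTIVES)
    front_ga = ga_front(list(models.values()), DEFAULT_OBJECTIVES, config.ga_config())
    result = PipelineResult(
        config=config,
        dataset=dataset,
        mean_table=mean_table,
        models=models,
        reports=reports,
        ri=ri,
        front_enumeration=front_enum,
        front_ga=front_ga,
        recommended=front_enum.recommended,
    )
    if outdir is not None:
        write_artifacts(result, Path(outdir))
    return result


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    cfg.to_yaml(outdir / "config.yaml")
    write_dataset(result.dataset, outdir / "dataset.csv")
    result.mean_table.to_csv(outdir / "condition_means.csv", index=False, float_format="%.6g")
    fit_rows = []
    for g in GROUPS:
        save_model(result.models[g], outdir / f"model_{g}.json")
        result.ri[g].to_csv(outdir / f"ri_{g}.csv", float_format="%.6g")
        from .sensitivity import RelativeInfluenceMatrix

        agg = aggregate_by_factor(
            RelativeInfluenceMatrix(ri=result.ri[g], model_label=result.reports[g].topology_label)
        )
        agg.to_csv(outdir / f"ri_{g}_by_factor.csv", index=False, float_format="%.6g")
        for cand in result.reports[g].candidates:
            fit_rows.append({"group": g, **cand})
    if fit_rows:
        pd.DataFrame(fit_rows).to_csv(outdir / "fit_report.csv", index=False)
    result.front_enumeration.to_frame().to_csv(
        outdir / "pareto_front.csv", index=False, float_format="%.6g"
    )
    result.front_ga.to_frame().to_csv(
        outdir / "pareto_front_ga.csv", index=False, float_format="%.6g"
    )
    summary = result.summary()
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "artifacts": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.iterdir())
            if p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
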