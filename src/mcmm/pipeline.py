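"""Orchestration of the three workflows: prediction/validation, association
scanning, and the intervention screen.

Each workflow isolates per-sample failures (skip-and-log) so a single bad
sample cannot abort a cohort run, and every output table carries the config
hash and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from .community import CommunityModel, read_abundance_table
from .ctfba import flux_range_at_optimum
from .interventions import (
    InterventionSpec,
    PROBIOTIC_FRACTION_DEFAULT,
    classify_response,
    screen_interventions,
)
from .medium import DietDefinition, Medium, build_medium, read_diet_tsv
from .stats import pearson_assoc, validate_study_table, zscore_within
from .synthetic import SCFAS, default_diet, high_fiber_diet

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "run_prediction",
    "run_validation",
    "run_screen",
    "default_intervention_specs",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A configuration violating its schema, raised before any compute."""


@dataclass
class PipelineConfig:
    """Pipeline defaults; the printed defaults are the modeling defaults
    used throughout (tradeoff 0.7, abundance cutoff 0.001, growth floor
    0.3 1/h)."""

    model_library: str | None = None
    diet: str = "european"
    recipe: str = "in_vivo"
    tradeoff: float = 0.7
    abundance_cutoff: float = 0.001
    growth_floor: float = 0.3
    fiber_dilution: float | None = None
    probiotic_taxon: str = "butyrogen"
    probiotic_fraction: float = PROBIOTIC_FRACTION_DEFAULT
    baseline_cut: float = 15.0
    increase_cut: float = 0.20
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if not 0 < self.tradeoff <= 1:
            raise ConfigError("tradeoff must be in (0, 1]")
        if not 0 <= self.abundance_cutoff < 1:
            raise ConfigError("abundance_cutoff must be in [0, 1)")
        if self.growth_floor <= 0:
            raise ConfigError("growth_floor must be positive")
        if not 0 <= self.probiotic_fraction < 1:
            raise ConfigError("probiotic_fraction must be in [0, 1)")
        if self.recipe not in ("in_vivo", "ex_vivo"):
            raise ConfigError(f"unknown recipe {self.recipe!r}")
        if self.recipe == "ex_vivo" and self.fiber_dilution is None:
            raise ConfigError("ex_vivo recipe requires fiber_dilution")
        return self

    @property
    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _resolve_diet(config: PipelineConfig) -> DietDefinition:
    named = {"european": default_diet, "high_fiber": high_fiber_diet}
    if config.diet in named:
        return named[config.diet]()
    return read_diet_tsv(config.diet)


def run_prediction(config: PipelineConfig, profiles, library,
                   medium: Medium | None = None,
                   report_ranges: bool = False) -> pd.DataFrame:
    """Per sample: filter -> match -> assemble -> ctFBA -> production rates.

    Returns one row per sample and SCFA with growth diagnostics; failed
    samples are flagged, not fatal.
    """
    config.validate()
    library = list(library)
    if medium is None:
        medium = build_medium(_resolve_diet(config), config.recipe,
                              models=library,
                              growth_floor=config.growth_floor,
                              fiber_dilution=config.fiber_dilution)
    rows = []
    for profile in profiles:
        base = {"sample_id": profile.sample_id, "config_hash": config.hash,
                "seed": config.seed}
        try:
            cm = CommunityModel.build(profile, library, medium,
                                      cutoff=config.abundance_cutoff)
            res = cm.fit(tradeoff=config.tradeoff)
        except Exception as err:
            log.warning("sample %s failed: %s", profile.sample_id, err)
            rows.append({**base, "metabolite": None, "status": f"error:{err}",
                         "production_rate": float("nan")})
            continue
        if res.status != "optimal":
            rows.append({**base, "metabolite": None, "status": res.status,
                         "production_rate": float("nan")})
            continue
        production = res.production_rates()
        for met in SCFAS:
            row = {**base, "metabolite": met, "status": "optimal",
                   "production_rate": production.get(met, 0.0),
                   "community_growth": res.community_growth,
                   "matched_fraction": cm.matched_fraction}
            if report_ranges and met in cm.community_ex_col:
                lo, hi = flux_range_at_optimum(cm, res, met)
                row["flux_min"], row["flux_max"] = lo, hi
            rows.append(row)
    return pd.DataFrame(rows)


def run_validation(study_table: pd.DataFrame,
                   group_key: str = "study_id") -> pd.DataFrame:
    """Compare predicted against measured fluxes.

    Z-scores both axes within each study, then reports per-metabolite Pearson
    r and p (pooled across studies on the Z scale) plus per-treatment
    subgroup correlations where a treatment column is informative.
    """
    table = validate_study_table(study_table).dropna(subset=["metabolite"])
    if table.empty:
        raise ValueError("no joined (sample, metabolite) rows to validate")
    scored = zscore_within(table, group_key)
    rows = []
    for met, grp in scored.groupby("metabolite"):
        r, p = pearson_assoc(grp["predicted_flux"], grp["measured_flux"])
        rows.append({"metabolite": met, "scope": "all", "n": len(grp),
                     "pearson_r": r, "p_value": p})
        if grp["treatment"].nunique() > 1:
            for arm, sub in grp.groupby("treatment"):
                if len(sub) >= 3 and sub["predicted_flux"].nunique() > 1 \
                        and sub["measured_flux"].nunique() > 1:
                    r, p = pearson_assoc(sub["predicted_flux"],
                                         sub["measured_flux"])
                    rows.append({"metabolite": met, "scope": f"treatment:{arm}",
                                 "n": len(sub), "pearson_r": r, "p_value": p})
    return pd.DataFrame(rows)


def default_intervention_specs(config: PipelineConfig) -> list:
    """The screened grid: each background diet alone, plus single-fiber
    (inulin, pectin) and probiotic additions on each."""
    probiotic = (config.probiotic_taxon, config.probiotic_fraction)
    specs = []
    for diet in ("european", "high_fiber"):
        specs.append(InterventionSpec(f"{diet}", diet=diet))
        specs.append(InterventionSpec(f"{diet}+inulin", diet=diet,
                                      fiber="inulin"))
        specs.append(InterventionSpec(f"{diet}+pectin", diet=diet,
                                      fiber="pectin"))
        specs.append(InterventionSpec(f"{diet}+probiotic", diet=diet,
                                      probiotic=probiotic))
    return specs


def run_screen(config: PipelineConfig, profiles, library,
               specs: list | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diet-swap classification plus the intervention screen.

    Every sample gets butyrate predictions on the European and high-fiber
    diets and a responder/non-responder/regressor label; non-responders and
    regressors are then screened over ``specs`` (default grid) with the
    best-performing intervention flagged.
    """
    config.validate()
    library = list(library)
    media = {
        "european": build_medium(default_diet(), "in_vivo", models=library,
                                 growth_floor=config.growth_floor),
        "high_fiber": build_medium(high_fiber_diet(), "in_vivo",
                                   models=library,
                                   growth_floor=config.growth_floor),
    }
    class_rows = []
    screen_rows = []
    if specs is None:
        specs = default_intervention_specs(config)
    for profile in profiles:
        rates = {}
        failed = None
        for diet, medium in media.items():
            try:
                cm = CommunityModel.build(profile, library, medium,
                                          cutoff=config.abundance_cutoff)
                res = cm.fit(tradeoff=config.tradeoff)
                if res.status != "optimal":
                    failed = res.status
                    break
                rates[diet] = res.production_rates().get("butyrate", 0.0)
            except Exception as err:
                failed = f"error:{err}"
                break
        if failed is not None:
            class_rows.append({"sample_id": profile.sample_id,
                               "butyrate_eu": float("nan"),
                               "butyrate_hf": float("nan"),
                               "label": failed,
                               "config_hash": config.hash,
                               "seed": config.seed})
            continue
        label = classify_response(rates["european"], rates["high_fiber"],
                                  config.baseline_cut, config.increase_cut)
        class_rows.append({"sample_id": profile.sample_id,
                           "butyrate_eu": rates["european"],
                           "butyrate_hf": rates["high_fiber"],
                           "label": label, "config_hash": config.hash,
                           "seed": config.seed})
        if label in ("non_responder", "regressor"):
            screened = screen_interventions(
                profile, library, specs, tradeoff=config.tradeoff,
                cutoff=config.abundance_cutoff,
                growth_floor=config.growth_floor,
            )
            screened.insert(0, "sample_id", profile.sample_id)
            screen_rows.append(screened)
    classification = pd.DataFrame(class_rows)
    screen = (pd.concat(screen_rows, ignore_index=True)
              if screen_rows else pd.DataFrame(
                  columns=["sample_id", "spec", "butyrate", "status", "best"]))
    return classification, screen


def load_inputs(abundance_path, library_paths):
    """Convenience loader for CLI workflows."""
    from .io import load_taxon_model

    profiles = read_abundance_table(abundance_path)
    library = [load_taxon_model(p) for p in library_paths]
    return profiles, library
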