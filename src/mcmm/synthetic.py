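"""Synthetic inputs with known ground truth for every pipeline stage.

Generates small taxon models built around six metabolic archetypes (fiber
degrader, butyrogen, propionogen, acetogen, acetate-to-butyrate cross-feeder,
non-producer), Dirichlet-distributed community compositions, forward-model
"measured" fluxes with multiplicative lognormal error, and clinical marker
tables linearly coupled to the true butyrate flux. One integer seed fixes
every stochastic choice in a study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import AbundanceProfile, CommunityModel
from .gem_core import Metabolite, Reaction, TaxonModel, UNBOUNDED, validate_model
from .medium import DietDefinition, Medium, build_medium, supplement_fiber

__all__ = [
    "TaxonArchetype",
    "SyntheticStudy",
    "ARCHETYPES",
    "SCFAS",
    "make_taxon_model",
    "make_degenerate_taxon",
    "make_cohort",
    "default_diet",
    "high_fiber_diet",
    "simulate_measurements",
    "simulate_clinical",
]

SCFAS = ("acetate", "propionate", "butyrate")


class ConstructionError(ValueError):
    """An archetype whose stated yields cannot form a valid model."""


@dataclass
class TaxonArchetype:
    """Recipe for a minimal taxon model: one substrate, one catabolic reaction
    realizing the stated SCFA yields, one biomass reaction.

    ``biomass_yield`` is gDW per mmol substrate; ``scfa_yields`` mmol SCFA per
    mmol substrate. ``formulas``, when given, must close the carbon balance of
    the catabolic reaction exactly. ``extra_requirements`` adds trace
    co-substrates (e.g. iron) consumed per mmol of substrate.
    """

    name: str
    substrate: str
    biomass_yield: float
    scfa_yields: dict = field(default_factory=dict)
    uptake_bound: float = 10.0
    formulas: dict = field(default_factory=dict)
    extra_requirements: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.biomass_yield < 0 or any(y < 0 for y in self.scfa_yields.values()):
            raise ConstructionError(f"{self.name}: yields must be nonnegative")


#: Default archetype library. Yields are in mmol product per mmol substrate
#: and chosen so a lone taxon on 10 mmol/gDW/h of substrate grows at a
#: database-plausible 1-4 1/h; the cross-feeder closes the acetate->butyrate loop.
ARCHETYPES: dict[str, TaxonArchetype] = {
    a.name: a
    for a in [
        TaxonArchetype("fiber_degrader", "inulin", 0.25,
                       {"acetate": 1.0, "butyrate": 1.0}),
        TaxonArchetype("butyrogen", "glucose", 0.2, {"butyrate": 2.0}),
        TaxonArchetype("propionogen", "glucose", 0.25, {"propionate": 1.5}),
        TaxonArchetype("acetogen", "glucose", 0.3, {"acetate": 2.0}),
        TaxonArchetype("acetate_to_butyrate_crossfeeder", "acetate", 0.1,
                       {"butyrate": 0.5}),
        TaxonArchetype("non_producer", "glucose", 0.4, {}),
    ]
}


def _check_carbon_balance(arch: TaxonArchetype) -> None:
    from .gem_core import carbon_count

    if not arch.formulas:
        return
    needed = {arch.substrate, "biomass_precursor", *arch.scfa_yields}
    if not needed <= set(arch.formulas):
        raise ConstructionError(
            f"{arch.name}: formulas must cover substrate, biomass_precursor "
            "and every SCFA product"
        )
    c_in = carbon_count(arch.formulas[arch.substrate])
    c_out = arch.biomass_yield * carbon_count(arch.formulas["biomass_precursor"])
    c_out += sum(y * carbon_count(arch.formulas[s])
                 for s, y in arch.scfa_yields.items())
    if abs(c_in - c_out) > 1e-9:
        raise ConstructionError(
            f"{arch.name}: catabolic reaction is carbon-imbalanced "
            f"({c_in} in vs {c_out:g} out)"
        )


def make_taxon_model(archetype: TaxonArchetype | str,
                     rank: str = "genus") -> TaxonModel:
    """Build the archetype's TaxonModel (passes ``validate_model``).

    Structure: EX_substrate (uptake bounded), one catabolic reaction
    substrate -> biomass_yield precursor + SCFA yields, one biomass reaction
    draining the precursor, and one export exchange per SCFA.
    """
    arch = ARCHETYPES[archetype] if isinstance(archetype, str) else archetype
    _check_carbon_balance(arch)

    mets = [
        Metabolite(arch.substrate, compartment="e",
                   formula=arch.formulas.get(arch.substrate)),
        Metabolite("biomass_precursor", compartment="c",
                   formula=arch.formulas.get("biomass_precursor")),
    ]
    stoich = {arch.substrate: -1.0, "biomass_precursor": arch.biomass_yield}
    rxns = [
        Reaction(f"EX_{arch.substrate}", {arch.substrate: -1.0},
                 lower_bound=-arch.uptake_bound, upper_bound=UNBOUNDED,
                 is_exchange=True),
        Reaction("biomass", {"biomass_precursor": -1.0},
                 lower_bound=0.0, upper_bound=UNBOUNDED, is_biomass=True),
    ]
    for scfa, y in arch.scfa_yields.items():
        mets.append(Metabolite(scfa, compartment="e",
                               formula=arch.formulas.get(scfa)))
        stoich[scfa] = stoich.get(scfa, 0.0) + y
        rxns.append(Reaction(f"EX_{scfa}", {scfa: -1.0},
                             lower_bound=0.0, upper_bound=UNBOUNDED,
                             is_exchange=True))
    for extra, coef in arch.extra_requirements.items():
        mets.append(Metabolite(extra, compartment="e",
                               formula=arch.formulas.get(extra)))
        stoich[extra] = -coef
        rxns.append(Reaction(f"EX_{extra}", {extra: -1.0},
                             lower_bound=-UNBOUNDED, upper_bound=UNBOUNDED,
                             is_exchange=True))
    rxns.insert(1, Reaction("catabolism", stoich, 0.0, UNBOUNDED))
    return TaxonModel.from_parts(arch.name, mets, rxns, rank=rank)


def make_degenerate_taxon(name: str = "degenerate_producer",
                          rank: str = "genus") -> TaxonModel:
    """A taxon with two isoenergetic pathways splitting carbon between acetate
    and butyrate — engineered flux degeneracy at the growth optimum."""
    mets = [
        Metabolite("glucose", compartment="e"),
        Metabolite("biomass_precursor", compartment="c"),
        Metabolite("acetate", compartment="e"),
        Metabolite("butyrate", compartment="e"),
    ]
    rxns = [
        Reaction("EX_glucose", {"glucose": -1.0}, -10.0, UNBOUNDED,
                 is_exchange=True),
        Reaction("catabolism_ac",
                 {"glucose": -1.0, "biomass_precursor": 0.2, "acetate": 2.0},
                 0.0, UNBOUNDED),
        Reaction("catabolism_but",
                 {"glucose": -1.0, "biomass_precursor": 0.2, "butyrate": 2.0},
                 0.0, UNBOUNDED),
        Reaction("biomass", {"biomass_precursor": -1.0}, 0.0, UNBOUNDED,
                 is_biomass=True),
        Reaction("EX_acetate", {"acetate": -1.0}, 0.0, UNBOUNDED,
                 is_exchange=True),
        Reaction("EX_butyrate", {"butyrate": -1.0}, 0.0, UNBOUNDED,
                 is_exchange=True),
    ]
    return TaxonModel.from_parts(name, mets, rxns, rank=rank)


@dataclass
class SyntheticStudy:
    """Configuration of one fully reproducible synthetic study."""

    seed: int
    n_samples: int = 20
    archetypes: tuple = tuple(ARCHETYPES)
    dirichlet_alpha: float = 1.0
    noise_sigma: float = 0.3
    dilution_factor: float = 5.0
    treatment_arms: tuple = ("control",)
    tradeoff: float = 0.7
    name: str = "synthetic"


@dataclass
class Cohort:
    """A generated study: abundance profiles + model library + diet."""

    study: SyntheticStudy
    profiles: list
    library: list
    diet: DietDefinition

    def abundance_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": p.sample_id, "taxon": t, "relative_abundance": a,
             "rank": p.rank}
            for p in self.profiles
            for t, a in sorted(p.entries.items())
        ]
        return pd.DataFrame(rows)


def default_diet() -> DietDefinition:
    """A minimal European-style diet: absorbable glucose, residual inulin,
    and trace iron; fluxes in mmol/gDW/h."""
    return DietDefinition(
        name="synthetic_european",
        entries={"glucose": 10.0, "inulin": 2.0, "fe3": 0.1},
        flags={
            "glucose": {"host_absorbable": True},
            "inulin": {"residual_fiber": True},
        },
        formulas={"glucose": "C6H12O6", "inulin": "C36H62O31", "fe3": "Fe"},
    )


def high_fiber_diet() -> DietDefinition:
    """The diet-swap counterpart: less free sugar, much more fermentable
    fiber (resistant-starch-rich)."""
    return DietDefinition(
        name="synthetic_high_fiber",
        entries={"glucose": 5.0, "inulin": 20.0, "fe3": 0.1},
        flags={
            "glucose": {"host_absorbable": True},
            "inulin": {"residual_fiber": True},
        },
        formulas={"glucose": "C6H12O6", "inulin": "C36H62O31", "fe3": "Fe"},
    )


def make_cohort(study: SyntheticStudy) -> Cohort:
    """Draw Dirichlet community compositions and build the model library.

    Identical seeds yield identical cohorts; every taxon has a model and
    every generated model passes validation.
    """
    rng = np.random.default_rng(study.seed)
    taxa = list(study.archetypes)
    library = [make_taxon_model(t) if t in ARCHETYPES else make_degenerate_taxon(t)
               for t in taxa]
    for model in library:
        violations = validate_model(model)
        if violations:
            raise ConstructionError(
                f"generated model {model.taxon_id} invalid: {violations[0]}"
            )
    alpha = np.full(len(taxa), study.dirichlet_alpha)
    profiles = []
    for i in range(study.n_samples):
        weights = rng.dirichlet(alpha)
        weights = np.clip(weights, 1e-12, None)
        weights /= weights.sum()
        profiles.append(AbundanceProfile(
            f"{study.name}_{i:03d}", dict(zip(taxa, weights)), rank="genus",
        ))
    return Cohort(study, profiles, library, default_diet())


def _study_medium(cohort: Cohort, treatment: str) -> Medium:
    medium = build_medium(cohort.diet, "in_vivo", models=cohort.library)
    if treatment != "control":
        medium = supplement_fiber(medium, treatment)
    return medium


def simulate_measurements(cohort: Cohort, medium: Medium | None = None,
                          tradeoff: float | None = None,
                          noise_sigma: float | None = None,
                          seed: int | None = None) -> pd.DataFrame:
    """Forward-simulate the cohort and emit a study table.

    Predicted fluxes come from the ctFBA forward model; measured fluxes are
    predicted * exp(eps) with eps ~ Normal(0, sigma^2), i.i.d. per sample and
    metabolite (multiplicative lognormal measurement error, matching the
    proportionality between predicted and measured axes). Ground truth is the
    ``predicted_flux`` column itself.
    """
    study = cohort.study
    tradeoff = study.tradeoff if tradeoff is None else tradeoff
    sigma = study.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(study.seed + 1 if seed is None else seed)
    arms = study.treatment_arms
    media = {arm: medium if medium is not None else _study_medium(cohort, arm)
             for arm in arms}
    rows = []
    for i, profile in enumerate(cohort.profiles):
        arm = arms[i % len(arms)]
        try:
            cm = CommunityModel.build(profile, cohort.library, media[arm])
            res = cm.fit(tradeoff=tradeoff)
        except Exception as err:  # per-sample isolation
            rows.append({"sample_id": profile.sample_id, "study_id": study.name,
                         "treatment": arm,
                         "dilution_factor": study.dilution_factor,
                         "metabolite": None, "predicted_flux": np.nan,
                         "measured_flux": np.nan, "status": f"error:{err}"})
            continue
        if res.status != "optimal":
            rows.append({"sample_id": profile.sample_id, "study_id": study.name,
                         "treatment": arm,
                         "dilution_factor": study.dilution_factor,
                         "metabolite": None, "predicted_flux": np.nan,
                         "measured_flux": np.nan, "status": res.status})
            continue
        production = res.production_rates()
        for met in SCFAS:
            pred = production.get(met, 0.0)
            eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            rows.append({
                "sample_id": profile.sample_id,
                "study_id": study.name,
                "treatment": arm,
                "dilution_factor": study.dilution_factor,
                "metabolite": met,
                "predicted_flux": pred,
                "measured_flux": pred * float(np.exp(eps)),
                "status": "optimal",
            })
    return pd.DataFrame(rows)


def simulate_clinical(flux: np.ndarray, n_markers: int,
                      effect_betas, seed: int
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical marker tables linearly coupled to a (butyrate) flux vector.

    marker_j = beta_j * flux_z + 0.2 * age_z + 0.1 * sex + vendor effect
    + N(0, 1) noise. Covariates: age ~ N(45, 12), sex ~ Bernoulli(0.5),
    vendor ~ uniform over two sequencing vendors (effect +0.15 for V2).
    """
    flux = np.asarray(flux, dtype=float)
    betas = np.asarray(effect_betas, dtype=float)
    if betas.shape != (n_markers,):
        raise ValueError("effect_betas length must equal n_markers")
    rng = np.random.default_rng(seed)
    n = flux.size
    age = rng.normal(45.0, 12.0, n)
    sex = rng.integers(0, 2, n)
    vendor = np.where(rng.integers(0, 2, n) == 1, "V2", "V1")
    flux_z = (flux - flux.mean()) / flux.std(ddof=1)
    age_z = (age - age.mean()) / age.std(ddof=1)
    markers = {}
    for j in range(n_markers):
        noise = rng.normal(0.0, 1.0, n)
        markers[f"marker_{j:03d}"] = (
            betas[j] * flux_z + 0.2 * age_z + 0.1 * sex
            + 0.15 * (vendor == "V2") + noise
        )
    covariates = pd.DataFrame({"age": age, "sex": sex, "vendor": vendor})
    return pd.DataFrame(markers), covariates
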