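"""In-silico growth media built from diet definitions.

A :class:`Medium` maps exchangeable metabolite ids to maximal import fluxes
(mmol/gDW/h) and is applied to a community model as lower bounds on its
community exchange reactions. Media are derived from a :class:`DietDefinition`
through a fixed transformation sequence that mimics the journey of dietary
components to the distal gut:

``in_vivo``  : host absorption (dilute absorbable components to 20%)
               -> add host-supplied metabolites (mucins, bile acids)
               -> LP completion to a minimal augmentation supporting a
               community growth floor (default 0.3 1/h)
``ex_vivo``  : the in-vivo sequence, then stripping of carbon sources (keeping
               residual fiber and host-supplied entries), then 10% dilution
               mimicking the fecal microenvironment, with residual fiber
               instead rescaled by the study's slurry dilution factor.

Every mutation is recorded both per metabolite (``provenance``) and as a
replayable ``history``: applying the recorded history to the raw diet
reproduces the final medium bit-exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gem_core import (
    Metabolite,
    TaxonModel,
    UNBOUNDED,
    ValidationError,
    _stoichiometric_matrix,
    carbon_count,
    fba_optimum,
)

__all__ = [
    "Medium",
    "DietDefinition",
    "CompletionInfeasibleError",
    "apply_host_absorption",
    "add_host_metabolites",
    "complete_medium",
    "strip_carbon",
    "dilute",
    "supplement_fiber",
    "build_medium",
    "replay",
    "read_diet_tsv",
    "write_diet_tsv",
]

FLAG_NAMES = ("host_absorbable", "host_supplied", "residual_fiber")

#: Default single-fiber supplementation bounds, mmol/gDW/h, set from the
#: carbon content of each polymer (one FOS unit carries far less carbon than
#: one pectin chain, hence the higher molar bound).
FIBER_DEFAULTS = {"pectin": 1.0, "inulin": 10.0, "fos": 100.0}

GROWTH_FLOOR_DEFAULT = 0.3  # 1/h, minimum community growth rate
HOST_ABSORPTION_RETAIN = 0.2  # fraction of diet flux escaping the small intestine
FECAL_DILUTION = 0.1  # all non-fiber components diluted to 10%

_EPS = 1e-9


class CompletionInfeasibleError(ValidationError):
    """A model cannot reach the growth floor even with all candidates open."""


@dataclass
class DietDefinition:
    """A diet: metabolite -> flux plus per-metabolite boolean flags.

    ``flags[m]`` holds ``host_absorbable`` / ``host_supplied`` /
    ``residual_fiber`` (absent = false); ``formulas`` optionally carries
    elemental formulas used for carbon stripping.
    """

    name: str
    entries: dict[str, float]
    flags: dict[str, dict] = field(default_factory=dict)
    formulas: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.entries:
            row = dict.fromkeys(FLAG_NAMES, False)
            row.update(self.flags.get(m, {}))
            self.flags[m] = row

    def flag(self, metabolite: str, name: str) -> bool:
        return bool(self.flags.get(metabolite, {}).get(name, False))


@dataclass
class Medium:
    """Max import fluxes per metabolite with full mutation provenance."""

    entries: dict[str, float]
    flags: dict[str, dict] = field(default_factory=dict)
    formulas: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, list] = field(default_factory=dict)
    history: list = field(default_factory=list)
    reference: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_diet(cls, diet: DietDefinition) -> "Medium":
        if any(v < 0 for v in diet.entries.values()):
            raise ValueError("diet fluxes must be nonnegative")
        return cls(
            entries=dict(diet.entries),
            flags=copy.deepcopy(diet.flags),
            formulas=dict(diet.formulas),
            provenance={m: [f"diet:{diet.name}"] for m in diet.entries},
            history=[],
            reference=dict(diet.entries),
        )

    def get(self, metabolite: str, default: float = 0.0) -> float:
        return self.entries.get(metabolite, default)

    def flag(self, metabolite: str, name: str) -> bool:
        return bool(self.flags.get(metabolite, {}).get(name, False))

    def carbon(self, metabolite: str) -> int:
        formula = self.formulas.get(metabolite)
        if formula:
            return carbon_count(formula)
        if self.flags.get(metabolite, {}).get("carbon_source_override"):
            return 1
        return 0

    def _evolve(self, entries: dict, note_for: dict, step: dict) -> "Medium":
        new = Medium(
            entries=entries,
            flags=copy.deepcopy(self.flags),
            formulas=dict(self.formulas),
            provenance=copy.deepcopy(self.provenance),
            history=copy.deepcopy(self.history) + [step],
            reference=dict(self.reference),
        )
        for m, note in note_for.items():
            new.provenance.setdefault(m, []).append(note)
        return new


# ------------------------------------------------------------ transforms

def apply_host_absorption(diet: DietDefinition | Medium,
                          retain: float = HOST_ABSORPTION_RETAIN) -> Medium:
    """Dilute host-absorbable components to ``retain`` (default 20%) of their
    dietary flux, modeling absorption in the small intestine."""
    if not 0 < retain <= 1:
        raise ValueError("retain must be in (0, 1]")
    medium = diet if isinstance(diet, Medium) else Medium.from_diet(diet)
    entries = dict(medium.entries)
    notes = {}
    for m in entries:
        if medium.flag(m, "host_absorbable"):
            entries[m] *= retain
            notes[m] = f"host_absorption:x{retain:g}"
    return medium._evolve(entries, notes,
                          {"op": "apply_host_absorption", "retain": retain})


def add_host_metabolites(medium: Medium, host_set: dict[str, float],
                         formulas: dict[str, str] | None = None) -> Medium:
    """Add host-supplied metabolites (mucins, bile acids...). Existing entries
    keep the larger of their current and host-supplied flux."""
    if any(v < 0 for v in host_set.values()):
        raise ValueError("host fluxes must be nonnegative")
    entries = dict(medium.entries)
    notes = {}
    out = medium._evolve(entries, notes, {"op": "add_host_metabolites",
                                          "host_set": dict(host_set),
                                          "formulas": dict(formulas or {})})
    for m, flux in host_set.items():
        if m in out.entries:
            merged = max(out.entries[m], flux)
            out.provenance.setdefault(m, []).append(
                f"host_supply:merge_max({out.entries[m]:g},{flux:g})")
            out.entries[m] = merged
        else:
            out.entries[m] = flux
            out.provenance.setdefault(m, []).append(f"host_supply:{flux:g}")
        row = out.flags.setdefault(m, dict.fromkeys(FLAG_NAMES, False))
        row["host_supplied"] = True
        if formulas and m in formulas:
            out.formulas[m] = formulas[m]
    return out


def _completion_lp(model, entries: dict[str, float], growth_floor: float,
                   candidates: set[str]) -> dict[str, float]:
    """Minimal added import flux so ``model`` grows at >= growth_floor.

    LP over (fluxes v, slacks e >= 0): min sum(e) s.t. S v = 0,
    v_EX(m) >= -(medium(m) + e_m) for candidate m, biomass >= floor.
    Duck-types over TaxonModel and CommunityModel (which provides its own
    ``_completion_lp_parts``).
    """
    if isinstance(model, TaxonModel):
        S, _, rxn_ids = _stoichiometric_matrix(model)
        lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
        ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
        ex_cols = {model.reactions[r].exchange_metabolite: j
                   for j, r in enumerate(rxn_ids)
                   if model.reactions[r].is_exchange}
        biomass_obj = np.zeros(len(rxn_ids))
        biomass_obj[rxn_ids.index(model.biomass_reaction_id)] = 1.0
        name = model.taxon_id
    else:  # CommunityModel-compatible object
        S, lb, ub, ex_cols, biomass_obj, name = model._completion_lp_parts()
        lb, ub = lb.copy(), ub.copy()

    n = S.shape[1]
    cand = sorted(candidates & set(ex_cols))
    k = len(cand)
    # medium availability for non-candidate exchanged metabolites
    for m, j in ex_cols.items():
        if m not in candidates:
            lb[j] = max(lb[j], -entries.get(m, 0.0))
    A_ub_rows, b_ub = [], []
    for i, m in enumerate(cand):
        row = np.zeros(n + k)
        row[ex_cols[m]] = -1.0
        row[n + i] = -1.0
        A_ub_rows.append(row)           # -v - e <= medium(m)
        b_ub.append(entries.get(m, 0.0))
    growth_row = np.zeros(n + k)
    growth_row[:n] = -biomass_obj
    A_ub_rows.append(growth_row)        # biomass >= floor
    b_ub.append(-growth_floor)

    c = np.concatenate([np.zeros(n), np.ones(k)])
    bounds = list(zip(lb, ub)) + [(0.0, UNBOUNDED)] * k
    res = linprog(c, A_ub=np.array(A_ub_rows), b_ub=np.array(b_ub),
                  A_eq=np.hstack([S, np.zeros((S.shape[0], k))]),
                  b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if not res.success:
        raise CompletionInfeasibleError(
            f"medium completion infeasible for model {name}: {res.message}"
        )
    e = res.x[n:]
    return {m: float(e[i]) for i, m in enumerate(cand) if e[i] > _EPS}


def _all_candidates(models) -> set[str]:
    out: set[str] = set()
    for model in models:
        if isinstance(model, TaxonModel):
            out |= set(model.exchanged_metabolites)
        else:
            out |= set(model._completion_lp_parts()[3])
    return out


def complete_medium(medium: Medium, models,
                    growth_floor: float = GROWTH_FLOOR_DEFAULT,
                    candidates: set[str] | None = None,
                    ) -> tuple[Medium, dict[str, float]]:
    """Augment the medium with a minimal set of import fluxes so every model
    reaches the growth floor.

    Minimality is minimum total added flux (one LP per model); the union of
    per-model additions (max over models per metabolite) is applied. Returns
    ``(completed_medium, additions)``; additions below 1e-9 are treated as
    zero, so completing an already-complete medium is the identity.
    """
    if growth_floor <= 0:
        raise ValueError("growth_floor must be positive")
    models = list(models)
    if candidates is None:
        candidates = _all_candidates(models)
    additions: dict[str, float] = {}
    for model in models:
        for m, e in _completion_lp(model, medium.entries, growth_floor,
                                   set(candidates)).items():
            additions[m] = max(additions.get(m, 0.0), e)
    out = _apply_additions(medium, additions)
    return out, additions


def _apply_additions(medium: Medium, additions: dict[str, float]) -> Medium:
    entries = dict(medium.entries)
    notes = {}
    for m, e in additions.items():
        entries[m] = entries.get(m, 0.0) + e
        notes[m] = f"completion:+{e:.12g}"
    return medium._evolve(entries, notes,
                          {"op": "complete", "additions": dict(additions)})


def strip_carbon(medium: Medium) -> Medium:
    """Remove carbon sources, keeping residual fiber and host-supplied entries.

    A metabolite counts as a carbon source when its formula contains carbon or
    its ``carbon_source_override`` flag is set; formula-free metabolites are
    treated as carbon-free.
    """
    entries = {}
    notes = {}
    for m, flux in medium.entries.items():
        keep = (medium.carbon(m) == 0
                or medium.flag(m, "residual_fiber")
                or medium.flag(m, "host_supplied"))
        if keep:
            entries[m] = flux
        else:
            notes[m] = "strip_carbon:removed"
    return medium._evolve(entries, notes, {"op": "strip_carbon"})


def dilute(medium: Medium, factor: float = FECAL_DILUTION,
           fiber_dilution: float | None = None) -> Medium:
    """Dilute all components to ``factor`` (default 10%) of their flux.

    Residual-fiber entries are instead reset to their dietary value divided by
    the study's slurry ``fiber_dilution`` (e.g. 5 for a 1:5 homogenate), since
    indigestible fiber persists in stool at dietary levels and is only diluted
    by sample preparation.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    if fiber_dilution is not None and fiber_dilution <= 0:
        raise ValueError("fiber_dilution must be positive")
    entries = {}
    notes = {}
    for m, flux in medium.entries.items():
        if medium.flag(m, "residual_fiber") and fiber_dilution is not None:
            entries[m] = medium.reference.get(m, flux) / fiber_dilution
            notes[m] = f"fiber_dilution:diet/{fiber_dilution:g}"
        else:
            entries[m] = flux * factor
            notes[m] = f"dilute:x{factor:g}"
    return medium._evolve(entries, notes, {"op": "dilute", "factor": factor,
                                           "fiber_dilution": fiber_dilution})


def supplement_fiber(medium: Medium, fiber: str,
                     amount: float | None = None) -> Medium:
    """Set a single-fiber supplement bound (pectin 1.0, inulin 10.0, FOS 100
    mmol/gDW/h by default)."""
    key = fiber.lower()
    if key not in FIBER_DEFAULTS:
        raise ValueError(
            f"unknown fiber {fiber!r}; expected one of {sorted(FIBER_DEFAULTS)}"
        )
    value = FIBER_DEFAULTS[key] if amount is None else float(amount)
    entries = dict(medium.entries)
    entries[key] = value
    out = medium._evolve(entries, {key: f"supplement:{value:g}"},
                         {"op": "supplement_fiber", "fiber": key,
                          "amount": amount})
    out.flags.setdefault(key, dict.fromkeys(FLAG_NAMES, False))
    return out


# ------------------------------------------------------------ recipes

def build_medium(diet: DietDefinition, recipe: str, *,
                 models=None,
                 retain: float = HOST_ABSORPTION_RETAIN,
                 host_metabolites: dict[str, float] | None = None,
                 host_formulas: dict[str, str] | None = None,
                 growth_floor: float = GROWTH_FLOOR_DEFAULT,
                 candidates: set[str] | None = None,
                 dilution: float = FECAL_DILUTION,
                 fiber_dilution: float | None = None,
                 supplement: str | None = None,
                 supplement_amount: float | None = None) -> Medium:
    """Build a medium with the ``in_vivo`` or ``ex_vivo`` recipe.

    ``in_vivo``: absorption -> host metabolites -> completion.
    ``ex_vivo``: the above, then carbon stripping and dilution; requires
    ``fiber_dilution`` (the study's slurry dilution factor). An optional
    single-fiber ``supplement`` is applied last. Completion runs only when
    ``models`` is given; the growth-floor guarantee holds on the pre-strip
    medium.
    """
    if recipe not in ("in_vivo", "ex_vivo"):
        raise ValueError(f"unknown recipe {recipe!r}")
    medium = apply_host_absorption(diet, retain)
    if host_metabolites:
        medium = add_host_metabolites(medium, host_metabolites, host_formulas)
    if models is not None:
        medium, _ = complete_medium(medium, models, growth_floor, candidates)
    if recipe == "ex_vivo":
        if fiber_dilution is None:
            raise ValueError("ex_vivo recipe requires fiber_dilution")
        medium = strip_carbon(medium)
        medium = dilute(medium, dilution, fiber_dilution)
    if supplement is not None:
        medium = supplement_fiber(medium, supplement, supplement_amount)
    return medium


def replay(diet: DietDefinition, history: list) -> Medium:
    """Re-apply a recorded transformation history to a raw diet.

    Completion steps re-apply their recorded additions (not a fresh LP), so
    replay reproduces the built medium bit-exactly.
    """
    medium = Medium.from_diet(diet)
    for step in history:
        op = step["op"]
        if op == "apply_host_absorption":
            medium = apply_host_absorption(medium, step["retain"])
        elif op == "add_host_metabolites":
            medium = add_host_metabolites(medium, step["host_set"],
                                          step.get("formulas") or None)
        elif op == "complete":
            medium = _apply_additions(medium, step["additions"])
        elif op == "strip_carbon":
            medium = strip_carbon(medium)
        elif op == "dilute":
            medium = dilute(medium, step["factor"], step["fiber_dilution"])
        elif op == "supplement_fiber":
            medium = supplement_fiber(medium, step["fiber"], step["amount"])
        else:
            raise ValueError(f"unknown history op {op!r}")
    return medium


def assert_growth_floor(medium: Medium, models,
                        growth_floor: float = GROWTH_FLOOR_DEFAULT,
                        tol: float = 1e-6) -> None:
    """Raise unless every taxon model reaches the growth floor on medium."""
    for model in models:
        mu = fba_optimum(model, medium=medium.entries)
        if mu < growth_floor - tol:
            raise ValidationError(
                f"model {model.taxon_id} grows at {mu:.4g} < floor "
                f"{growth_floor:g} on medium"
            )


# ------------------------------------------------------------ TSV I/O

def read_diet_tsv(path, name: str | None = None) -> DietDefinition:
    """Read a diet table: columns metabolite, flux, and optional boolean flag
    columns (host_absorbable, host_supplied, residual_fiber) and formula."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"metabolite", "flux"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: diet table needs columns {sorted(required)}")
    entries, flags, formulas = {}, {}, {}
    for _, row in df.iterrows():
        m = str(row["metabolite"])
        entries[m] = float(row["flux"])
        flags[m] = {k: bool(row[k]) for k in FLAG_NAMES if k in df.columns}
        if "formula" in df.columns and isinstance(row["formula"], str):
            formulas[m] = row["formula"]
    return DietDefinition(name or path.stem, entries, flags, formulas)


def write_diet_tsv(diet: DietDefinition, path) -> None:
    rows = []
    for m, flux in diet.entries.items():
        row = {"metabolite": m, "flux": flux}
        row.update({k: diet.flag(m, k) for k in FLAG_NAMES})
        row["formula"] = diet.formulas.get(m, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def medium_to_frame(medium: Medium) -> pd.DataFrame:
    """Medium as a tidy table (metabolite, flux, provenance)."""
    return pd.DataFrame(
        [{"metabolite": m, "flux": flux,
          "provenance": ";".join(medium.provenance.get(m, []))}
         for m, flux in sorted(medium.entries.items())]
    )


def host_metabolite_defaults() -> tuple[dict[str, float], dict[str, str]]:
    """A small default host-supplied set (mucin glycans, primary bile acids)."""
    fluxes = {"mucin": 1.0, "bile_acid": 0.1}
    formulas = {"mucin": "C30H50N2O20", "bile_acid": "C24H40O4"}
    return fluxes, formulas
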