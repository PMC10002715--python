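"""Domain types for single-taxon genome-scale metabolic models (GEMs).

A :class:`TaxonModel` is a stoichiometric reaction network for one taxon:
metabolites, reactions with flux bounds in mmol/gDW/h, exactly one biomass
reaction (whose flux is the growth rate in 1/h), and exchange reactions that
move metabolites across the model boundary.

Sign convention, used everywhere in this package: an exchange reaction touches
exactly one metabolite with stoichiometric coefficient -1, and **positive flux
means secretion** to the environment; uptake is a negative flux bounded below
by the medium.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "TaxonModel",
    "Violation",
    "FormulaError",
    "ValidationError",
    "parse_formula",
    "carbon_count",
    "validate_model",
    "fba_optimum",
]

#: Upper bound used as the conventional "unbounded" sentinel (mmol/gDW/h).
UNBOUNDED = 1000.0

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """An elemental formula string that does not tokenize."""


class ValidationError(ValueError):
    """A model violating a structural invariant where an exception is required."""


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``annotations`` carries boolean/string flags used by the medium builder:
    ``host_absorbable``, ``host_supplied``, ``residual_fiber`` and
    ``carbon_source_override``.
    """

    id: str
    name: str = ""
    compartment: str = "e"
    formula: str | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be nonempty")
        if self.formula:
            parse_formula(self.formula)  # raises FormulaError if malformed


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds in mmol/gDW/h.

    ``stoichiometry`` maps metabolite id to a signed coefficient; negative
    means consumed. Exchange reactions have exactly one metabolite with
    coefficient -1 (positive flux = secretion).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = UNBOUNDED
    is_exchange: bool = False
    is_biomass: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be nonempty")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id}: empty stoichiometry")
        self.stoichiometry = {m: float(c) for m, c in self.stoichiometry.items()}
        self.lower_bound = float(self.lower_bound)
        self.upper_bound = float(self.upper_bound)

    @property
    def exchange_metabolite(self) -> str:
        """The single boundary metabolite of an exchange reaction."""
        if not self.is_exchange:
            raise ValueError(f"{self.id} is not an exchange reaction")
        (met,) = self.stoichiometry
        return met


@dataclass
class TaxonModel:
    """One taxon's GEM at genus or species rank."""

    taxon_id: str
    rank: str  # {"genus", "species"}
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str

    @classmethod
    def from_parts(
        cls,
        taxon_id: str,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        rank: str = "genus",
    ) -> "TaxonModel":
        biomass = [r.id for r in reactions if r.is_biomass]
        if len(biomass) != 1:
            raise ValidationError(
                f"model {taxon_id}: expected exactly one biomass reaction, "
                f"found {len(biomass)}"
            )
        model = cls(
            taxon_id=taxon_id,
            rank=rank,
            metabolites={m.id: m for m in metabolites},
            reactions={r.id: r for r in reactions},
            biomass_reaction_id=biomass[0],
        )
        dangling = [
            (r.id, m)
            for r in reactions
            for m in r.stoichiometry
            if m not in model.metabolites
        ]
        if dangling:
            rid, mid = dangling[0]
            raise ValidationError(
                f"model {taxon_id}: reaction {rid} references unknown metabolite {mid}"
            )
        return model

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    @property
    def exchanged_metabolites(self) -> list[str]:
        return [r.exchange_metabolite for r in self.exchange_reactions]


@dataclass
class Violation:
    """A structural or functional defect found by :func:`validate_model`."""

    code: str
    target: str
    message: str


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into element -> count.

    Element symbols are one uppercase letter optionally followed by one
    lowercase letter (``Cu`` is copper, not carbon + u). Counts default to 1.
    Repeated elements are summed, so the result is additive over concatenated
    fragments and invariant to element order.
    """
    if not formula:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _ELEMENT_RE.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable formula {formula!r} at position {pos}"
            )
        element, digits = match.groups()
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count in formula {formula!r}")
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
    return counts


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a formula; 0 when carbon is absent."""
    return parse_formula(formula).get("C", 0)


def metabolite_carbon(met: Metabolite) -> int:
    """Carbon count for a metabolite; formula-free metabolites count as 0
    unless flagged ``carbon_source_override`` (then treated as 1)."""
    if met.formula:
        return carbon_count(met.formula)
    if met.annotations.get("carbon_source_override"):
        return 1
    return 0


def _stoichiometric_matrix(model: TaxonModel):
    """Dense S (metabolites x reactions) plus ordered id lists."""
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            S[met_index[met], j] = coef
    return S, met_ids, rxn_ids


def fba_optimum(
    model: TaxonModel,
    medium: dict[str, float] | None = None,
    open_exchanges: bool = False,
) -> float:
    """Classic single-organism FBA: maximal biomass flux (1/h).

    ``medium`` maps exchanged metabolite id to a maximal import flux; exchange
    lower bounds become ``-medium[m]`` (0 when absent). With
    ``open_exchanges`` all exchange lower bounds are opened to -UNBOUNDED
    instead.
    """
    S, _, rxn_ids = _stoichiometric_matrix(model)
    lb, ub = [], []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        lo, hi = rxn.lower_bound, rxn.upper_bound
        if rxn.is_exchange:
            if open_exchanges:
                lo = -UNBOUNDED
            elif medium is not None:
                lo = max(lo, -medium.get(rxn.exchange_metabolite, 0.0))
        lb.append(lo)
        ub.append(hi)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.biomass_reaction_id)] = -1.0
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)),
        method="highs",
    )
    if not res.success:
        raise ValidationError(
            f"model {model.taxon_id}: FBA LP failed ({res.message})"
        )
    return -res.fun


def validate_model(model: TaxonModel) -> list[Violation]:
    """Structural + functional validation; returns violations as data.

    The functional check asks whether the network can carry nonzero biomass
    flux at all under fully opened exchanges — a guard against blocked biomass
    precursors of the kind semi-curated database models are known to contain.
    """
    out: list[Violation] = []
    biomass = [r for r in model.reactions.values() if r.is_biomass]
    if len(biomass) != 1:
        out.append(
            Violation("biomass_count", model.taxon_id,
                      f"expected 1 biomass reaction, found {len(biomass)}")
        )
    compartments = {m.compartment for m in model.metabolites.values()}
    for rxn in model.reactions.values():
        if rxn.lower_bound > rxn.upper_bound:
            out.append(Violation("inverted bounds", rxn.id,
                                 f"lower_bound {rxn.lower_bound} > "
                                 f"upper_bound {rxn.upper_bound}"))
        for met in rxn.stoichiometry:
            if met not in model.metabolites:
                out.append(Violation("dangling_metabolite", rxn.id,
                                     f"unknown metabolite {met}"))
            elif not rxn.is_exchange:
                if model.metabolites[met].compartment not in compartments:
                    out.append(Violation("foreign_compartment", rxn.id,
                                         f"metabolite {met} outside model"))
        if rxn.is_exchange:
            coefs = list(rxn.stoichiometry.values())
            if len(coefs) != 1 or coefs[0] != -1:
                out.append(Violation("bad_exchange", rxn.id,
                                     "exchange must touch one metabolite "
                                     "with coefficient -1"))
    if out:
        return out  # structure broken; the LP below could be ill-posed
    try:
        mu = fba_optimum(model, open_exchanges=True)
    except ValidationError as err:
        out.append(Violation("infeasible", model.taxon_id, str(err)))
        return out
    if mu <= 1e-9:
        out.append(Violation("biomass blocked", model.taxon_id,
                             "no flux distribution yields nonzero biomass "
                             "under unconstrained exchanges"))
    return out
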