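"""Abundance-weighted community model assembly.

A :class:`CommunityModel` is the union of taxon GEMs coupled through one
shared external compartment. Each taxon's network keeps its own namespaced
compartment (fluxes in mmol per gDW of *that taxon* per hour); its exchange
reactions are rewired into transfer reactions whose contribution to the
shared mass balance is scaled by the taxon's relative abundance a_i, so
community-level exchange fluxes are per gDW of *community*. Community growth
is the abundance-weighted sum of taxon growth rates, mu_c = sum_i a_i mu_i.

The class follows the model/results idiom: build it from data
(``CommunityModel.build``) and call :meth:`CommunityModel.fit` to run the
two-step cooperative-tradeoff FBA, which returns a
:class:`~mcmm.ctfba.CommunityFluxResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gem_core import TaxonModel, UNBOUNDED
from .medium import Medium

__all__ = [
    "AbundanceProfile",
    "CommunityModel",
    "EmptyCommunityError",
    "NoModelsError",
    "AssemblyError",
    "filter_and_normalize",
    "match_models",
    "assemble",
    "read_abundance_table",
]

log = logging.getLogger(__name__)

ABUNDANCE_CUTOFF_DEFAULT = 0.001  # drop taxa below 0.1% relative abundance
MATCHED_FRACTION_FLOOR = 0.5

_NORM_TOL = 1e-9


class EmptyCommunityError(ValueError):
    """All taxa removed by the abundance cutoff."""


class NoModelsError(ValueError):
    """No taxon in the profile has a model in the library."""


class AssemblyError(ValueError):
    """Namespace collision or inconsistent inputs during assembly."""


@dataclass
class AbundanceProfile:
    """Relative abundances for one sample at one taxonomic rank."""

    sample_id: str
    entries: dict[str, float]
    rank: str = "genus"

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.entries.values()):
            raise ValueError("relative abundances must be positive")

    def normalized(self) -> "AbundanceProfile":
        total = sum(self.entries.values())
        return AbundanceProfile(
            self.sample_id,
            {t: a / total for t, a in self.entries.items()},
            self.rank,
        )

    @property
    def is_normalized(self) -> bool:
        return abs(sum(self.entries.values()) - 1.0) <= _NORM_TOL


def filter_and_normalize(profile: AbundanceProfile,
                         cutoff: float = ABUNDANCE_CUTOFF_DEFAULT
                         ) -> AbundanceProfile:
    """Drop taxa below the relative-abundance cutoff and renormalize.

    The default cutoff 0.001 omits taxa under 0.1% relative abundance.
    """
    if not 0 <= cutoff < 1:
        raise ValueError("cutoff must be in [0, 1)")
    kept = {t: a for t, a in profile.entries.items() if a >= cutoff}
    removed = len(profile.entries) - len(kept)
    if not kept:
        raise EmptyCommunityError(
            f"sample {profile.sample_id}: all {removed} taxa below cutoff "
            f"{cutoff}"
        )
    if removed:
        log.info("sample %s: removed %d taxa below abundance cutoff %g",
                 profile.sample_id, removed, cutoff)
    return AbundanceProfile(profile.sample_id, kept, profile.rank).normalized()


def match_models(profile: AbundanceProfile, library,
                 floor: float = MATCHED_FRACTION_FLOOR
                 ) -> tuple[dict[str, TaxonModel], float]:
    """Exact-identifier matching of profile taxa against a model library.

    Returns the matched models and the fraction of abundance mass they cover
    (before renormalization). A matched fraction of zero is an error; one
    below ``floor`` only logs a warning.
    """
    models: dict[str, TaxonModel] = {}
    for model in library:
        if model.taxon_id in models:
            raise AssemblyError(
                f"library holds two models for taxon {model.taxon_id!r}"
            )
        models[model.taxon_id] = model
    norm = profile.normalized()
    matches = {t: models[t] for t in norm.entries if t in models}
    unmatched = {t: a for t, a in norm.entries.items() if t not in models}
    matched_fraction = sum(norm.entries[t] for t in matches)
    if not matches:
        raise NoModelsError(
            f"sample {profile.sample_id}: no taxon matched the model library"
        )
    for t, a in unmatched.items():
        log.info("sample %s: taxon %s (abundance %.4g) has no model",
                 profile.sample_id, t, a)
    if matched_fraction < floor:
        log.warning("sample %s: only %.1f%% of abundance mass matched models",
                    profile.sample_id, 100 * matched_fraction)
    return matches, matched_fraction


@dataclass
class _Column:
    kind: str  # {"internal", "transfer", "community_exchange"}
    taxon: str | None
    reaction_id: str
    metabolite: str | None  # exchanged metabolite for transfer/exchange cols


@dataclass
class CommunityModel:
    """Abundance-weighted union of taxon models over one shared environment.

    The compiled representation is a dense stoichiometric matrix ``S`` (rows:
    namespaced taxon metabolites then shared metabolites; columns: taxon
    internal reactions, taxon<->shared transfers, community exchanges) with
    flux bounds ``lb``/``ub``.
    """

    sample_id: str
    members: list  # [(TaxonModel, a_i)]
    medium: Medium
    matched_fraction: float
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    row_ids: list
    columns: list
    biomass_col: dict
    community_ex_col: dict
    shared_metabolites: list = field(default_factory=list)

    # -------------------------------------------------------- construction
    @classmethod
    def build(cls, profile: AbundanceProfile, library, medium: Medium,
              cutoff: float = ABUNDANCE_CUTOFF_DEFAULT) -> "CommunityModel":
        """filter -> match -> renormalize over matched taxa -> assemble."""
        filtered = filter_and_normalize(profile, cutoff)
        matches, matched_fraction = match_models(filtered, library)
        kept = AbundanceProfile(
            filtered.sample_id,
            {t: filtered.entries[t] for t in matches},
            filtered.rank,
        ).normalized()
        return assemble(kept, matches, medium,
                        matched_fraction=matched_fraction)

    @property
    def abundances(self) -> dict[str, float]:
        return {m.taxon_id: a for m, a in self.members}

    @property
    def objective(self) -> np.ndarray:
        """Community growth objective: a_i on each taxon biomass column."""
        c = np.zeros(self.S.shape[1])
        for model, a in self.members:
            c[self.biomass_col[model.taxon_id]] = a
        return c

    def with_medium(self, medium: Medium) -> "CommunityModel":
        """Same community, different medium (community-exchange lower bounds)."""
        lb = self.lb.copy()
        for met, j in self.community_ex_col.items():
            lb[j] = -medium.get(met, 0.0)
        return CommunityModel(
            self.sample_id, self.members, medium, self.matched_fraction,
            self.S, lb, self.ub.copy(), self.row_ids, self.columns,
            self.biomass_col, self.community_ex_col, self.shared_metabolites,
        )

    def _completion_lp_parts(self):
        """Hook for the medium-completion LP: bounds with community imports
        closed (candidates are relaxed by the LP itself)."""
        lb = self.lb.copy()
        for j in self.community_ex_col.values():
            lb[j] = 0.0
        return (self.S, lb, self.ub.copy(), dict(self.community_ex_col),
                self.objective, self.sample_id)

    # -------------------------------------------------------- fitting
    def fit(self, tradeoff: float = 0.7):
        """Two-step cooperative-tradeoff FBA; returns CommunityFluxResults."""
        from .ctfba import fit_community

        return fit_community(self, tradeoff=tradeoff)


def assemble(profile: AbundanceProfile, matches: dict[str, TaxonModel],
             medium: Medium, matched_fraction: float = 1.0) -> CommunityModel:
    """Assemble the compiled community model.

    ``profile`` must be normalized over exactly the matched taxa. Each taxon
    exchange for metabolite m becomes a transfer column with coefficient -1 on
    the taxon's own m and +a_i on shared m; each shared metabolite gets one
    community exchange with lower bound -medium(m) and upper bound 1000.
    """
    if not profile.is_normalized:
        raise AssemblyError(
            f"sample {profile.sample_id}: profile not normalized over matched "
            f"taxa (sum={sum(profile.entries.values()):.12g})"
        )
    if set(profile.entries) != set(matches):
        raise AssemblyError("profile taxa and matched models disagree")

    members = [(matches[t], profile.entries[t]) for t in sorted(matches)]

    row_ids: list[str] = []
    row_index: dict[str, int] = {}

    def add_row(rid: str) -> int:
        if rid in row_index:
            raise AssemblyError(f"duplicate namespaced id {rid!r}")
        row_index[rid] = len(row_ids)
        row_ids.append(rid)
        return row_index[rid]

    shared = sorted({m for model, _ in members
                     for m in model.exchanged_metabolites})
    for model, _ in members:
        for met in model.metabolites:
            add_row(f"{model.taxon_id}::{met}")
    for met in shared:
        add_row(f"ext::{met}")

    columns: list[_Column] = []
    entries: list[tuple[int, int, float]] = []
    lb, ub = [], []
    biomass_col: dict[str, int] = {}

    def add_col(col: _Column, stoich: dict[int, float],
                lo: float, hi: float) -> int:
        j = len(columns)
        columns.append(col)
        for i, coef in stoich.items():
            entries.append((i, j, coef))
        lb.append(lo)
        ub.append(hi)
        return j

    for model, a in members:
        tax = model.taxon_id
        for rxn in model.reactions.values():
            if rxn.is_exchange:
                met = rxn.exchange_metabolite
                j = add_col(
                    _Column("transfer", tax, rxn.id, met),
                    {row_index[f"{tax}::{met}"]: -1.0,
                     row_index[f"ext::{met}"]: a},
                    rxn.lower_bound, rxn.upper_bound,
                )
            else:
                j = add_col(
                    _Column("internal", tax, rxn.id, None),
                    {row_index[f"{tax}::{met}"]: coef
                     for met, coef in rxn.stoichiometry.items()},
                    rxn.lower_bound, rxn.upper_bound,
                )
            if rxn.id == model.biomass_reaction_id:
                biomass_col[tax] = j

    community_ex_col: dict[str, int] = {}
    for met in shared:
        j = add_col(
            _Column("community_exchange", None, f"EX_{met}__community", met),
            {row_index[f"ext::{met}"]: -1.0},
            -medium.get(met, 0.0), UNBOUNDED,
        )
        community_ex_col[met] = j

    S = np.zeros((len(row_ids), len(columns)))
    for i, j, coef in entries:
        S[i, j] = coef

    return CommunityModel(
        sample_id=profile.sample_id,
        members=members,
        medium=medium,
        matched_fraction=matched_fraction,
        S=S,
        lb=np.array(lb, dtype=float),
        ub=np.array(ub, dtype=float),
        row_ids=row_ids,
        columns=columns,
        biomass_col=biomass_col,
        community_ex_col=community_ex_col,
        shared_metabolites=shared,
    )


def read_abundance_table(path) -> list[AbundanceProfile]:
    """Read a tidy abundance table (sample_id, taxon, relative_abundance)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "taxon", "relative_abundance"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: abundance table needs columns {sorted(required)}")
    rank = str(df["rank"].iloc[0]) if "rank" in df.columns and len(df) else "genus"
    profiles = []
    for sample_id, group in df.groupby("sample_id", sort=True):
        profiles.append(AbundanceProfile(
            str(sample_id),
            dict(zip(group["taxon"].astype(str),
                     group["relative_abundance"].astype(float))),
            rank,
        ))
    return profiles
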