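"""Genome-scale metabolic model container and stoichiometric system.

A metabolic network is represented as a list of :class:`Reaction` objects over
a list of metabolites.  The steady-state flux polytope is the convex set

    {v : S v = 0,  lb <= v <= ub}

where ``S`` is the m x n stoichiometric matrix (rows = metabolites, columns =
reactions, negative coefficients = consumption).  Exchange reactions are
boundary pseudo-reactions touching a single metabolite; by convention a
negative exchange flux is uptake and a positive one secretion.

Fluxes are in mmol gDW^-1 h^-1 throughout the package.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field

import numpy as np

#: Default magnitude for unspecified reaction bounds (standard CBM convention).
DEFAULT_BOUND = 1000.0

_GPR_SPLIT = re.compile(r"[^\s()]+")


class ModelValidationError(ValueError):
    """The model violates a structural invariant (duplicate ids, bad bounds...)."""


class ModelParseError(ValueError):
    """A model file could not be read in the requested format."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and annotations.

    ``stoichiometry`` maps metabolite id to a signed coefficient; all
    coefficients must be nonzero.  ``gene_association`` is a raw boolean
    expression over gene names (e.g. ``"PDC1 or PDC5"``); it is kept as a
    string and only gene-name extraction is supported.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_association: str = ""
    subsystem: str = ""

    def genes(self) -> set[str]:
        """Gene names appearing in the boolean gene association."""
        toks = _GPR_SPLIT.findall(self.gene_association)
        return {t for t in toks if t.lower() not in ("and", "or")}

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    model_id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_reaction_id: str | None = None

    # -- indexing -----------------------------------------------------------

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index()[rid]
        except KeyError:
            raise KeyError(f"no reaction with id {rid!r} in model {self.model_id!r}")

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index()

    def _rxn_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def gene_count(self) -> int:
        return len(self.genes())

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes()
        return out

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on failure."""
        rids = self.reaction_ids()
        if len(rids) != len(set(rids)):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        mids = self.metabolite_ids()
        if len(mids) != len(set(mids)):
            dup = sorted({m for m in mids if mids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        known = set(mids)
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id!r} has empty stoichiometry")
            for mid, coeff in r.stoichiometry.items():
                if mid not in known:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
                if coeff == 0:
                    raise ModelValidationError(
                        f"reaction {r.id!r} has zero coefficient for {mid!r}"
                    )
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} > upper bound "
                    f"{r.upper_bound}"
                )


@dataclass
class StoichiometricSystem:
    """Dense stoichiometric matrix plus bounds, defining the flux polytope."""

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)


# ---------------------------------------------------------------------------
# operations


def build_stoichiometric_system(model: MetabolicModel) -> StoichiometricSystem:
    """Assemble S, lb, ub preserving the model's reaction and metabolite order."""
    model.validate()
    mids = model.metabolite_ids()
    midx = {m: i for i, m in enumerate(mids)}
    n, m = len(model.reactions), len(mids)
    S = np.zeros((m, n))
    lb = np.empty(n)
    ub = np.empty(n)
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.stoichiometry.items():
            S[midx[mid], j] = coeff
        lb[j] = r.lower_bound
        ub[j] = r.upper_bound
    return StoichiometricSystem(S, lb, ub, model.reaction_ids(), mids)


def find_exchange_reactions(model: MetabolicModel) -> list[str]:
    """Reactions touching exactly one metabolite (boundary exchanges).

    Detection is structural, not id-prefix based, so it works for any naming
    convention and either orientation ("glc ->" or "-> glc").
    """
    return [r.id for r in model.reactions if len(r.stoichiometry) == 1]


def model_summary(model: MetabolicModel) -> tuple[int, int, int]:
    """(n_metabolites, n_reactions, n_genes) with genes counted uniquely."""
    return len(model.metabolites), len(model.reactions), model.gene_count


# ---------------------------------------------------------------------------
# I/O


def read_model(path: str, format: str = "sbml") -> MetabolicModel:
    """Read a model from ``path`` in the given format ("sbml" or "internal-json").

    SBML Level 3 (with the fbc package for bounds and gene associations) is
    read through cobrapy/libsbml.  Reactions lacking explicit bounds receive
    the package defaults: (-1000, 1000) if reversible, (0, 1000) otherwise.
    """
    if format == "sbml":
        return _read_sbml(path)
    if format == "internal-json":
        return read_model_json(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_sbml(path: str) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(path)
    except Exception as exc:  # cobra raises various libsbml/IO errors
        raise ModelParseError(f"cannot parse SBML file {path!r}: {exc}") from exc
    return from_cobra(cm)


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy model to the package's container."""
    mets = [Metabolite(m.id, m.name or "", m.compartment or "c") for m in cm.metabolites]
    rxns = []
    for r in cm.reactions:
        rxns.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gene_association=r.gene_reaction_rule or "",
                subsystem=r.subsystem or "",
            )
        )
    biomass = None
    for r in cm.reactions:
        if r.objective_coefficient:
            biomass = r.id
            break
    if biomass is None:
        for r in cm.reactions:
            if "biomass" in r.id.lower() or "biomass" in (r.name or "").lower():
                biomass = r.id
                break
    model = MetabolicModel(cm.id or "model", mets, rxns, biomass)
    model.validate()
    return model


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML export of small models)."""
    import cobra

    cm = cobra.Model(model.model_id)
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[mid]: c for mid, c in r.stoichiometry.items()})
        if r.gene_association:
            cr.gene_reaction_rule = r.gene_association
        if r.subsystem:
            cr.subsystem = r.subsystem
    if model.biomass_reaction_id is not None:
        cm.objective = model.biomass_reaction_id
    return cm


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write a (small) model as SBML L3/fbc via cobrapy."""
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), path)


def write_model_json(model: MetabolicModel, path: str) -> None:
    payload = {
        "model_id": model.model_id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_association": r.gene_association,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_model_json(path: str) -> MetabolicModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"cannot parse JSON model {path!r}: {exc}") from exc
    model = MetabolicModel(
        model_id=payload["model_id"],
        metabolites=[Metabolite(**m) for m in payload["metabolites"]],
        reactions=[Reaction(**r) for r in payload["reactions"]],
        biomass_reaction_id=payload.get("biomass_reaction_id"),
    )
    model.validate()
    return model
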