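"""Enological (anaerobic) model setup and measured-flux constraint fixing.

Wine fermentations are anaerobic: the oxygen exchange is closed, sterol and
oleate uptakes are opened (yeast cannot synthesise them without oxygen, so
anaerobic media supply them), respiratory shuttle reactions are blocked, and
heme A is dropped from the biomass equation.  Measured extracellular fluxes
are then imposed on the corresponding exchange reactions as LB = UB equality
constraints, and the growth rate is imposed on the biomass reaction the same
way, which shrinks the flux polytope to the states consistent with the
observed fermentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    build_stoichiometric_system,
    find_exchange_reactions,
)


class ConfigurationError(ValueError):
    """A recipe or constraint references ids missing from the model."""


#: Yeast8 reaction ids for the anaerobic uptakes: ergosterol (r_1757),
#: lanosterol (r_1915), zymosterol (r_2106), 14-demethyllanosterol (r_2134),
#: ergosta-5,7,22,24(28)-tetraen-3beta-ol (r_2137), oleate (r_2189).
YEAST8_UNRESTRICTED_UPTAKES = ["r_1757", "r_1915", "r_2106", "r_2134", "r_2137", "r_2189"]
#: Oxaloacetate-malate shuttle (r_0713, r_0714) and glycerol dehydrogenase (r_0487).
YEAST8_BLOCKED_REACTIONS = ["r_0713", "r_0714", "r_0487"]


@dataclass
class AnaerobicRecipe:
    """Which reactions to close/open and which biomass precursors to drop.

    Defaults target Yeast8; toy models supply their own ids (see
    :func:`vinoflux.synthetic.toy_anaerobic_recipe`).
    """

    oxygen_exchange_id: str = "r_1992"
    unrestricted_uptake_ids: list[str] = field(
        default_factory=lambda: list(YEAST8_UNRESTRICTED_UPTAKES)
    )
    blocked_reaction_ids: list[str] = field(
        default_factory=lambda: list(YEAST8_BLOCKED_REACTIONS)
    )
    biomass_removals: list[str] = field(default_factory=lambda: ["s_3714"])  # heme A


@dataclass
class ConstraintSet:
    """Measured exchange fluxes and growth rate for one strain x time point.

    Uptake fluxes are negative, secretion positive (mmol gDW^-1 h^-1);
    ``growth_rate`` is in h^-1.
    """

    strain: str
    time_h: float
    fixed_exchanges: dict[str, float] = field(default_factory=dict)
    growth_rate: float | None = None


def apply_anaerobic_modifications(
    model: MetabolicModel, recipe: AnaerobicRecipe
) -> MetabolicModel:
    """Return a copy of ``model`` with the anaerobic recipe applied.

    Oxygen exchange and blocked reactions get bounds (0, 0); each unrestricted
    uptake gets its lower bound opened to -DEFAULT_BOUND; each
    ``biomass_removals`` metabolite is deleted from the biomass stoichiometry.
    Idempotent; never changes the number of reactions or metabolites.
    """
    missing = [
        rid
        for rid in (
            [recipe.oxygen_exchange_id]
            + recipe.unrestricted_uptake_ids
            + recipe.blocked_reaction_ids
        )
        if not model.has_reaction(rid)
    ]
    if recipe.biomass_removals:
        if model.biomass_reaction_id is None:
            raise ConfigurationError("recipe removes biomass precursors but the model has no biomass reaction")
        biomass = model.reaction(model.biomass_reaction_id)
        missing += [
            f"{mid} (in biomass)"
            for mid in recipe.biomass_removals
            if mid not in biomass.stoichiometry and mid not in model.metabolite_ids()
        ]
    if missing:
        raise ConfigurationError(f"anaerobic recipe ids not found in model: {missing}")

    out = model.copy()
    o2 = out.reaction(recipe.oxygen_exchange_id)
    o2.lower_bound = 0.0
    o2.upper_bound = 0.0
    for rid in recipe.unrestricted_uptake_ids:
        out.reaction(rid).lower_bound = -DEFAULT_BOUND
    for rid in recipe.blocked_reaction_ids:
        r = out.reaction(rid)
        r.lower_bound = 0.0
        r.upper_bound = 0.0
    if recipe.biomass_removals and out.biomass_reaction_id is not None:
        biomass = out.reaction(out.biomass_reaction_id)
        for mid in recipe.biomass_removals:
            biomass.stoichiometry.pop(mid, None)
    out.validate()
    return out


def fix_exchange_fluxes(
    model: MetabolicModel,
    constraints: ConstraintSet,
    tolerance_band: float = 0.0,
) -> MetabolicModel:
    """Fix measured exchange fluxes (and growth rate) as tight bounds.

    With ``tolerance_band`` = 0 each listed exchange gets LB = UB = flux; with
    band b > 0 the bounds are flux -/+ b*|flux| (a relaxation knob for
    measurement error), intersected with the reaction's prior bounds so a
    relaxation never opens a direction the unconstrained model forbids (e.g.
    ethanol uptake).  Constraints on reactions that are neither exchanges nor
    the biomass reaction are rejected.
    """
    exchanges = set(find_exchange_reactions(model))
    bad = [
        rid
        for rid in constraints.fixed_exchanges
        if rid not in exchanges and rid != model.biomass_reaction_id
    ]
    missing = [rid for rid in constraints.fixed_exchanges if not model.has_reaction(rid)]
    if missing:
        raise ConfigurationError(f"constraint ids not found in model: {missing}")
    if bad:
        raise ConfigurationError(
            f"constraints on non-exchange, non-biomass reactions: {bad}"
        )
    out = model.copy()

    def _set(rid: str, flux: float) -> None:
        if not np.isfinite(flux):
            raise ConfigurationError(f"non-finite constraint flux for {rid!r}: {flux}")
        half = tolerance_band * abs(flux)
        r = out.reaction(rid)
        lo, hi = flux - half, flux + half
        if tolerance_band > 0:  # keep the relaxed window inside prior bounds
            lo2, hi2 = max(lo, r.lower_bound), min(hi, r.upper_bound)
            if lo2 <= hi2:
                lo, hi = lo2, hi2
        r.lower_bound = lo
        r.upper_bound = hi
        if r.lower_bound > r.upper_bound:  # cannot happen for half >= 0
            raise RuntimeError(f"inverted bounds on {rid!r}")

    for rid, flux in constraints.fixed_exchanges.items():
        _set(rid, flux)
    if constraints.growth_rate is not None:
        if model.biomass_reaction_id is None:
            raise ConfigurationError("growth rate given but model has no biomass reaction")
        _set(model.biomass_reaction_id, constraints.growth_rate)
    return out


def check_feasibility(
    model: MetabolicModel, tol: float = 1e-9
) -> tuple[bool, np.ndarray | None]:
    """Solve the LP "find v with Sv = 0, lb <= v <= ub".

    Returns (feasible, witness-flux-vector-or-None).  A zero objective is
    used; any feasible vertex is an acceptable witness.
    """
    from scipy.optimize import linprog

    sys_ = build_stoichiometric_system(model)
    res = linprog(
        c=np.zeros(sys_.n_reactions),
        A_eq=sys_.S,
        b_eq=np.zeros(sys_.n_metabolites),
        bounds=list(zip(sys_.lb, sys_.ub)),
        method="highs",
    )
    if res.status == 2:  # infeasible
        return False, None
    if not res.success:
        raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")
    v = np.asarray(res.x)
    if np.max(np.abs(sys_.S @ v)) > max(tol, 1e-6):
        raise RuntimeError("LP returned a vector violating mass balance")
    return True, v


# ---------------------------------------------------------------------------
# I/O: constraint tables as CSV, recipes as YAML


def constraint_sets_to_frame(rows: list[ConstraintSet]) -> pd.DataFrame:
    """Long-format table: strain, time_h, reaction_id, flux (growth rate included
    under reaction_id "growth_rate")."""
    recs = []
    for cs in rows:
        for rid, flux in cs.fixed_exchanges.items():
            recs.append({"strain": cs.strain, "time_h": cs.time_h, "reaction_id": rid, "flux": flux})
        if cs.growth_rate is not None:
            recs.append(
                {"strain": cs.strain, "time_h": cs.time_h, "reaction_id": "growth_rate", "flux": cs.growth_rate}
            )
    return pd.DataFrame(recs, columns=["strain", "time_h", "reaction_id", "flux"])


def frame_to_constraint_sets(df: pd.DataFrame) -> list[ConstraintSet]:
    out = []
    for (strain, time_h), grp in df.groupby(["strain", "time_h"], sort=True):
        fixed = {}
        mu = None
        for _, row in grp.iterrows():
            if row["reaction_id"] == "growth_rate":
                mu = float(row["flux"])
            else:
                fixed[row["reaction_id"]] = float(row["flux"])
        out.append(ConstraintSet(str(strain), float(time_h), fixed, mu))
    return out


def write_constraints_csv(rows: list[ConstraintSet], path: str) -> None:
    constraint_sets_to_frame(rows).to_csv(path, index=False)


def read_constraints_csv(path: str) -> list[ConstraintSet]:
    return frame_to_constraint_sets(pd.read_csv(path))


def write_recipe_yaml(recipe: AnaerobicRecipe, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "oxygen_exchange_id": recipe.oxygen_exchange_id,
                "unrestricted_uptake_ids": recipe.unrestricted_uptake_ids,
                "blocked_reaction_ids": recipe.blocked_reaction_ids,
                "biomass_removals": recipe.biomass_removals,
            },
            fh,
        )


def read_recipe_yaml(path: str) -> AnaerobicRecipe:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return AnaerobicRecipe(**payload)
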