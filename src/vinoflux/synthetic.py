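"""Synthetic wine-fermentation network and multi-strain time-course generator.

The toy network is a ~25-reaction anaerobic wine-yeast caricature: glucose
uptake feeds a glycolysis-like chain (with duplicated isozyme steps so the
constrained polytope keeps free dimensions to sample), branching to glycerol
and to pyruvate -> acetaldehyde -> ethanol; an Ehrlich-like branch converts an
amino acid via transaminase -> decarboxylase -> dehydrogenase to a fusel
alcohol, part of which is esterified with acetaldehyde to an acetate-ester
VOC; optional condensed branches turn further amino acids into further VOCs.
A biomass pseudo-reaction consumes glucose, amino acids, a sterol and a trace
of heme A, so the anaerobic recipe (close O2, open sterol uptake, block
respiration, drop heme A) has targets to act on.

The strain scenario plants per-phase exchange-flux vectors that are exact
steady states of this network, integrates them into concentration time
courses with multiplicative measurement noise, and records the planted
differences as ground truth, so the full pipeline (estimate -> constrain ->
sample -> compare) can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enology import AnaerobicRecipe
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction
from .rates import FermentationSeries

PHASE_BOUNDARIES = (36.0, 58.0)  # h: end of exponential, end of deceleration
PHASES = ("exponential", "deceleration", "stationary")
DEFAULT_TIME_POINTS = (24.0, 58.0, 144.0)

#: measured compound -> toy exchange reaction
COMPOUND_TO_EXCHANGE = {
    "glucose": "EX_glc",
    "glycerol": "EX_glyc",
    "ethanol": "EX_etoh",
    "fusel_alcohol": "EX_fusel",
    "acetate_ester": "EX_ester",
    "amino_acid_1": "EX_aa1",
}

#: Reactions carrying the Ehrlich-branch flux in the toy network.
EHRLICH_REACTIONS = ("TA1", "KDC1a", "KDC1b", "ADH6", "EX_fusel", "EX_aa1")


@dataclass
class ToyNetworkSpec:
    n_branch_vocs: int = 2
    include_ehrlich: bool = True
    default_bound: float = DEFAULT_BOUND
    seed: int = 0

    def __post_init__(self):
        if self.n_branch_vocs < 1:
            raise ValueError("n_branch_vocs must be >= 1")


def phase_of(time_h: float) -> str:
    if time_h < PHASE_BOUNDARIES[0]:
        return "exponential"
    if time_h < PHASE_BOUNDARIES[1]:
        return "deceleration"
    return "stationary"


def build_toy_wine_network(spec: ToyNetworkSpec | None = None) -> MetabolicModel:
    """Deterministic small wine network (see module docstring)."""
    spec = spec or ToyNetworkSpec()
    B = spec.default_bound
    mets = [
        Metabolite("glc", "D-glucose"),
        Metabolite("t3p", "triose 3-phosphate"),
        Metabolite("glyc", "glycerol"),
        Metabolite("pyr", "pyruvate"),
        Metabolite("acald", "acetaldehyde"),
        Metabolite("etoh", "ethanol"),
        Metabolite("co2", "carbon dioxide"),
        Metabolite("o2", "oxygen"),
        Metabolite("st", "sterol"),
        Metabolite("hemea", "heme A"),
        Metabolite("bio", "biomass"),
    ]

    def rxn(rid, stoich, lb, ub, gene="", name="", subsystem=""):
        return Reaction(rid, name or rid, stoich, lb, ub, gene, subsystem)

    rxns = [
        rxn("EX_glc", {"glc": -1}, -10, 0, subsystem="Exchange"),
        rxn("HXK1", {"glc": -1, "t3p": 2}, 0, B, "TOY_HXK1", "hexokinase/upper glycolysis (isozyme 1)", "Glycolysis"),
        rxn("HXK2", {"glc": -1, "t3p": 2}, 0, B, "TOY_HXK2", "hexokinase/upper glycolysis (isozyme 2)", "Glycolysis"),
        rxn("PYK", {"t3p": -1, "pyr": 1}, 0, B, "TOY_PYK1", "lower glycolysis to pyruvate", "Glycolysis"),
        rxn("GPD", {"t3p": -1, "glyc": 1}, 0, B, "TOY_GPD1", "glycerol-3-phosphate dehydrogenase branch", "Glycerophospholipid metabolism"),
        rxn("EX_glyc", {"glyc": -1}, 0, B, subsystem="Exchange"),
        rxn("PDC", {"pyr": -1, "acald": 1, "co2": 1}, 0, B, "TOY_PDC1 or TOY_PDC5", "pyruvate decarboxylase", "Pyruvate metabolism"),
        rxn("ADH1", {"acald": -1, "etoh": 1}, 0, B, "TOY_ADH1", "alcohol dehydrogenase (isozyme 1)", "Glycolysis"),
        rxn("ADH4", {"acald": -1, "etoh": 1}, 0, B, "TOY_ADH4", "alcohol dehydrogenase (isozyme 2)", "Glycolysis"),
        rxn("EX_etoh", {"etoh": -1}, 0, B, subsystem="Exchange"),
        rxn("EX_co2", {"co2": -1}, 0, B, subsystem="Exchange"),
        rxn("RESP", {"pyr": -1, "o2": -2, "co2": 3}, 0, B, "TOY_COX1", "respiratory pyruvate oxidation", "Citric Acid Cycle"),
        rxn("EX_o2", {"o2": -1}, -B, 0, subsystem="Exchange"),
        rxn("EX_st", {"st": -1}, 0, 0, subsystem="Exchange"),  # opened by the anaerobic recipe
        rxn("HEM", {"glc": -1, "hemea": 1}, 0, B, "TOY_HEM1", "heme A synthesis (aerobic)", "Cofactor biosynthesis"),
    ]

    biomass_stoich = {"glc": -0.3, "st": -0.001, "hemea": -1e-5, "bio": 1}

    if spec.include_ehrlich:
        mets += [
            Metabolite("aa1", "amino acid 1"),
            Metabolite("oxo1", "2-oxo acid 1"),
            Metabolite("fusald1", "fusel aldehyde 1"),
            Metabolite("fusel1", "fusel alcohol 1"),
            Metabolite("ester", "acetate ester"),
        ]
        rxns += [
            rxn("EX_aa1", {"aa1": -1}, -10, 0, subsystem="Exchange"),
            rxn("TA1", {"aa1": -1, "oxo1": 1}, 0, B, "TOY_ARO8", "aromatic transaminase", "Biosynthesis of secondary metabolites (Ehrlich pathway)"),
            rxn("KDC1a", {"oxo1": -1, "fusald1": 1, "co2": 1}, 0, B, "TOY_ARO10", "2-oxo acid decarboxylase (isozyme 1)", "Biosynthesis of secondary metabolites (Ehrlich pathway)"),
            rxn("KDC1b", {"oxo1": -1, "fusald1": 1, "co2": 1}, 0, B, "TOY_PDC5", "2-oxo acid decarboxylase (isozyme 2)", "Biosynthesis of secondary metabolites (Ehrlich pathway)"),
            rxn("ADH6", {"fusald1": -1, "fusel1": 1}, 0, B, "TOY_ADH6", "fusel aldehyde reductase", "Biosynthesis of secondary metabolites (Ehrlich pathway)"),
            rxn("EX_fusel", {"fusel1": -1}, 0, B, subsystem="Exchange"),
            rxn("ATF", {"fusel1": -1, "acald": -1, "ester": 1}, 0, B, "TOY_ATF1", "alcohol acetyltransferase (toy acetyl donor)", "Ester formation"),
            rxn("EX_ester", {"ester": -1}, 0, B, subsystem="Exchange"),
        ]
        biomass_stoich["aa1"] = -0.05
        extra_branches = range(2, spec.n_branch_vocs + 1)
    else:
        extra_branches = range(1, spec.n_branch_vocs + 1)

    for v in extra_branches:
        mets += [Metabolite(f"aa{v}", f"amino acid {v}"), Metabolite(f"voc{v}", f"VOC {v}")]
        rxns += [
            rxn(f"EX_aa{v}", {f"aa{v}": -1}, -10, 0, subsystem="Exchange"),
            rxn(f"VOC{v}", {f"aa{v}": -1, f"voc{v}": 1}, 0, B, f"TOY_BAT{v}", f"condensed VOC branch {v}", "Biosynthesis of secondary metabolites (Ehrlich pathway)"),
            rxn(f"EX_voc{v}", {f"voc{v}": -1}, 0, B, subsystem="Exchange"),
        ]
        biomass_stoich[f"aa{v}"] = -0.05

    rxns += [
        rxn("BIOMASS", biomass_stoich, 0, B, "", "biomass pseudo-reaction", "Growth"),
        rxn("EX_bio", {"bio": -1}, 0, B, subsystem="Exchange"),
    ]

    model = MetabolicModel("toy_wine_network", mets, rxns, biomass_reaction_id="BIOMASS")
    model.validate()
    return model


def toy_anaerobic_recipe() -> AnaerobicRecipe:
    """The anaerobic recipe with ids resolving in the toy network."""
    return AnaerobicRecipe(
        oxygen_exchange_id="EX_o2",
        unrestricted_uptake_ids=["EX_st"],
        blocked_reaction_ids=["RESP"],
        biomass_removals=["hemea"],
    )


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class GroundTruth:
    """What the benchmark planted, for end-to-end recovery checks."""

    similar_pair: tuple[str, str]
    ehrlich_strain: str
    ehrlich_fold: float
    planted_reactions: tuple[str, ...]
    distinct_strain: str


@dataclass
class StrainScenario:
    """Per-strain, per-phase planted exchange fluxes and growth rates.

    ``exchange_fluxes[strain][phase]`` maps exchange ids to planted fluxes
    (uptake negative); ``growth_rates[strain][phase]`` is mu in 1/h.  The
    planted vectors are exact steady states of the toy network, so noise-free
    round trips through the flux estimator give feasible constraint sets.
    """

    strain_names: list[str]
    exchange_fluxes: dict[str, dict[str, dict[str, float]]]
    growth_rates: dict[str, dict[str, float]]
    initial_concentrations: dict[str, float]
    initial_biomass: float = 0.5
    noise_cv: float = 0.002
    seed: int = 0
    dt_h: float = 2.0
    horizon_h: float = 144.0
    ground_truth: GroundTruth | None = None
    compound_to_exchange: dict[str, str] = field(
        default_factory=lambda: dict(COMPOUND_TO_EXCHANGE)
    )

    def exchange_to_compound(self) -> dict[str, str]:
        return {v: k for k, v in self.compound_to_exchange.items()}


def phase_exchange_fluxes(
    mu: float,
    q_glc: float,
    q_glyc: float,
    q_fusel: float,
    q_ester: float,
    extra_vocs: dict[int, float] | None = None,
) -> dict[str, float]:
    """Derive a full consistent exchange-flux set from primitive targets.

    Given glucose uptake (negative), glycerol/fusel/ester secretion and mu,
    closes the toy network's mass balances: ethanol absorbs the remaining
    acetaldehyde, amino-acid uptakes cover the VOC branches plus biomass
    demand.  Raises if the targets force a negative internal flux.
    """
    extra_vocs = extra_vocs or {}
    # heme synthesis carries zero flux anaerobically (heme A leaves the
    # biomass equation), so the planted steady state routes no glucose there
    hxk = -q_glc - 0.3 * mu
    if hxk <= 0:
        raise ValueError("glucose uptake too small to cover biomass demand")
    gpd = q_glyc
    pyk = 2 * hxk - gpd
    pdc = pyk
    adh = pdc - q_ester
    if min(pyk, adh) < 0:
        raise ValueError("infeasible primitives: negative glycolytic flux")
    ta = q_fusel + q_ester
    fluxes = {
        "EX_glc": q_glc,
        "EX_glyc": q_glyc,
        "EX_etoh": adh,
        "EX_fusel": q_fusel,
        "EX_ester": q_ester,
        "EX_aa1": -(ta + 0.05 * mu),
    }
    for v, q in extra_vocs.items():
        fluxes[f"EX_voc{v}"] = q
        fluxes[f"EX_aa{v}"] = -(q + 0.05 * mu)
    return fluxes


def simulate_strain_timeseries(
    model: MetabolicModel, scenario: StrainScenario
) -> list[FermentationSeries]:
    """Integrate the planted fluxes into noisy concentration time courses.

    Within each phase the biomass grows exactly exponentially and each
    measured concentration accumulates as the exact integral
    C(t+dt) = C(t) + q * int X dt, so noise-free series are exactly
    consistent with the planted specific rates.  Multiplicative Gaussian
    noise (coefficient ``noise_cv``, truncated at +/-3 CV) is applied to
    every biomass and concentration reading.
    """
    del model  # the scenario is already expressed in exchange fluxes
    rng = np.random.default_rng(scenario.seed)
    ex2comp = scenario.exchange_to_compound()
    times = np.arange(0.0, scenario.horizon_h + scenario.dt_h / 2, scenario.dt_h)
    out = []
    for strain in scenario.strain_names:
        X = np.empty_like(times)
        X[0] = scenario.initial_biomass
        conc = {
            comp: np.full_like(times, scenario.initial_concentrations.get(comp, 0.0))
            for comp in scenario.compound_to_exchange
        }
        for i in range(1, times.size):
            t0 = times[i - 1]
            ph = phase_of(t0)
            mu = scenario.growth_rates[strain][ph]
            dt = times[i] - times[i - 1]
            if mu != 0.0:
                X[i] = X[i - 1] * np.exp(mu * dt)
                int_X = (X[i] - X[i - 1]) / mu
            else:
                X[i] = X[i - 1]
                int_X = X[i - 1] * dt
            qset = scenario.exchange_fluxes[strain][ph]
            for ex, q in qset.items():
                comp = ex2comp.get(ex)
                if comp is None:
                    continue
                conc[comp][i] = conc[comp][i - 1] + q * int_X
            for comp in conc:
                if scenario.compound_to_exchange[comp] not in qset:
                    conc[comp][i] = conc[comp][i - 1]

        def noisy(arr: np.ndarray) -> np.ndarray:
            if scenario.noise_cv == 0:
                return arr.copy()
            eps = rng.normal(0.0, scenario.noise_cv, size=arr.shape)
            np.clip(eps, -3 * scenario.noise_cv, 3 * scenario.noise_cv, out=eps)
            return arr * (1.0 + eps)

        out.append(
            FermentationSeries(
                strain=strain,
                times=times.copy(),
                biomass=noisy(X),
                concentrations={c: noisy(v) for c, v in conc.items()},
            )
        )
    return out


_BASE_PRIMITIVES = {
    # phase: (mu, q_glc, q_glyc, q_fusel, q_ester, q_voc2)
    "exponential": (0.05, -2.5, 0.25, 0.40, 0.05, 0.20),
    "deceleration": (0.01, -1.4, 0.15, 0.20, 0.03, 0.10),
    "stationary": (0.00, -0.35, 0.08, 0.10, 0.02, 0.05),
}


def make_benchmark_scenario(
    seed: int = 0, noise_cv: float = 0.002
) -> tuple[MetabolicModel, StrainScenario, GroundTruth]:
    """The four-strain benchmark with planted, recoverable differences.

    S1 and S2 share identical planted fluxes (the similar pair); S3 carries a
    3x higher Ehrlich-branch flux; S4 is the most divergent: globally lower
    VOC fluxes (x0.3), higher central-carbon flux while sugar lasts, and a
    markedly higher glycerol yield (a classic axis of strain variation in
    wine yeasts).  All planted vectors are exact steady states of the toy
    network.
    """
    model = build_toy_wine_network(ToyNetworkSpec(n_branch_vocs=2))

    def strain_fluxes(
        voc_scale=1.0, fusel_scale=1.0, glc_scale=1.0, glc_stat_scale=1.0, glyc_scale=1.0
    ):
        fluxes, mus = {}, {}
        for ph, (mu, q_glc, q_glyc, q_fusel, q_ester, q_voc2) in _BASE_PRIMITIVES.items():
            gscale = glc_stat_scale if ph == "stationary" else glc_scale
            fluxes[ph] = phase_exchange_fluxes(
                mu,
                q_glc * gscale,
                q_glyc * glyc_scale,
                q_fusel * voc_scale * fusel_scale,
                q_ester * voc_scale,
                {2: q_voc2 * voc_scale},
            )
            mus[ph] = mu
        return fluxes, mus

    names = ["S1", "S2", "S3", "S4"]
    specs = {
        "S1": strain_fluxes(),
        "S2": strain_fluxes(),
        "S3": strain_fluxes(fusel_scale=3.0),
        "S4": strain_fluxes(voc_scale=0.3, glc_scale=1.4, glc_stat_scale=0.5, glyc_scale=2.5),
    }
    truth = GroundTruth(
        similar_pair=("S1", "S2"),
        ehrlich_strain="S3",
        ehrlich_fold=3.0,
        planted_reactions=EHRLICH_REACTIONS,
        distinct_strain="S4",
    )
    mapping = dict(COMPOUND_TO_EXCHANGE)
    mapping["voc2"] = "EX_voc2"
    mapping["amino_acid_2"] = "EX_aa2"
    scenario = StrainScenario(
        strain_names=names,
        exchange_fluxes={s: specs[s][0] for s in names},
        growth_rates={s: specs[s][1] for s in names},
        initial_concentrations={
            "glucose": 400.0,
            "amino_acid_1": 250.0,
            "amino_acid_2": 60.0,
        },
        initial_biomass=0.5,
        noise_cv=noise_cv,
        seed=seed,
        ground_truth=truth,
        compound_to_exchange=mapping,
    )
    return model, scenario, truth
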