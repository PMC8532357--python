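"""Shared fixtures: analytic toy polytopes and benchmark artefacts.

The chain network has one free dimension (flux uniform on [0, 10]); the
simplex network fixes an input of 10 split over three identical branches
(a 2-simplex, two free dimensions).  Both have closed-form marginals, which
makes them the reference polytopes for sampler validation.  Expensive sample
sets are session-scoped so the analytic, oracle and histogram checks share
one chain run.
"""

import numpy as np
import pytest

from vinoflux import sampling, synthetic
from vinoflux.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    build_stoichiometric_system,
)


def make_chain_model(ex_a_bounds=(-10.0, 0.0), ex_b_bounds=(0.0, 10.0)) -> MetabolicModel:
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("EX_A", stoichiometry={"A": -1}, lower_bound=ex_a_bounds[0], upper_bound=ex_a_bounds[1]),
        Reaction("R1", stoichiometry={"A": -1, "B": 1}, lower_bound=0, upper_bound=10),
        Reaction("EX_B", stoichiometry={"B": -1}, lower_bound=ex_b_bounds[0], upper_bound=ex_b_bounds[1]),
    ]
    model = MetabolicModel("chain", mets, rxns)
    model.validate()
    return model


def make_simplex_model(n_branches: int = 3, total: float = 10.0) -> MetabolicModel:
    mets = [Metabolite("A")] + [Metabolite(f"B{i}") for i in range(1, n_branches + 1)]
    rxns = [Reaction("EX_A", stoichiometry={"A": -1}, lower_bound=-total, upper_bound=-total)]
    for i in range(1, n_branches + 1):
        rxns.append(
            Reaction(f"R{i}", stoichiometry={"A": -1, f"B{i}": 1}, lower_bound=0, upper_bound=1000)
        )
        rxns.append(
            Reaction(f"EX_B{i}", stoichiometry={f"B{i}": -1}, lower_bound=0, upper_bound=1000)
        )
    model = MetabolicModel("simplex", mets, rxns)
    model.validate()
    return model


@pytest.fixture(scope="session")
def chain_model():
    return make_chain_model()


@pytest.fixture(scope="session")
def chain_system(chain_model):
    return build_stoichiometric_system(chain_model)


@pytest.fixture(scope="session")
def simplex_model():
    return make_simplex_model()


@pytest.fixture(scope="session")
def simplex_system(simplex_model):
    return build_stoichiometric_system(simplex_model)


@pytest.fixture(scope="session")
def toy_model():
    return synthetic.build_toy_wine_network()


@pytest.fixture(scope="session")
def chain_samples_10k(chain_system):
    """One full-size ACHR run on the chain polytope, shared across tests."""
    cfg = sampling.SamplerConfig(n_samples=10000, seed=7)
    return sampling.achr_sample(chain_system, cfg)


@pytest.fixture(scope="session")
def benchmark_noise_free():
    """Noise-free benchmark scenario, simulated and estimated once."""
    from vinoflux import rates

    model, scenario, truth = synthetic.make_benchmark_scenario(seed=0, noise_cv=0.0)
    series = synthetic.simulate_strain_timeseries(model, scenario)
    table = rates.build_flux_table(series, list(synthetic.DEFAULT_TIME_POINTS), scenario.compound_to_exchange)
    return model, scenario, truth, table


def assert_models_equal(a: MetabolicModel, b: MetabolicModel) -> None:
    assert a.model_id == b.model_id
    assert a.biomass_reaction_id == b.biomass_reaction_id
    assert [(m.id, m.name, m.compartment) for m in a.metabolites] == [
        (m.id, m.name, m.compartment) for m in b.metabolites
    ]
    assert len(a.reactions) == len(b.reactions)
    for ra, rb in zip(a.reactions, b.reactions):
        assert ra.id == rb.id
        assert ra.stoichiometry == pytest.approx(rb.stoichiometry)
        assert ra.lower_bound == pytest.approx(rb.lower_bound)
        assert ra.upper_bound == pytest.approx(rb.upper_bound)
        assert ra.gene_association == rb.gene_association
        assert ra.subsystem == rb.subsystem
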