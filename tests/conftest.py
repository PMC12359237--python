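"""Shared fixtures: toy models and contexts built fresh per session."""

import cobra
import numpy as np
import pytest

from minnflux import MechanisticContext, make_toy_gem, split_reversible
from minnflux.synthetic_fixtures import GLC_UPTAKE, O2_UPTAKE


@pytest.fixture(scope="session")
def toy_model():
    """The unsplit branched toy network (with its dead-end reaction)."""
    return make_toy_gem()


@pytest.fixture(scope="session")
def split_model(toy_model):
    return split_reversible(toy_model)


@pytest.fixture(scope="session")
def toy_ctx(split_model):
    """Context with the two uptakes as inputs and every reaction referenced."""
    return MechanisticContext.from_model(split_model, [GLC_UPTAKE, O2_UPTAKE])


@pytest.fixture()
def pair_model():
    """One metabolite, producer + consumer: S = [1, -1]."""
    m = cobra.Model("pair")
    a = cobra.Metabolite("A")
    r1 = cobra.Reaction("R1", lower_bound=0.0, upper_bound=1000.0)
    r1.add_metabolites({a: 1})
    r2 = cobra.Reaction("R2", lower_bound=0.0, upper_bound=1000.0)
    r2.add_metabolites({a: -1})
    m.add_reactions([r1, r2])
    m.objective = "R2"
    return m


def make_chain_model(uptake_cap=2.0, n_steps=3):
    """Linear pathway EX -> A1 -> ... -> biomass with a capped uptake."""
    m = cobra.Model("chain")
    mets = [cobra.Metabolite(f"A{i}") for i in range(n_steps)]
    up = cobra.Reaction("UPTAKE", lower_bound=0.0, upper_bound=uptake_cap)
    up.add_metabolites({mets[0]: 1})
    rxns = [up]
    for i in range(n_steps - 1):
        r = cobra.Reaction(f"S{i}", lower_bound=0.0, upper_bound=1000.0)
        r.add_metabolites({mets[i]: -1, mets[i + 1]: 1})
        rxns.append(r)
    bm = cobra.Reaction("BIOMASS", lower_bound=0.0, upper_bound=1000.0)
    bm.add_metabolites({mets[-1]: -1})
    rxns.append(bm)
    m.add_reactions(rxns)
    m.objective = "BIOMASS"
    return m


@pytest.fixture()
def chain_model():
    return make_chain_model()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
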