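"""Shared fixtures: the canonical synthetic phototroph and its conditions."""

from __future__ import annotations

import numpy as np
import pytest

import synflux as sf


@pytest.fixture(scope="session")
def toy():
    model, gpr_table = sf.generate_toy_phototroph()
    return model


@pytest.fixture(scope="session")
def toy_gprs():
    _, gpr_table = sf.generate_toy_phototroph()
    return gpr_table


@pytest.fixture(scope="session")
def conditions():
    return sf.standard_conditions(sf.toy_exchange_map())


@pytest.fixture(scope="session")
def mixo(conditions):
    return conditions["mixotrophy"].constraints


@pytest.fixture(scope="session")
def dark(conditions):
    return conditions["dark_heterotrophy"].constraints


@pytest.fixture(scope="session")
def mixo_wt(toy, mixo):
    return sf.fba(toy, mixo)


@pytest.fixture(scope="session")
def stoich(toy):
    return sf.build_stoichiometric_matrix(toy)


def random_linear_model(seed: int, n_mets: int = 10, n_rxns: int = 15):
    """A random sparse stoichiometric model for structural oracles."""
    rng = np.random.default_rng(seed)
    mets = [
        sf.Metabolite(f"m{i}", external=bool(rng.random() < 0.2))
        for i in range(n_mets)
    ]
    rxns = []
    for j in range(n_rxns):
        k = int(rng.integers(2, 5))
        chosen = rng.choice(n_mets, size=k, replace=False)
        stoich = {}
        for idx, m in enumerate(chosen):
            coeff = float(rng.integers(1, 4))
            stoich[f"m{m}"] = -coeff if idx < k // 2 or idx == 0 else coeff
        rxns.append(
            sf.Reaction(f"r{j}", stoich, reversible=bool(rng.random() < 0.5))
        )
    return sf.MetabolicModel(mets, rxns, objective_reaction_id="r0")
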