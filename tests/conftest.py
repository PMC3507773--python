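import numpy as np
import pandas as pd
import pytest

import milkflow_gs as m


@pytest.fixture(scope="session")
def params():
    return m.TraitParameters()


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete population (3 generations)."""
    return m.SimulationConfig(
        n_founder_sires=15, n_founder_dams=400, n_generations=3,
        n_sires_per_generation=15, n_snps=200, n_qtl=50, seed=0,
    )


@pytest.fixture(scope="session")
def small_population(small_config, params):
    ped = m.simulate_pedigree(small_config, 11)
    gen = m.simulate_genotypes(ped, small_config, 11)
    tbv = m.simulate_true_breeding_values(ped, gen, params, small_config, 11)
    phen = m.simulate_phenotypes(ped, tbv, params, small_config, 11)
    return {"pedigree": ped, "genotypes": gen, "tbv": tbv,
            "phenotypes": phen, "config": small_config}


@pytest.fixture(scope="session")
def small_blup(small_population, params):
    return m.fit_multitrait_blup(
        small_population["phenotypes"], small_population["pedigree"], params
    )


def toy_pedigree(records):
    """records: list of (id, sire, dam) with '0' unknown; all male gen 0."""
    return m.Pedigree.from_records(
        [(a, s, d, "M", i) for i, (a, s, d) in enumerate(records)]
    )


@pytest.fixture
def trio():
    return m.Pedigree.from_records([
        ("S", "0", "0", "M", 0),
        ("D", "0", "0", "F", 0),
        ("O", "S", "D", "F", 1),
    ])
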