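import numpy as np
import pandas as pd
import pytest

from plastgwas import simdata


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimConfig(
        n_families=3,
        lines_per_family=20,
        markers_per_chromosome=30,
        missing_rate=0.02,
        n_replicates=2,
        env_effect=5.0,
        sigma2_poly=1.0,
        sigma2_resid=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simdata.simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def planted_case(small_config, small_panel):
    """Panel + registry (main, plastic, antagonistic QTL) + phenotypes."""
    registry = simdata.plant_qtls(
        small_panel,
        [
            simdata.QTLSpec(kind="main", var_frac=0.10),
            simdata.QTLSpec(kind="plastic", var_frac=0.20, env="WW"),
            simdata.QTLSpec(kind="antagonistic", var_frac=0.15),
        ],
        seed=23,
    )
    phenotypes = simdata.simulate_phenotypes(small_panel, registry, small_config)
    return small_panel, registry, phenotypes


@pytest.fixture(scope="session")
def env_mean_table(planted_case):
    from plastgwas import plasticity

    _, _, phen = planted_case
    return plasticity.env_means(phen)
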