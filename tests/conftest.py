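import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ncii import DesignSpec, FixedEffects, SimOptions, VarianceComponents, \
    simulate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_design() -> DesignSpec:
    """The reference layout: 2 blocks, 4 sires x 2 dams per block, 2 temperature
    x 3 pH levels, 3 replicate jars."""
    return DesignSpec()


@pytest.fixture(scope="session")
def sim_components() -> VarianceComponents:
    return VarianceComponents(block=5.0, sire=20.0, dam=10.0, sire_dam=5.0,
                              sire_temperature=10.0, sire_ph=5.0,
                              sire_temperature_ph=5.0, dam_temperature=5.0,
                              dam_ph=5.0, residual=100.0)


@pytest.fixture(scope="session")
def sim_dataset(ref_design, sim_components) -> pd.DataFrame:
    """One full simulated dataset with treatment effects, fixed seed."""
    fx = FixedEffects(mu=60.0, temperature=(-4.0, 4.0), ph=(6.0, 1.0, -7.0))
    return simulate_dataset(ref_design, sim_components, fx,
                            SimOptions(seed=20140))


@pytest.fixture(scope="session")
def two_trait_dataset(ref_design) -> pd.DataFrame:
    vc = VarianceComponents(block=5.0, sire=15.0, dam=15.0, sire_dam=20.0,
                            residual=60.0)
    opts = SimOptions(seed=915, traits=("fertilization", "gastrulation"),
                      rho_stage=0.8)
    return simulate_dataset(ref_design, vc, FixedEffects(), opts)


def one_factor_toy() -> tuple[pd.DataFrame, DesignSpec]:
    """Two groups of two observations: A=(1,3), B=(5,7).

    Mapped onto a degenerate design (one block, two sires, one dam, no
    environmental factors, two replicates): SS_between=16 (df 1),
    SS_within=4 (df 2), F=8; component estimates sigma_s^2=7, sigma_e^2=2.
    """
    design = DesignSpec(n_blocks=1, sires_per_block=2, dams_per_block=1,
                        env_factors=(), n_replicates=2)
    rows = [(1, "B1S1", "B1D1", 1, 1.0), (1, "B1S1", "B1D1", 2, 3.0),
            (1, "B1S2", "B1D1", 1, 5.0), (1, "B1S2", "B1D1", 2, 7.0)]
    records = pd.DataFrame(rows, columns=["block", "sire", "dam",
                                          "replicate", "percent"])
    return records, design
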