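import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("suite")

from beanmet.bammi import fit_bammi
from beanmet.mcmc_core import MCMCSettings
from beanmet.synthetic import SimConfig, simulate_gxe_means, simulate_trial
from beanmet.traits import derive_all


@pytest.fixture(scope="session")
def small_trial():
    """Complete 6 x 2 x 2 x 2 synthetic trial with rank-1 G x E interaction."""
    cfg = SimConfig(
        g=6,
        sites=2,
        blocks=2,
        env_effects=(-50.0, 50.0),
        interaction_rank=1,
        lambdas=(120.0,),
        seed=7,
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def small_traits(small_trial):
    table, _ = small_trial
    return derive_all(table)


@pytest.fixture(scope="session")
def bammi_noiseless():
    """Noiseless rank-2 12 x 6 mean table and its long BAMMI fit.

    The exact SVD of the double-centred matrix is the oracle for this fit.
    """
    means, truth = simulate_gxe_means(
        12, 6, 2, (60.0, 25.0), sd_eps=1e-6, seed=11, mu=100.0, sd_tau=10.0, sd_delta=8.0
    )
    post = fit_bammi(means, t=2, settings=MCMCSettings(20_000, 5_000, 5), seed=3)
    return means, truth, post


@pytest.fixture(scope="session")
def bammi_additive():
    """Additive-only table (interaction ~ 0) + unit noise, fit with t=2."""
    means, truth = simulate_gxe_means(
        8, 5, 1, (1e-8,), sd_eps=1.0, seed=21, mu=50.0, sd_tau=5.0, sd_delta=4.0
    )
    post = fit_bammi(means, t=2, settings=MCMCSettings(3_000, 1_000, 2), seed=5)
    return means, truth, post
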