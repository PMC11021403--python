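import numpy as np
import pytest

from tempdisc import (
    CohortConfig,
    fit_hierarchical,
    generate_item_set,
    simulate_agents,
    simulate_choices,
)

SMALL_MCMC = {"chains": 2, "warmup": 700, "draws": 500}


@pytest.fixture(scope="session")
def item_set():
    return generate_item_set(27, seed=11)


@pytest.fixture(scope="session")
def small_cohort(item_set):
    """40 hyperbolic agents, frame effect 0.4, no magnitude effect."""
    cfg = CohortConfig(
        n_participants=40, mu_lnk=-4.8, sd_lnk=1.8, frame_effect=0.4,
        dde_sd=0.5, magnitude_effect=0.0,
    )
    agents = simulate_agents(cfg, seed=21)
    choices = simulate_choices(item_set, agents, seed=22)
    return {"config": cfg, "agents": agents, "choices": choices}


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Shared hierarchical frame-model fit on the small cohort."""
    return fit_hierarchical(
        small_cohort["choices"], family="hyperbolic", condition_var="frame",
        mcmc_opts=SMALL_MCMC, seed=33,
    )
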