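import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message=".*ArviZ.*", category=FutureWarning)

from polaripm.lifecycle import VitalRates, litter_thinning  # noqa: E402


@pytest.fixture(scope="session")
def modes():
    """Point-estimate vital rates for the Chukchi Sea subpopulation."""
    return VitalRates.chukchi_modes()


@pytest.fixture(scope="session")
def modes_litter(modes):
    return litter_thinning(modes.omega_L0, modes.phi_C0, modes.phi_C1)


def random_rates(rng) -> VitalRates:
    """A random valid parameter set, for property-style checks."""
    u = lambda: float(rng.uniform(0.02, 0.98))
    w = rng.dirichlet([1.0, 1.0, 1.0])
    return VitalRates(
        phi_C0=u(), phi_C1=u(), phi_SF=u(), phi_AF=u(), phi_SM=u(),
        phi_AM=u(), psi1_II=u(), psi1_OO=u(), psi2_II=u(), psi2_OO=u(),
        B1=u(), B2=u(), W=u(), omega_L0=tuple(w), p=u(), delta=u(),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic dataset (fast to fit)."""
    from polaripm.simulate import SimulationScenario, simulate_bundle

    return simulate_bundle(SimulationScenario.default(seed=11, n_per_sex=250))


@pytest.fixture(scope="session")
def short_fit(small_bundle):
    """One short posterior fit shared by downstream tests.

    Deliberately short: downstream assertions are about structure and
    coarse location, not sampler convergence.
    """
    from polaripm.model import IPMModel

    model = IPMModel(small_bundle.counts, small_bundle.captures)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(draws=400, tune=250, walkers=40, seed=5, thin=4)
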