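import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hlcea.parameters import ArmParameters, SharedParameters
from hlcea.survival import WeibullFit
from hlcea.synthetic import default_parameter_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_params():
    return default_parameter_fixture()


@pytest.fixture(scope="session")
def point(fixture_params):
    return fixture_params.point()


def exponential_fit(p_cycle: float, cycle: float = 6.0) -> WeibullFit:
    """Shape-1 Weibull whose per-cycle event probability is exactly p_cycle."""
    return WeibullFit(1.0, -cycle / np.log1p(-p_cycle))


def random_arm(rng: np.random.Generator, name: str = "arm") -> ArmParameters:
    """A random but structurally valid arm (zero-covariance fits)."""
    fits = {
        key: WeibullFit(
            shape=float(rng.uniform(0.5, 2.5)), scale=float(rng.uniform(20.0, 600.0))
        )
        for key in (
            "progression_cr",
            "mortality_cr",
            "mortality_progression",
            "progression_post_asct",
            "mortality_second_progression",
        )
    }
    return ArmParameters(
        name=name,
        p_adverse_event=float(rng.uniform(0, 1)),
        p_discontinuation=float(rng.uniform(0, 0.5)),
        p_mortality_on_treatment=float(rng.uniform(0, 0.2)),
        drug_cost=float(rng.uniform(0, 200_000)),
        fits=fits,
    )


def random_shared(rng: np.random.Generator) -> SharedParameters:
    return SharedParameters(
        p_asct_eligible=float(rng.uniform(0, 1)),
        p_asct_success=float(rng.uniform(0, 1)),
        cost_pet=float(rng.uniform(0, 5_000)),
        cost_adverse_event=float(rng.uniform(0, 30_000)),
        cost_asct=float(rng.uniform(0, 100_000)),
        cost_salvage=float(rng.uniform(0, 200_000)),
        u_treatment=float(rng.uniform(0.2, 1)),
        u_complete_remission=float(rng.uniform(0.2, 1)),
        u_adverse_event=float(rng.uniform(0.1, 1)),
        u_progressive_disease=float(rng.uniform(0.1, 1)),
    )
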