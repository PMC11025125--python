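import numpy as np
import pytest

from hydrep import GeneratorSpec, LGParameters

#: published fit values for the three simulated systems (and bulk water)
TABLE1 = {
    "decanol": {"lam_pi_ind": 0.11, "lam_mz": 0.14, "h_over_a": -0.011, "a": 35_684.0},
    "dppc_liquid": {
        "lam_pi_ind": 0.22,
        "lam_mz": 0.28,
        "lam_dipolar": 0.27,
        "h_over_a": -0.273,
        "h1_over_a1": -0.228,
        "a": 492.0,
        "a1": 706.0,
    },
    "dppc_gel": {"lam_pi_ind": 0.21, "lam_mz": 0.25, "h_over_a": -0.329, "a": 496.0},
    "bulk": {"a_300K": 355.0, "a_330K": 323.0},
}


@pytest.fixture
def dppc_params() -> LGParameters:
    row = TABLE1["dppc_liquid"]
    return LGParameters.from_correlation_length(
        a=row["a"], lam=row["lam_pi_ind"], h_over_a=row["h_over_a"]
    )


@pytest.fixture
def decanol_params() -> LGParameters:
    row = TABLE1["decanol"]
    return LGParameters.from_correlation_length(
        a=row["a"], lam=row["lam_pi_ind"], h_over_a=row["h_over_a"]
    )


@pytest.fixture
def small_slab_spec() -> GeneratorSpec:
    """A fast slab: enough molecules for stable profiles, ~0.2 s."""
    return GeneratorSpec(n_water=20_000, d=2.0, lam=0.27, h_over_a=-0.228,
                         a=706.0, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ordered_profiles():
    """A well-sampled ordered slab for multipole/bound-charge comparisons."""
    from hydrep import bin_profiles, generate_ordered_slab

    spec = GeneratorSpec(n_water=400_000, lam=0.27, h_over_a=-0.228,
                         a=706.0, seed=7)
    return bin_profiles(generate_ordered_slab(spec), 0.05)
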