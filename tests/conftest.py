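import numpy as np
import pytest

from factor_entropy import (
    GroupSpec,
    SyntheticSpec,
    builtin_fixture,
    simulate_factor_model,
)


@pytest.fixture(scope="session")
def example1():
    """Five school-subject scores, two varimax factors."""
    return builtin_fixture("example1")


@pytest.fixture(scope="session")
def example2():
    """Six ability scores, two varimax ML factors."""
    return builtin_fixture("example2")


@pytest.fixture(scope="session")
def example1_groups(example1):
    """Liberal-arts {X1,X2,X3} and sciences {X4,X5} subgroups."""
    return GroupSpec.from_names(
        example1, {"arts": ["X1", "X2", "X3"], "sciences": ["X4", "X5"]}
    )


@pytest.fixture(scope="session")
def example2_groups(example2):
    """General {X1}, problem-solving {X2,X3,X4}, verbal {X5,X6} subgroups."""
    return GroupSpec.from_names(
        example2,
        {"g": ["X1"], "problem": ["X2", "X3", "X4"], "verbal": ["X5", "X6"]},
    )


def random_models(n_models, seed=0, p_range=(3, 10), m_range=(1, 4)):
    """Seeded stream of random simple-structure factor models."""
    rng = np.random.default_rng(seed)
    for _ in range(n_models):
        m = int(rng.integers(*m_range, endpoint=True))
        p = int(rng.integers(max(m, p_range[0]), p_range[1], endpoint=True))
        spread = float(rng.uniform(0, 0.4))
        yield simulate_factor_model(
            SyntheticSpec(
                p=p, m=m, seed=int(rng.integers(2**31)), factor_corr_spread=spread
            )
        )
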