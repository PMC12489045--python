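import numpy as np
import pytest

from drtkit import synthetic_data as sd

# Conditions of the reference simulation used across the suite: 10,000 reads,
# 80% poly(dA) products with geometric mean core 30 nt, 30% of products with a
# geometric mean 8 nt poly-C tail, 1% substitution and 0.1% N noise.
STUDY_SIM = dict(
    n_reads=10_000,
    product_fraction=0.8,
    mu_core=30.0,
    p_tail=0.3,
    mu_tail=8.0,
    sub_error_rate=0.01,
    n_rate=0.001,
)


@pytest.fixture(scope="session")
def contaminant_ref() -> str:
    return sd.random_reference(5000, seed=7)


@pytest.fixture(scope="session")
def ncrna_ref() -> str:
    return sd.random_ncrna_reference(188, seed=3)


@pytest.fixture(scope="session")
def study_readset(contaminant_ref) -> sd.LabeledReadSet:
    """The standard simulated read mixture at the study conditions."""
    params = sd.ReadSimParams(
        contaminant_reference=contaminant_ref, seed=1, **STUDY_SIM
    )
    return sd.simulate_product_read_set(params)


@pytest.fixture(scope="session")
def clean_readset(contaminant_ref) -> sd.LabeledReadSet:
    """Noise-free variant (e=0, no N) for truth-agreement checks."""
    params = dict(STUDY_SIM, sub_error_rate=0.0, n_rate=0.0)
    return sd.simulate_product_read_set(
        sd.ReadSimParams(contaminant_reference=contaminant_ref, seed=2, **params)
    )


def rigid_motion(seed: int = 0):
    """A random rotation matrix + translation vector."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=50.0, size=3)
    return q, t
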