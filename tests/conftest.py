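import numpy as np
import pytest

from filarelax import FilamentProperties


@pytest.fixture(scope="session")
def chromosome():
    """Chromosome-arm parameters: E = 500 Pa, G = 227 Pa, r = 1 um."""
    return FilamentProperties(E=500.0, G=227.0, r=1e-6, kappa=0.75, eta=1e-3)


@pytest.fixture(scope="session")
def chromosome_7um(chromosome):
    """Chromosome with the 7-um arm's fitted internal-friction coefficients."""
    return chromosome.with_internal_friction(66.0, 162.0)


def random_props(rng: np.random.Generator) -> FilamentProperties:
    """Log-uniform draw over physically sensible parameter ranges."""
    lu = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return FilamentProperties(
        E=lu(1e1, 1e10),
        G=lu(1e1, 1e10),
        r=lu(1e-9, 1e-5),
        kappa=float(rng.uniform(0.3, 1.0)),
        eta=lu(1e-6, 1e-1),
        eta_b=lu(1e-2, 1e4),
        eta_s=lu(1e-2, 1e4),
    )
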