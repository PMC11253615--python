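import warnings

import numpy as np
import pytest

from guildscope.core_io import AbundanceMatrix
from guildscope.synthetic_data import SimulationSpec, simulate_community

warnings.filterwarnings("ignore", message="sparcc received relative abundances")


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """Scaled-down cohort: fast enough for unit tests, same structure."""
    return SimulationSpec(
        group_sizes=(15, 15, 18, 18),
        n_guild1=10,
        n_guild2=8,
        n_background=40,
        n_ko=30,
        ko_guild_unique=6,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_community(small_spec, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (45/46/57/59, 34+20+200 genomes)."""
    return simulate_community(SimulationSpec(), seed=7)


def make_counts(n: int, d: int, seed: int = 0, depth: int = 20_000,
                corr_pair=None, rho: float = 0.7) -> AbundanceMatrix:
    """Compositional counts with independent log-normal basis abundances,
    optionally with one planted basis correlation."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, d))
    if corr_pair is not None:
        i, j = corr_pair
        z[:, j] = rho * z[:, i] + np.sqrt(1 - rho**2) * z[:, j]
    basis = np.exp(z + rng.normal(2.0, 1.0, size=d))
    frac = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, row) for row in frac]).astype(float)
    return AbundanceMatrix(
        tuple(f"s{k}" for k in range(n)),
        tuple(f"g{k}" for k in range(d)),
        counts,
        "counts",
    )
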