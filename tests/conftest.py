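import warnings

import numpy as np
import pandas as pd
import pytest

from dhgs import (
    MarkerMatrix,
    SimConfig,
    simulate_dh_genotypes,
    simulate_population,
)

warnings.filterwarnings("ignore", message="EM imputation did not converge")


@pytest.fixture(scope="session")
def small_pop():
    """Complete 80-line DH population with trials, no G-by-E, moderate noise."""
    cfg = SimConfig(
        n_lines=80,
        chromosomes=(100.0,) * 4,
        markers_per_chromosome=40,
        n_qtl=60,
        seed=101,
        gxe_sd=0.0,
    )
    pop, trials, masked = simulate_population(cfg)
    return cfg, pop, trials, masked


@pytest.fixture(scope="session")
def tiny_genotypes():
    """A 40-line x 60-marker complete DH genotype matrix."""
    cfg = SimConfig(
        n_lines=40, chromosomes=(80.0,) * 2, markers_per_chromosome=30, seed=7
    )
    return simulate_dh_genotypes(cfg).genotypes


def random_marker_matrix(rng: np.random.Generator, n: int, m: int) -> MarkerMatrix:
    """Random three-code genotype matrix (not necessarily DH)."""
    values = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
    return MarkerMatrix(
        [f"L{i}" for i in range(n)], [f"M{j}" for j in range(m)], values
    )
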