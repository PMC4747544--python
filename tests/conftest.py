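import numpy as np
import pytest

from rhomap.likelihood import build_two_locus_table, default_rho_grid


@pytest.fixture(scope="session")
def table_n40():
    """MAF-conditioned lookup table for 40 haplotypes (shared; expensive)."""
    return build_two_locus_table(40, grid=default_rho_grid(256.0),
                                 reps=4000, seed=5, min_maf=0.1)


@pytest.fixture(scope="session")
def table_n8():
    """Small-sample table for engine and chain unit tests."""
    return build_two_locus_table(8, grid=default_rho_grid(64.0),
                                 reps=3000, seed=3)


@pytest.fixture(scope="session")
def table_n4():
    """Tiny-sample table (fast to build, used by interpolation tests)."""
    return build_two_locus_table(4, grid=np.array([0, 0.25, 0.5, 1, 2, 4,
                                                   8, 16.0]),
                                 reps=4000, seed=7)
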