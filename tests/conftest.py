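import logging

import numpy as np
import pandas as pd
import pytest

from xqtlscan import QTLSpec, default_genome, simulate_cross

logging.getLogger("xqtlscan").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_genome():
    """4 chromosomes x 500 kb, 400 markers: desk-size but multi-chromosome."""
    return default_genome(
        n_markers=400, n_chromosomes=4, total_bp=2_000_000, recombination_rate=2.0
    )


@pytest.fixture(scope="session")
def medium_genome():
    """16 chromosomes, 3200 markers over 12 Mb: full genome layout, reduced density."""
    return default_genome(n_markers=3200, n_chromosomes=16, total_bp=12_000_000)


@pytest.fixture(scope="session")
def small_pool(small_genome):
    return simulate_cross(small_genome, 2000, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_factorial_table(
    coefs, n_per_cell=4, noise_sd=0.0, seed=0, mrna=None
) -> pd.DataFrame:
    """Balanced 2x2x2 growth table generated from known treatment-coded
    coefficients (COEF_NAMES order)."""
    from xqtlscan.factorial import FACTORS, design_matrix

    rng = np.random.default_rng(seed)
    rows = []
    for bg in FACTORS["background"]:
        for su in FACTORS["sup35"]:
            for sk in FACTORS["sky1"]:
                for rep in range(n_per_cell):
                    rows.append(
                        {"background": bg, "sup35": su, "sky1": sk, "replicate": rep + 1}
                    )
    df = pd.DataFrame(rows)
    X = design_matrix(df)
    df["rate"] = X @ np.asarray(coefs) + noise_sd * rng.standard_normal(len(df))
    if mrna is not None:
        df["mrna"] = mrna(rng, len(df))
    return df
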