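"""Shared fixtures: one small simulated population reused across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from skimbin.simulate import (
    GenomeSpec,
    SimConfig,
    simulate_parents,
    simulate_ril_population,
    simulate_skim_calls,
)


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return GenomeSpec(
        names=["c1", "c2"], lengths=[100_000_000] * 2, snp_density=1.0 / 20_000
    )


@pytest.fixture(scope="session")
def small_population(small_genome):
    """40 lines at 0.2x on two 100-Mb chromosomes (key, truth, coded calls)."""
    cfg = SimConfig(n_lines=40, coverage=0.2, seed=11)
    key = simulate_parents(small_genome, seed=11)
    truth = simulate_ril_population(key, cfg, small_genome)
    calls = simulate_skim_calls(truth, key, cfg)
    return key, truth, calls


@pytest.fixture()
def toy_coded() -> pd.DataFrame:
    """One line, one chromosome, a clean switch P1->P2 at 5 Mb."""
    pos = np.arange(100_000, 10_000_001, 100_000)
    code = np.where(pos <= 5_000_000, 0, 1).astype(np.int8)
    return pd.DataFrame({"line": "L1", "chrom": "c1", "pos": pos, "code": code})
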