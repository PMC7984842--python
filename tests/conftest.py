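import numpy as np
import pandas as pd
import pytest

from protcov.io import SampleDesign
from protcov.simulate import SimulationConfig, simulate_dataset


def make_design(
    n_mixtures=3, fractions=7, genotypes=("WT", "MUT"), spqc=2
) -> SampleDesign:
    rows = []
    fracs = [f"F{i}" for i in range(1, fractions + 1)]
    for m in range(1, n_mixtures + 1):
        ch = 0
        for g in genotypes:
            for f in fracs:
                ch += 1
                rows.append((f"M{m}.{g}.{f}", f"M{m}", f"C{ch:02d}", g, f, False))
        for s in range(1, spqc + 1):
            ch += 1
            rows.append((f"M{m}.SPQC.{s}", f"M{m}", f"C{ch:02d}", "", "", True))
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "mixture", "channel", "genotype", "fraction", "is_spqc"]
    ))


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def clean_config():
    """No missingness or outliers: every peptide survives preprocessing."""
    return SimulationConfig(
        n_proteins=60, n_modules=5, missing_rate_at_floor=0.0, outlier_rate=0.0, seed=11
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return simulate_dataset(clean_config)


def eq1_null_data(rng, n_mixtures=3, fractions=7, sigma_m=0.2, sigma=0.25):
    """One protein's worth of data drawn from the null mixed model.

    Returns (y, X cell-means design, mixture codes, conditions) for a
    balanced genotype × fraction layout with one sample per cell per mixture.
    """
    conditions = [f"{g}.F{f}" for g in ("MUT", "WT") for f in range(1, fractions + 1)]
    conditions = sorted(conditions)
    n_cond = len(conditions)
    rows = n_mixtures * n_cond
    X = np.tile(np.eye(n_cond), (n_mixtures, 1))
    groups = np.repeat(np.arange(n_mixtures), n_cond)
    y = rng.normal(0, sigma_m, n_mixtures)[groups] + rng.normal(0, sigma, rows)
    return y, X, groups, conditions
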