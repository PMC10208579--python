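import numpy as np
import pandas as pd
import pytest

from stripenet.core import enumerate_genotypes
from stripenet.epistasis import epistasis_table, log_fold_changes
from stripenet.simulate import SimulationConfig, generate_dataset


def random_lfc(rng: np.random.Generator, mutants_per_node: int = 1) -> pd.DataFrame:
    """A random but well-formed log-fold-change table (no model behind it)."""
    rows = []
    for g in enumerate_genotypes(mutants_per_node):
        for lvl in ("low", "medium", "high"):
            rows.append(
                {
                    "genotype": g.name(),
                    "inducer_label": lvl,
                    "G": 0.0 if g.is_wt else rng.normal(0, 0.5),
                    "sd": abs(rng.normal(0, 0.1)),
                    "n": 3,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def null_cv0_m10():
    """Exact multiplicative-null dataset, no noise, full M=10 panel."""
    cfg = SimulationConfig(mutants_per_node=10, replicate_cv=0.0)
    return generate_dataset(cfg, "multiplicative_null", seed=1)


@pytest.fixture(scope="session")
def null_cv0_m10_table(null_cv0_m10):
    lfc = log_fold_changes(null_cv0_m10.data)
    return epistasis_table(lfc)


@pytest.fixture(scope="session")
def null_cv10_m10_table():
    """Multiplicative null with 10% replicate noise, fixed seed."""
    cfg = SimulationConfig(mutants_per_node=10, replicate_cv=0.10)
    ds = generate_dataset(cfg, "multiplicative_null", seed=1)
    lfc = log_fold_changes(ds.data)
    return epistasis_table(lfc, sigma_mode="sum_of_variances")
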