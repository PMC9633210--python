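import numpy as np
import pandas as pd
import pytest

from omiprog.containers import SurvivalTable
from omiprog.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort with clear subgroup signal."""
    cfg = SimulationConfig(
        n_samples=120, n_mrna=300, n_mirna=60, n_cpg=900, n_genes_annotated=300,
        signal_fraction=0.1, effect_size=1.2, true_log_hr=np.log(3.0),
        censor_rate=0.5, seed=42,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def toy_survival():
    """Six subjects with censoring, small enough for hand computation."""
    return SurvivalTable(pd.DataFrame(
        {"time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
         "event": [1, 0, 1, 1, 0, 1]},
        index=[f"p{i}" for i in range(6)]))


def random_survival(rng, n, censor=0.3):
    t = rng.exponential(100.0, size=n).round(3) + 0.001
    e = (rng.random(n) > censor).astype(int)
    return SurvivalTable(pd.DataFrame({"time": t, "event": e},
                                      index=[f"r{i}" for i in range(n)]))
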