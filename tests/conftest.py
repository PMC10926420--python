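import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from nutriscape import (
    Experiment1Design,
    Experiment2Design,
    generate_experiment1,
    generate_experiment2,
    prepare_experiment1,
)


@pytest.fixture(scope="session")
def exp1_full_scale():
    """Full-size no-choice dataset (1200 flies) at a fixed seed."""
    return generate_experiment1(Experiment1Design(seed=7))


@pytest.fixture(scope="session")
def exp1_analysis(exp1_full_scale):
    table, log = prepare_experiment1(exp1_full_scale)
    return table


@pytest.fixture(scope="session")
def exp2_full_scale():
    """Full-size choice dataset (280 flies) at a fixed seed."""
    return generate_experiment2(Experiment2Design(seed=7))


def simulate_surface_data(
    rng,
    n=300,
    beta=(0.1, 0.8),
    gamma=(0.0, 0.0, 0.0),
    noise_sd=1.0,
    n_replicates=4,
    replicate_sd=0.0,
):
    """Flies with standardized intakes on a 15-cell grid and a known surface.

    Intakes mimic the standardized rail structure: five ratios at three
    concentration levels with within-cell jitter, then z-scored.
    """
    ratios = np.array([0.0, 1 / 8, 1 / 4, 1 / 2, 1.0])
    concs = np.array([0.5, 1.0, 2.0])
    cells = [(r, c) for r in ratios for c in concs]
    idx = rng.integers(0, len(cells), n)
    base = np.array([cells[i] for i in idx])
    vol = base[:, 1] * rng.lognormal(0, 0.3, n)
    P = vol * base[:, 0] / (1 + base[:, 0])
    C = vol / (1 + base[:, 0])
    zP = (P - P.mean()) / P.std(ddof=1)
    zC = (C - C.mean()) / C.std(ddof=1)
    bP, bC = beta
    gPP, gCC, gPC = gamma
    mean = bP * zP + bC * zC + gPP * zP**2 + gCC * zC**2 + gPC * zP * zC
    rep = rng.integers(1, n_replicates + 1, n)
    rep_shift = {r: rng.normal(0, replicate_sd) for r in range(1, n_replicates + 1)}
    y = mean + np.array([rep_shift[r] for r in rep]) + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"zP": zP, "zC": zC, "y": y, "replicate": rep,
                         "P_mg_day": P, "C_mg_day": C})
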