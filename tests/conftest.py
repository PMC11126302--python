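"""Shared fixtures: small synthetic experiments reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asvgrowth.simulate import SimConfig, simulate_experiment


def closed_form_ols(x, y):
    """Independent textbook OLS + slope t-test, used as oracle."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    df = n - 2
    s2 = np.sum(resid**2) / df
    se = np.sqrt(s2 / sxx)
    if se == 0:
        t = np.inf if slope != 0 else 0.0
    else:
        t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return slope, intercept, p


@pytest.fixture(scope="session")
def noisy_sim():
    """Full 4x6 design, 60 ASVs, multinomial reads and 10% cytometry CV."""
    return simulate_experiment(SimConfig(n_asvs=60, depth=20_000, seed=11))


@pytest.fixture(scope="session")
def exact_sim():
    """Single-condition noise-free experiment (exact proportions, CV=0)."""
    cfg = SimConfig(
        n_asvs=25,
        seasons=("winter",),
        treatments=("CL",),
        season_scale={"winter": 1.0},
        treatment_shifts={"CL": 0.0},
        exact_counts=True,
        cytometry_cv=0.0,
        motu_dirichlet=None,
        seed=7,
    )
    return simulate_experiment(cfg)


@pytest.fixture()
def toy_experiment():
    """Hand-built 3-ASV x 4-sample experiment for IO tests."""
    from asvgrowth.datamodel import ExperimentTable

    counts = pd.DataFrame(
        {
            "winter_CL_t0_r1": [50, 30, 20],
            "winter_CL_t2_r1": [10, 60, 30],
            "winter_CL_t3_r1": [5, 75, 20],
            "winter_CL_t4_r1": [2, 88, 10],
        },
        index=pd.Index(["ASV_a", "ASV_b", "ASV_c"], name="asv_id"),
    )
    samples = pd.DataFrame(
        {
            "season": ["winter"] * 4,
            "treatment": ["CL"] * 4,
            "timepoint": ["t0", "t2", "t3", "t4"],
            "replicate": [1, 1, 1, 1],
            "hours": [0.0, 24.0, 48.0, 72.0],
        },
        index=counts.columns,
    )
    totals = pd.Series(
        [1.0e6, 2.0e6, 4.0e6, 8.0e6], index=counts.columns, name="cells_per_ml"
    )
    taxonomy = pd.DataFrame(
        {
            "domain": ["Bacteria"] * 3,
            "phylum": ["P1", "P1", "P2"],
            "class": ["P1.c1", "P1.c1", "P2.c1"],
            "order": ["P1.c1.o1", "P1.c1.o1", "P2.c1.o1"],
            "family": ["F1", "F1", "F2"],
            "genus": ["G1", "G2", "G3"],
        },
        index=counts.index,
    )
    return ExperimentTable(
        counts=counts, samples=samples, totals=totals, taxonomy=taxonomy
    ).validate()
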