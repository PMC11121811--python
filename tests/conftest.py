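import dataclasses

import numpy as np
import pytest

import wingbeat as wb

#: Cluster means (Hz at 20 degC) and thermal slopes (Hz/degC) of the default
#: five-cluster population; the independent reference for recovery tests.
CLUSTER_TABLE = [
    (1, 50.51, 2.02),
    (2, 100.42, 3.66),
    (3, 171.33, 5.10),
    (4, 290.71, 7.69),
    (5, 525.58, 9.63),
]


@pytest.fixture(scope="session")
def instrument():
    return wb.InstrumentConfig()


@pytest.fixture(scope="session")
def small_campaign():
    """A modest five-cluster campaign for structural tests."""
    spec = dataclasses.replace(wb.CampaignSpec(), n_events=5_000, seed=42)
    return wb.simulate_campaign(spec)


@pytest.fixture(scope="session")
def pipeline_50k():
    """One full desk-scale pipeline run on a 50,000-event campaign.

    Session-scoped: the heavy clustering sweep runs once and is shared by
    the parameter-recovery and acceptance tests.
    """
    cfg = wb.PipelineConfig(
        clustering=wb.ClusteringConfig(restarts=2, tol=1e-3),
        simulation=dataclasses.replace(wb.CampaignSpec(), n_events=50_000),
    )
    return wb.run_pipeline(cfg, seed=0)


def quad_fit_oracle(freqs, slopes):
    """Independent normal-equations solution of slope = a f^2 + b f.

    Solves the 2x2 system X'X beta = X's by explicit inversion; shares no
    code with the implementation under test.
    """
    f = np.asarray(freqs, float)
    s = np.asarray(slopes, float)
    s11 = np.sum(f**4)
    s12 = np.sum(f**3)
    s22 = np.sum(f**2)
    r1 = np.sum(f**2 * s)
    r2 = np.sum(f * s)
    det = s11 * s22 - s12 * s12
    a = (s22 * r1 - s12 * r2) / det
    b = (s11 * r2 - s12 * r1) / det
    return a, b


def line_fit_oracle(x, y):
    """Closed-form simple OLS slope/intercept/slope-SE (textbook formulas)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    se = np.sqrt(np.sum(resid**2) / (n - 2) / sxx) if n > 2 else np.nan
    return slope, intercept, se
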