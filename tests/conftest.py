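"""Shared fixtures: small hand-built trials and independent WLS oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seetrial import SimulationConfig, simulate_trial, table1_fixture
from seetrial.trial_data import SUBJECT_COLUMNS


def make_subjects(rows: list[dict]) -> pd.DataFrame:
    """Build a subject table from sparse row dicts with sensible defaults.

    Defaults describe an event-free subject censored at 4 years.
    """
    defaults = {
        "country": "AA", "site_id": "AA-001", "arm": 0,
        "t_surrogate": 4.0, "e_surrogate": 0,
        "t_true_cv": 4.0, "e_true_cv": 0,
        "t_true_all": 4.0, "e_true_all": 0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"subject_id": f"S{i + 1:04d}", **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out, columns=SUBJECT_COLUMNS)


def wls_oracle(x, y, w):
    """Weighted least squares by explicit normal equations.

    Returns (intercept, slope, sigma2, r2, xtwx_inv); independent of the
    package's regression path.
    """
    x, y, w = (np.asarray(a, dtype=float) for a in (x, y, w))
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ X.T @ W @ y
    resid = y - X @ beta
    sigma2 = float(resid @ W @ resid) / (len(x) - 2)
    ybar = float(w @ y / w.sum())
    ss_tot = float(w @ (y - ybar) ** 2)
    ss_res = float(resid @ W @ resid)
    r2 = 1.0 - ss_res / ss_tot
    return float(beta[0]), float(beta[1]), sigma2, r2, xtwx_inv


def effects_frame(x, y, w, usable=None) -> pd.DataFrame:
    """Wrap raw regression inputs as a per-group effect table."""
    n = len(x)
    return pd.DataFrame({
        "group_id": np.arange(1, n + 1),
        "n_subjects": np.asarray(w, dtype=float),
        "events_surrogate": 50,
        "events_true": 30,
        "log_hr_surrogate": np.asarray(x, dtype=float),
        "se_surrogate": 0.1,
        "log_hr_true": np.asarray(y, dtype=float),
        "se_true": 0.15,
        "usable": True if usable is None else usable,
    })


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def small_trial():
    """A compact simulated trial (8 countries, ~4,000 subjects)."""
    config = SimulationConfig(
        country_sizes=(700, 650, 600, 550, 500, 450, 400, 350),
        sd_alpha=0.3, sd_beta=0.3, rho=0.9, seed=7,
    )
    return simulate_trial(config)


@pytest.fixture(scope="session")
def leader_like_trial():
    """A trial with the published country sizes (9,340 subjects)."""
    return simulate_trial(SimulationConfig(seed=11))
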