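"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from matrep.io import COLUMNS


def make_table(rows):
    """Build an observation table from partial row dicts."""
    full = []
    for i, r in enumerate(rows):
        base = {c: np.nan for c in COLUMNS}
        base["observation_id"] = f"obs{i:05d}"
        base.update(r)
        full.append(base)
    return pd.DataFrame(full, columns=COLUMNS)


def one_way_table(n_mothers, n_per_mother, var_mother, var_resid, mean, seed,
                  trait="subadult_fid"):
    """Balanced one-way Gaussian design, one row per observation."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(var_mother), n_mothers)
    y = mean + u[:, None] + rng.normal(0, np.sqrt(var_resid),
                                       (n_mothers, n_per_mother))
    rows = []
    for m in range(n_mothers):
        for k in range(n_per_mother):
            rows.append(
                {
                    "individual_id": f"i{m}_{k}",
                    "rearing_mother_id": f"F{m:03d}",
                    "biological_mother_id": f"F{m:03d}",
                    "trait": trait,
                    "value": y[m, k],
                }
            )
    return make_table(rows), y


def anova_oracle(y):
    """Method-of-moments one-way ANOVA variance components for a balanced
    (n_groups, n_per_group) response matrix -- the frequentist cross-check
    for the Bayesian fits."""
    n_groups, k = y.shape
    msb = k * np.var(y.mean(axis=1), ddof=1)
    msw = float(np.mean(np.var(y, axis=1, ddof=1)))
    return (msb - msw) / k, msw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
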