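"""Synthetic-data generator: structure, determinism, recovery, adoptions."""

import numpy as np
import pandas as pd
import pytest

from conftest import anova_oracle
from matrep import (
    CountDistribution,
    LatentDecomposition,
    SimulationConfig,
    assign_adoptions,
    data_scale_components,
    simulate_dataset,
    simulate_py_stage_scores,
    zero_fixed_effects,
)
from matrep.synthetic import ConfigurationError


def _cov(vals):
    g = np.zeros((4, 4))
    np.fill_diagonal(g, vals)
    return g


def _recovery_config(seed=0, **kw):
    cfg = SimulationConfig(
        n_mothers=200,
        n_mothers_with_offspring=200,
        offspring_per_mother=CountDistribution(2, 2, 2),
        fid_trials_per_subadult=CountDistribution(5, 5, 5),
        p_py_measured=1.0,
        p_subadult_fid_measured=1.0,
        fixed_effects=zero_fixed_effects(),
        seed=seed,
    )
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestSimulateDataset:
    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(seed=17)
        t1, tr1 = simulate_dataset(cfg)
        t2, tr2 = simulate_dataset(SimulationConfig(seed=17))
        pd.testing.assert_frame_equal(t1, t2)
        assert tr1.mother_effects == tr2.mother_effects

    def test_zero_mother_variance_leaves_no_clustering(self):
        cfg = _recovery_config(
            seed=5,
            mother_cov=_cov([0, 0, 0, 0]),
            offspring_var_subadult_fid=0.0,
            resid_var_subadult_fid=8.0,
        )
        table, _ = simulate_dataset(cfg)
        sub = table[table.trait == "subadult_fid"]
        means = sub.groupby("rearing_mother_id")["value"].mean()
        trials = sub.groupby("rearing_mother_id").size().mean()
        # between-mother variance of means ~ within variance / trials
        expected = sub["value"].var() / trials
        assert means.var() == pytest.approx(expected, rel=0.25)

    def test_moments_oracle_recovers_components(self):
        g = _cov([0, 5.0, 0, 0])
        cfg = _recovery_config(
            seed=11,
            mother_cov=g,
            offspring_var_subadult_fid=3.6,
            resid_var_subadult_fid=8.0,
        )
        table, _ = simulate_dataset(cfg)
        sub = table[table.trait == "subadult_fid"].copy()
        # individual level: 10 trials per mother (2 offspring x 5 trials)
        piv_i = sub.pivot_table(
            index="individual_id", columns="test_number", values="value"
        ).to_numpy()
        v_between_ind, v_within_ind = anova_oracle(piv_i)
        assert v_within_ind == pytest.approx(8.0, rel=0.15)
        # between-individual variance splits into mother + offspring parts
        assert v_between_ind == pytest.approx(5.0 + 3.6, rel=0.15)
        ind_means = sub.groupby(["rearing_mother_id", "individual_id"])[
            "value"
        ].mean()
        m = np.array([g.to_numpy() for _, g in ind_means.groupby(level=0)])
        v_mother, v_off_noise = anova_oracle(m)
        # offspring + sampling noise at 5 trials: 3.6 + 8/5
        assert v_mother == pytest.approx(5.0, rel=0.15)
        assert v_off_noise == pytest.approx(3.6 + 8.0 / 5, rel=0.15)

    def test_large_mother_variance_drives_icc_to_one(self):
        cfg = _recovery_config(
            seed=2,
            mother_cov=_cov([0, 5000.0, 0, 0]),
            offspring_var_subadult_fid=1.0,
            resid_var_subadult_fid=1.0,
        )
        table, _ = simulate_dataset(cfg)
        sub = table[table.trait == "subadult_fid"]
        means = sub.groupby(["rearing_mother_id", "individual_id"])["value"].mean()
        m = np.array([g.to_numpy() for _, g in means.groupby(level=0)])
        vb, vw = anova_oracle(m)
        assert vb / (vb + vw) > 0.99

    def test_survival_fraction_matches_quadrature(self):
        cfg = SimulationConfig(
            seed=8,
            n_mothers=400,
            n_mothers_with_offspring=400,
            offspring_per_mother=CountDistribution(2, 2, 2),
            fixed_effects=zero_fixed_effects(),
            fid_trials_per_mother=CountDistribution(1, 1, 1),
            p_py_measured=0.0,
            p_subadult_fid_measured=0.0,
        )
        cfg.fixed_effects["subadult_survival"]["intercept"] = 1.0
        table, _ = simulate_dataset(cfg)
        surv = table[table.trait == "subadult_survival"]["value"]
        vm = cfg.mother_cov[2, 2]
        expected = data_scale_components(
            LatentDecomposition(vm, 1.0, [1.0])
        ).expected_phenotype
        se = np.sqrt(expected * (1 - expected) / len(surv)) + np.sqrt(
            0.25 * vm / 400
        ) * 0.25
        assert surv.mean() == pytest.approx(expected, abs=4 * se)

    def test_invalid_configs_rejected(self):
        bad = SimulationConfig(mother_cov=np.eye(4) * -1.0)
        with pytest.raises(ConfigurationError, match="mother_cov"):
            simulate_dataset(bad)
        with pytest.raises(ConfigurationError, match="n_mothers"):
            simulate_dataset(SimulationConfig(n_mothers=0))

    def test_table_invariants(self):
        table, _ = simulate_dataset(SimulationConfig(seed=4))
        py = table[table.trait == "py_movement"]["value"]
        assert np.allclose((py * 8) % 1, 0)
        surv = table[table.trait == "subadult_survival"]["value"]
        assert set(surv) <= {0.0, 1.0}
        first = table[
            (table.trait == "subadult_fid") & (table.test_number == 1)
        ]["days_since_prev_test"]
        assert (first == 500.0).all()


class TestPyStageScores:
    def test_degenerate_propensity_gives_zero_scores(self):
        s = simulate_py_stage_scores(50, -1e3, 0.0, 8, rng_state=0)
        assert np.all(s == 0.0)

    def test_binomial_moments_at_zero_intercept(self):
        s = simulate_py_stage_scores(
            200_000, 0.0, 0.0, 8, rng_state=1, intercept=0.0
        )
        assert s.mean() == pytest.approx(0.5, abs=0.01)
        assert s.var() == pytest.approx(0.25 / 8, rel=0.03)

    def test_six_stage_protocol_grid(self):
        s = simulate_py_stage_scores(500, 0.0, 1.0, 6, rng_state=2)
        assert np.allclose((s * 6) % 1, 0)

    def test_zero_stages_rejected(self):
        with pytest.raises(ValueError):
            simulate_py_stage_scores(10, 0.0, 1.0, 0)


class TestAdoptions:
    @pytest.fixture
    def table(self):
        t, _ = simulate_dataset(SimulationConfig(seed=21))
        return t

    def test_zero_pairs_is_identity(self, table):
        out = assign_adoptions(table, 0, rng_state=0)
        pd.testing.assert_frame_equal(out, table)

    def test_pair_count_and_conservation(self, table):
        out = assign_adoptions(table, 2, rng_state=3)
        moved = out[
            out["rearing_mother_id"].notna()
            & (out["rearing_mother_id"] != out["biological_mother_id"])
        ]["individual_id"].nunique()
        assert moved == 4

        def rearing_multiset(t):
            per_kid = t.dropna(subset=["biological_mother_id"]).drop_duplicates(
                "individual_id"
            )
            return sorted(per_kid["rearing_mother_id"])

        assert rearing_multiset(out) == rearing_multiset(table)
        # biological assignments untouched
        pd.testing.assert_series_equal(
            out["biological_mother_id"], table["biological_mother_id"]
        )

    def test_insufficient_offspring_rejected(self, table):
        with pytest.raises(ValueError, match="at least"):
            assign_adoptions(table, 10_000, rng_state=0)
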