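"""Gibbs sampler, covariance updates, latent updates and ESS."""

import warnings

import numpy as np
import pytest
from scipy.stats import invwishart, ks_2samp

from conftest import anova_oracle, make_table, one_way_table
from matrep import (
    MCMCConfig,
    ModelSpec,
    PosteriorSamples,
    TraitSpec,
    effective_sample_size,
    fit_model,
    gibbs_update_covariance,
    hpd_interval,
    update_binary_latents,
)
from matrep.model import _sample_invwishart, _sample_invwishart_fixed


class TestGibbsUpdateCovariance:
    def test_mask_yields_block_diagonal(self, rng):
        s = np.array(
            [[4.0, 1.0, 0.5], [1.0, 3.0, 0.2], [0.5, 0.2, 2.0]]
        )
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 2] = mask[2, 0] = mask[1, 2] = mask[2, 1] = True
        out = gibbs_update_covariance(s * 50, 50, (np.eye(3), 3.002), mask, rng)
        assert out[0, 2] == out[1, 2] == 0.0
        assert out[0, 1] != 0.0

    def test_prior_washes_out_at_large_n(self, rng):
        truth = np.array([[2.0, 0.8], [0.8, 1.5]])
        n = 5000
        s = truth * n
        draws = np.mean(
            [
                gibbs_update_covariance(s, n, (np.eye(2), 2.002), None, rng)
                for _ in range(10_000)
            ],
            axis=0,
        )
        assert np.allclose(draws, s / n, rtol=0.02)

    def test_univariate_matches_scaled_inverse_chisquare(self, rng):
        draws = np.array(
            [
                gibbs_update_covariance([[1.0]], 0, (1.0, 3.0), None, rng)[0, 0]
                for _ in range(10_000)
            ]
        )
        # IW(psi=2, nu=3) in 1d is the scaled inverse-chi-square density
        ref = invwishart(df=3.0, scale=2.0).rvs(10_000, random_state=rng)
        assert ks_2samp(draws, ref).pvalue > 0.01

    def test_rejects_insufficient_degrees_of_freedom(self):
        with pytest.raises(ValueError, match="nu"):
            gibbs_update_covariance(np.eye(3), 0, (np.eye(3), 1.5), None, 0)

    def test_conditional_draw_matches_rejection_sampler(self, rng):
        # fix element [1,1] at 1; compare against rejection sampling of the
        # unconstrained inverse-Wishart in a thin band around the constraint
        psi = np.array([[3.0, 1.2], [1.2, 2.0]])
        nu = 8.0
        samp = invwishart(df=nu, scale=psi).rvs(1_000_000, random_state=rng)
        sel = samp[np.abs(samp[:, 1, 1] - 1.0) < 0.006]
        cond = np.array(
            [
                _sample_invwishart_fixed(psi, nu, [1], [[1.0]], rng)
                for _ in range(8000)
            ]
        )
        assert ks_2samp(cond[:, 0, 1], sel[:, 0, 1]).pvalue > 0.01
        assert ks_2samp(cond[:, 0, 0], sel[:, 0, 0]).pvalue > 0.01


class TestUpdateBinaryLatents:
    def test_strong_predictor_concentrates_above_zero(self, rng):
        l = np.zeros(1000)
        for _ in range(50):
            l, _ = update_binary_latents(l, 10.0, 1.0, rng_state=rng)
        assert np.mean(l > 0) > 0.99

    def test_symmetric_outcomes_give_zero_mean(self, rng):
        y = np.concatenate([np.ones(500), np.zeros(500)])
        l = np.zeros(1000)
        means = []
        for i in range(4000):
            l, _ = update_binary_latents(l, 0.0, y, rng_state=rng)
            if i > 500:
                means.append(l.mean())
        assert abs(np.mean(means)) < 0.05

    def test_stationary_distribution_matches_rejection_oracle(self, rng):
        eta, y, v = 0.4, 1.0, 1.3
        l = np.zeros(1)
        chain = []
        for i in range(30_000):
            l, _ = update_binary_latents(
                l, eta, y, tuning=1.8, rng_state=rng, resid_var=v
            )
            if i > 2000:
                chain.append(l[0])
        chain = np.array(chain[::10])
        props = rng.normal(eta, np.sqrt(v), 300_000)
        accp = 1 / (1 + np.exp(-props))
        ref = props[rng.random(props.size) < accp][:15_000]
        assert ks_2samp(chain, ref).pvalue > 0.01

    def test_rejects_non_binary_outcomes(self):
        with pytest.raises(ValueError):
            update_binary_latents(np.zeros(3), 0.0, np.array([0.0, 0.5, 1.0]))


class TestEffectiveSampleSize:
    def test_iid_chain(self, rng):
        ess = effective_sample_size(rng.standard_normal(1000))
        assert 700 <= ess <= 1300

    def test_alternating_chain_capped_at_length(self):
        chain = np.tile([1.0, -1.0], 500)
        with pytest.warns(UserWarning, match="capped"):
            assert effective_sample_size(chain) == 1000

    def test_ar1_closed_form(self, rng):
        n, rho = 10_000, 0.9
        x = np.zeros(n)
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)  # ~526
        assert abs(effective_sample_size(x) - expected) / expected < 0.30

    def test_constant_chain_reports_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert effective_sample_size(np.ones(100)) == 0.0

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(5))


class TestFitModel:
    def test_conjugate_intercept_posterior(self):
        # known residual variance held fixed, no random effects: the
        # posterior of the intercept is N(ybar, v/n) in closed form
        rng = np.random.default_rng(3)
        v = 4.0
        y = rng.normal(2.5, np.sqrt(v), 120)
        rows = [
            {
                "individual_id": f"i{k}",
                "trait": "subadult_fid",
                "value": y[k],
            }
            for k in range(y.size)
        ]
        spec = ModelSpec(
            traits=[
                TraitSpec(
                    "subadult_fid",
                    "gaussian",
                    (),
                    random_terms=(),
                    residual_variance_fixed=v,
                    unit_mode="observation",
                )
            ]
        )
        s = fit_model(spec, make_table(rows), MCMCConfig(2000, 200, 1, seed=5))
        b = s.get("B.fixed[subadult_fid:intercept]")
        assert b.mean() == pytest.approx(y.mean(), abs=4 * np.sqrt(v / y.size / b.size) + 0.02)
        assert b.std() == pytest.approx(np.sqrt(v / y.size), rel=0.1)
        assert np.all(s.get("R.resid[subadult_fid,subadult_fid]") == v)

    def test_balanced_one_way_recovery_against_anova(self):
        table, y = one_way_table(100, 4, 2.0, 2.0, 5.0, seed=6)
        am, aw = anova_oracle(y)
        spec = ModelSpec(
            traits=[
                TraitSpec(
                    "subadult_fid", "gaussian", (), ("mother",),
                    unit_mode="observation",
                )
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit_model(spec, table, MCMCConfig(6000, 1000, 5, seed=2))
        gm = s.get("G.motherCov[subadult_fid,subadult_fid]")
        rv = s.get("R.resid[subadult_fid,subadult_fid]")
        assert gm.mean() == pytest.approx(am, rel=0.20)
        assert rv.mean() == pytest.approx(aw, rel=0.20)
        for chain in (gm, rv):
            lo, hi = hpd_interval(chain)
            assert lo <= 2.0 <= hi  # generating value

    def test_binary_null_mother_variance(self):
        # survival-like binary trait generated with zero mother variance
        rng = np.random.default_rng(9)
        rows = []
        for m in range(200):
            for k in range(3):
                rows.append(
                    {
                        "individual_id": f"i{m}_{k}",
                        "rearing_mother_id": f"F{m:03d}",
                        "biological_mother_id": f"F{m:03d}",
                        "trait": "subadult_survival",
                        "value": float(rng.random() < 0.65),
                    }
                )
        spec = ModelSpec(
            traits=[
                TraitSpec(
                    "subadult_survival", "binary_logit", (), ("mother",),
                    unit_mode="observation",
                )
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit_model(spec, make_table(rows), MCMCConfig(6000, 1000, 5, seed=4))
        gm = s.get("G.motherCov[subadult_survival,subadult_survival]")
        assert np.median(gm) < 0.4
        from matrep import LatentDecomposition, data_scale_components

        rep = data_scale_components(
            LatentDecomposition(float(np.median(gm)), 1.0, [0.6])
        ).maternal_repeatability_data
        assert rep < 0.05
        assert np.all(s.get("R.resid[subadult_survival,subadult_survival]") == 1.0)

    def test_label_invariance_under_trait_permutation(self):
        from matrep import SimulationConfig, simulate_dataset, build_model_II_spec

        table, _ = simulate_dataset(
            SimulationConfig(seed=13, n_mothers=60, n_mothers_with_offspring=45)
        )
        spec = build_model_II_spec(table)
        flipped = ModelSpec(
            traits=[spec.traits[1], spec.traits[0]],
            residual_zero_mask=spec.residual_zero_mask[::-1, ::-1].copy(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_model(spec, table, MCMCConfig(4000, 1000, 3, seed=8))
            b = fit_model(flipped, table, MCMCConfig(4000, 1000, 3, seed=8))
        name = "G.motherCov[subadult_fid,adult_female_fid]"
        assert a.get(name).mean() == pytest.approx(b.get(name).mean(), abs=0.8)
        for s in (a, b):
            assert np.all(s.get("R.resid[subadult_fid,adult_female_fid]") == 0.0)

    def test_error_contracts(self):
        table, _ = one_way_table(5, 2, 1.0, 1.0, 0.0, seed=0)
        spec = ModelSpec(
            traits=[
                TraitSpec(
                    "subadult_fid", "gaussian", ("no_such_column",),
                    ("mother",), unit_mode="observation",
                )
            ]
        )
        with pytest.raises(ValueError, match="no_such_column"):
            fit_model(spec, table, MCMCConfig(100, 10, 1))
        good = ModelSpec(
            traits=[
                TraitSpec("subadult_fid", "gaussian", (), ("mother",),
                          unit_mode="observation")
            ]
        )
        with pytest.raises(ValueError, match="burn_in"):
            fit_model(good, table, MCMCConfig(100, 100, 1))
        with pytest.raises(ValueError, match="lacks trait"):
            fit_model(good, table[table.trait == "none"], MCMCConfig(100, 10, 1))

    def test_single_observation_per_mother_warns(self):
        table, _ = one_way_table(30, 1, 1.0, 1.0, 0.0, seed=1)
        spec = ModelSpec(
            traits=[
                TraitSpec("subadult_fid", "gaussian", (), ("mother",),
                          unit_mode="observation")
            ]
        )
        with pytest.warns(UserWarning, match="weakly identified"):
            fit_model(spec, table, MCMCConfig(300, 100, 1, seed=0))

    def test_posterior_csv_round_trip(self, tmp_path):
        table, _ = one_way_table(20, 2, 1.0, 1.0, 0.0, seed=3)
        spec = ModelSpec(
            traits=[
                TraitSpec("subadult_fid", "gaussian", (), ("mother",),
                          unit_mode="observation")
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit_model(spec, table, MCMCConfig(400, 100, 2, seed=1))
        path = tmp_path / "posterior.csv"
        s.write_csv(path)
        back = PosteriorSamples.read_csv(path)
        assert back.equals(s)
        assert back.trait_names == s.trait_names
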