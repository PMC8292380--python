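"""Tests for the synthetic-study generator and its ground-truth ledger."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from socioepi.simulate import (
    SimulationConfig,
    TrueEffects,
    kinship_from_pedigree,
    simulate_behavior,
    simulate_dataset,
    simulate_fgcm,
    simulate_methylation,
    simulate_pedigree,
)
from socioepi.stats import fit_lmm, percentile_bootstrap_ci


class TestKinship:
    def test_unrelated_founders_zero(self):
        ped = pd.DataFrame({"individual_id": ["a", "b"], "mother_id": [None, None],
                            "sex": ["F", "F"]})
        K = kinship_from_pedigree(ped)
        assert K.loc["a", "b"] == 0.0
        np.testing.assert_array_equal(np.diag(K), [1.0, 1.0])

    def test_maternal_sibs_quarter(self):
        """Path-counting on the 3-node pedigree: maternal half sibs at 0.25."""
        ped = pd.DataFrame({"individual_id": ["m", "c1", "c2"],
                            "mother_id": [None, "m", "m"],
                            "sex": ["F", "F", "M"]})
        K = kinship_from_pedigree(ped)
        assert K.loc["c1", "c2"] == 0.25
        assert K.loc["m", "c1"] == 0.5

    def test_simulated_kinship_properties(self):
        cfg = SimulationConfig(seed=7, n_mothers=8)
        ped, K = simulate_pedigree(cfg)
        A = K.to_numpy()
        np.testing.assert_allclose(A, A.T)
        assert np.all(np.linalg.eigvalsh(A) > -1e-10)  # PSD
        np.testing.assert_allclose(np.diag(A), 1.0)
        sibs = ped[ped["mother_id"] == "M000"]["individual_id"].tolist()
        assert K.loc[sibs[0], sibs[1]] == 0.25

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=7, n_mothers=6)
        _, k1 = simulate_pedigree(cfg)
        _, k2 = simulate_pedigree(cfg)
        pd.testing.assert_frame_equal(k1, k2)

    def test_invalid_config_errors(self):
        with pytest.raises(ValueError):
            simulate_pedigree(SimulationConfig(n_mothers=0))
        with pytest.raises(ValueError):
            SimulationConfig(mean_coverage=5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(effects=TrueEffects(z_inflation=0.0)).validate()


class TestBehaviorGeneration:
    def test_care_minutes_nested_in_proximity(self, small_study):
        fas = small_study.fas_records
        assert (fas["minutes_nursing"] <= fas["minutes_close"]).all()
        assert (fas["minutes_grooming"] <= fas["minutes_close"]).all()
        assert (fas["minutes_close"] <= fas["minutes_together"]).all()

    def test_zero_care_rate_gives_zero_proportions(self):
        cfg = SimulationConfig(seed=3, n_mothers=6, care_rate_override=0.0)
        ped, _ = simulate_pedigree(cfg)
        fas, _, _ = simulate_behavior(ped, cfg)
        assert (fas[["minutes_close", "minutes_nursing", "minutes_grooming"]] == 0).all().all()

    def test_full_proximity_rate(self):
        cfg = SimulationConfig(seed=3, n_mothers=6, care_rate_override=1.0)
        ped, _ = simulate_pedigree(cfg)
        fas, _, _ = simulate_behavior(ped, cfg)
        assert (fas["minutes_close"] == fas["minutes_together"]).all()

    def test_gregariousness_drives_cooccurrence(self):
        """Planted sociability correlates with realized attendance counts."""
        rhos = []
        for rep in range(20):
            cfg = SimulationConfig(seed=100 + rep, n_mothers=15, n_sessions=500)
            ped, _ = simulate_pedigree(cfg)
            _, sessions, cov = simulate_behavior(ped, cfg)
            counts = {c: 0 for c in cov["individual_id"]}
            for ids in sessions["present_ids"]:
                for i in ids.split(";"):
                    if i in counts:
                        counts[i] += 1
            realized = cov["individual_id"].map(counts)
            rho = sps.spearmanr(cov["gregariousness"], realized).statistic
            rhos.append(rho)
        assert np.mean(rhos) > 0.5

    def test_empty_pedigree_errors(self):
        with pytest.raises(ValueError):
            simulate_behavior(pd.DataFrame(), SimulationConfig())


class TestFgcm:
    def _individuals(self, n=20):
        return pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(n)],
            "sex": ["F", "M"] * (n // 2),
        })

    def test_noiseless_samples_constant_per_individual(self):
        cfg = SimulationConfig(seed=1, covariate_effects_scale=0.0)
        eff = TrueEffects(sigma_id=0.0, sigma_resid_fgcm=0.0)
        samples, _ = simulate_fgcm(self._individuals(), eff, cfg)
        per = samples.groupby("individual_id")["fgcm_ng_g"].nunique()
        assert (per == 1).all()
        np.testing.assert_allclose(samples["fgcm_ng_g"],
                                   np.exp(cfg.fgcm_log_mean))

    def test_repeat_counts_in_range(self):
        samples, _ = simulate_fgcm(self._individuals(60), TrueEffects(),
                                   SimulationConfig(seed=2))
        reps = samples.groupby("individual_id").size()
        assert reps.min() >= 1 and reps.max() <= 18

    def test_values_strictly_positive(self):
        samples, _ = simulate_fgcm(self._individuals(), TrueEffects(),
                                   SimulationConfig(seed=3))
        assert (samples["fgcm_ng_g"] > 0).all()

    def test_planted_slope_recovered_in_bootstrap_ci(self):
        """beta = -0.12 inside its 95% bootstrap CI in >= 90% of sims.

        Scaled to 60 simulations with n_boot = 300 to keep the suite fast."""
        hits = 0
        n_sims = 60
        for s in range(n_sims):
            cfg = SimulationConfig(seed=500 + s)
            eff = TrueEffects(beta_network_on_logfgcm=-0.12)
            ind = self._individuals(80)
            net_z = np.random.default_rng(900 + s).standard_normal(80)
            net_z = (net_z - net_z.mean()) / net_z.std(ddof=1)
            samples, _ = simulate_fgcm(ind, eff, cfg, network_z=net_z)
            df = samples.merge(
                pd.DataFrame({"individual_id": ind["individual_id"], "xz": net_z}),
                on="individual_id")
            df["log_fgcm"] = np.log(df["fgcm_ng_g"])
            ci = percentile_bootstrap_ci(df, "log_fgcm", ["xz"], "individual_id",
                                         n_boot=300, seed=s)["xz"]
            hits += ci.lower <= -0.12 <= ci.upper
        assert hits / n_sims >= 0.90

    def test_null_slope_unbiased(self):
        """No planted effect: slope estimates center on zero (200 sims)."""
        est = []
        for s in range(200):
            cfg = SimulationConfig(seed=2000 + s)
            ind = self._individuals(40)
            net_z = np.random.default_rng(s).standard_normal(40)
            eff = TrueEffects(beta_network_on_logfgcm=0.0, beta_care_on_logfgcm=0.0)
            samples, _ = simulate_fgcm(ind, eff, cfg, network_z=net_z)
            df = samples.merge(
                pd.DataFrame({"individual_id": ind["individual_id"], "xz": net_z}),
                on="individual_id")
            df["log_fgcm"] = np.log(df["fgcm_ng_g"])
            est.append(fit_lmm(df, "log_fgcm", ["xz"], "individual_id").coef("xz"))
        assert abs(np.mean(est)) < 0.02


class TestMethylation:
    def _setup(self, n_mothers=13, n_cpg=1000, **eff_kw):
        cfg = SimulationConfig(seed=9, n_mothers=n_mothers, n_cpg=n_cpg,
                               effects=TrueEffects(**eff_kw))
        ped, K = simulate_pedigree(cfg)
        cubs = ped[ped["mother_id"].notna()].reset_index(drop=True)
        cubs = cubs.assign(age_at_darting_months=20.0)
        ids = cubs["individual_id"].tolist()
        return cfg, cubs, K.loc[ids, ids]

    def test_pure_binomial_dispersion(self):
        """tau = 0, no effects: fraction variance matches binomial expectation."""
        cfg, cubs, K = self._setup(tau_kinship=0.0, frac_true_dms=0.0)
        counts, _, _ = simulate_methylation(cubs, K, cfg.effects, cfg)
        frac = counts.fractions()
        obs = frac.var(axis=1, ddof=1)
        p_hat = frac.mean(axis=1)
        expected = (p_hat * (1 - p_hat))[:, None] / counts.total
        ratio = obs.mean() / expected.mean(axis=1).mean()
        assert 0.9 <= ratio <= 1.1

    def test_kinship_dimension_mismatch_errors(self):
        cfg, cubs, K = self._setup(n_cpg=10)
        with pytest.raises(ValueError):
            simulate_methylation(cubs.iloc[:-1], K, cfg.effects, cfg)

    def test_true_dms_bookkeeping_exact(self):
        cfg, cubs, K = self._setup(n_cpg=2000, frac_true_dms=0.1)
        rng_x = np.random.default_rng(0).standard_normal(len(cubs))
        _, _, truth = simulate_methylation(cubs, K, cfg.effects, cfg, exposure=rng_x)
        assert len(truth["true_dms_sites"]) == 200

    def test_zero_total_cell_representable(self):
        """A forced zero-coverage cell flows through the container."""
        cfg, cubs, K = self._setup(n_cpg=20)
        counts, _, _ = simulate_methylation(cubs, K, cfg.effects, cfg)
        counts.total[0, 0] = 0
        counts.meth[0, 0] = 0
        frac = counts.fractions()
        assert np.isnan(frac[0, 0])

    def test_ccgg_maternal_clustering(self):
        cfg, cubs, K = self._setup(sigma_mom=2.0, sigma_resid_ccgg=0.5)
        _, ccgg, _ = simulate_methylation(cubs, K, cfg.effects, cfg)
        fit = fit_lmm(ccgg, "pct_ccgg", [], "mother_id")
        assert fit.group_var > fit.resid_var  # mom variance dominates by design


class TestDeterminism:
    def test_written_outputs_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_mothers=6, n_cpg=50, n_sessions=60)
        for sub in ("a", "b"):
            simulate_dataset(cfg).write(tmp_path / sub)
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == twin.read_bytes(), f.name

    def test_ground_truth_ledger_complete(self, small_study):
        gt = small_study.ground_truth
        assert set(gt["u_id"]) == set(small_study.covariates["individual_id"])
        n_true = round(small_study.config.effects.frac_true_dms
                       * small_study.config.n_cpg)
        assert len(gt["true_dms_sites"]) == n_true
        assert len(gt["beta_site"]) == small_study.config.n_cpg
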