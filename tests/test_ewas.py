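"""Tests for CpG filtering, the kinship site model, the empirical-null
correction, and genomic-context annotation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from socioepi.ewas import (
    annotate_sites,
    apply_null_correction,
    estimate_empirical_null,
    filter_cpgs,
    fit_site_model,
    run_ewas,
    NullModelEstimate,
)
from socioepi.methylation import MethylationCounts
from socioepi.stats import DegenerateInputError


def make_counts(meth, total, chrom="s1"):
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    n_sites = meth.shape[0]
    sites = pd.DataFrame({"chrom": [chrom] * n_sites,
                          "start": np.arange(n_sites) * 10,
                          "end": np.arange(n_sites) * 10 + 1})
    inds = [f"i{j}" for j in range(meth.shape[1])]
    return MethylationCounts(sites, inds, meth, total)


class TestFiltering:
    def test_high_mean_site_removed(self):
        total = np.full((2, 6), 20)
        meth = np.vstack([np.full(6, 19), np.full(6, 10)])  # means 0.95, 0.5
        filt, log = filter_cpgs(make_counts(meth, total), low_var_drop=0.0)
        assert filt.n_sites == 1
        assert log.n_removed_mean_bounds == 1

    def test_low_coverage_individual_removes_site(self):
        total = np.full((2, 6), 20)
        total[0, 3] = 8
        meth = np.minimum(10, total)
        filt, log = filter_cpgs(make_counts(meth, total), low_var_drop=0.0)
        assert filt.n_sites == 1
        assert log.n_removed_coverage == 1

    def test_variance_tie_break_drops_first_five_of_hundred(self):
        rng = np.random.default_rng(0)
        # identical variance pattern at every site
        base = np.array([8, 9, 10, 11, 12, 10])
        meth = np.tile(base, (100, 1))
        total = np.full((100, 6), 20)
        filt, log = filter_cpgs(make_counts(meth, total))
        assert log.n_removed_low_variance == 5
        # ties broken by site order: the first five sites are gone
        assert filt.sites["start"].iloc[0] == 50

    def test_coverage_and_mean_stages_idempotent(self):
        rng = np.random.default_rng(1)
        total = 10 + rng.poisson(20, size=(50, 8))
        meth = rng.binomial(total, 0.5)
        filt, _ = filter_cpgs(make_counts(meth, total))
        again, log2 = filter_cpgs(filt, low_var_drop=0.0)
        assert again.n_sites == filt.n_sites
        assert log2.n_removed_coverage == 0 and log2.n_removed_mean_bounds == 0

    def test_all_removed_errors(self):
        counts = make_counts([[1, 1]], [[2, 2]])  # coverage 2 < 10
        with pytest.raises(ValueError, match="all CpG sites removed"):
            filter_cpgs(counts)


class TestSiteModel:
    def _data(self, seed=1, n=25):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        age = rng.uniform(11, 27, n)
        tot = 1 + rng.poisson(29, n)
        return rng, x, age, tot

    def test_identity_kinship_reduces_to_logistic(self):
        """tau -> 0 under identity kinship: matches plain GLM to 1e-4.

        The slope equals the GLM slope; the p-value equals the GLM Wald
        statistic referred to its t(n - p) small-sample reference."""
        from scipy.stats import t as t_dist
        rng, x, age, tot = self._data()
        y = rng.binomial(tot, 1 / (1 + np.exp(-0.2)))
        fit = fit_site_model(y, tot, x, age, np.eye(25))
        X = np.column_stack([np.ones(25), x, age - age.mean()])
        glm = sm.GLM(np.column_stack([y, tot - y]), X,
                     family=sm.families.Binomial()).fit()
        assert fit.tau_boundary
        assert abs(fit.beta - glm.params[1]) < 1e-4
        t_glm = glm.params[1] / glm.bse[1]
        assert abs(fit.p - 2 * t_dist.sf(abs(t_glm), 22)) < 1e-6

    def test_planted_effect_recovered(self):
        """Mean slope within +-0.1 of the planted 0.8 over 100 sims."""
        K = np.kron(np.eye(13), np.array([[1, 0.25], [0.25, 1]]))[:25, :25]
        L = np.linalg.cholesky(K + 1e-9 * np.eye(25))
        _, x, age, tot = self._data()
        betas = []
        for s in range(100):
            r = np.random.default_rng(300 + s)
            u = 0.7 * (L @ r.standard_normal(25))
            p = 1 / (1 + np.exp(-(0.1 + 0.8 * x + u)))
            betas.append(fit_site_model(r.binomial(tot, p), tot, x, age, K).beta)
        assert abs(np.mean(betas) - 0.8) < 0.1

    def test_constant_exposure_errors(self):
        _, x, age, tot = self._data()
        with pytest.raises(DegenerateInputError):
            fit_site_model(np.minimum(5, tot), tot, np.ones(25), age, np.eye(25))

    def test_zero_total_rejected(self):
        _, x, age, tot = self._data()
        tot2 = tot.copy()
        tot2[0] = 0
        with pytest.raises(ValueError, match="positive"):
            fit_site_model(np.zeros(25), tot2, x, age, np.eye(25))


class TestEmpiricalNull:
    def test_standard_null_calibrated(self):
        z = np.random.default_rng(0).standard_normal(10_000)
        est = estimate_empirical_null(z)
        assert abs(est.bias) < 0.05
        assert 0.95 <= est.inflation <= 1.05
        assert est.null_proportion > 0.9

    def test_planted_bias_inflation_recovered(self):
        z = 0.3 + 1.2 * np.random.default_rng(1).standard_normal(10_000)
        est = estimate_empirical_null(z)
        assert abs(est.bias - 0.3) < 0.05
        assert abs(est.inflation - 1.2) < 0.05

    def test_robust_to_signal_component(self):
        """Null parameters recovered despite a 10% planted-signal component.

        Scaled to 5 replicates of 5,000 scores to keep the suite fast."""
        for rep in range(5):
            r = np.random.default_rng(40 + rep)
            z = np.concatenate([0.2 + 1.1 * r.standard_normal(4500),
                                3.0 + r.standard_normal(500)])
            est = estimate_empirical_null(z)
            assert abs(est.bias - 0.2) < 0.07
            assert abs(est.inflation - 1.1) < 0.07

    def test_few_scores_warns(self):
        with pytest.warns(UserWarning, match="z-scores"):
            estimate_empirical_null(np.random.default_rng(2).standard_normal(100))


class TestCorrection:
    def test_identity_correction_is_noop(self):
        est = NullModelEstimate(bias=0.0, inflation=1.0, null_proportion=1.0)
        beta = np.array([0.5, -0.2])
        se = np.array([0.1, 0.1])
        b, s, p = apply_null_correction(beta, se, est)
        np.testing.assert_allclose(b, beta)
        np.testing.assert_allclose(s, se)

    def test_round_trip_recalibration(self):
        rng = np.random.default_rng(3)
        se = np.full(5000, 0.1)
        z = 0.3 + 1.2 * rng.standard_normal(5000)
        beta = z * se
        est = NullModelEstimate(bias=0.3, inflation=1.2, null_proportion=1.0)
        b, s, _ = apply_null_correction(beta, se, est)
        zc = b / s
        assert abs(zc.mean()) < 0.05
        assert 0.95 <= zc.std(ddof=1) <= 1.05

    def test_p_at_z_1_96(self):
        est = NullModelEstimate(bias=0.0, inflation=1.0, null_proportion=1.0)
        _, _, p = apply_null_correction([1.96], [1.0], est)
        assert abs(p[0] - 0.05) < 1e-3

    def test_nonpositive_se_errors(self):
        est = NullModelEstimate(bias=0.0, inflation=1.0, null_proportion=1.0)
        with pytest.raises(ValueError):
            apply_null_correction([1.0], [0.0], est)


class TestRunEwas:
    def test_individual_order_invariance(self, small_study):
        """Consistently permuting individuals leaves results identical."""
        fg = small_study.fgcm.copy()
        fg["log_fgcm"] = np.log(fg["fgcm_ng_g"])
        from socioepi.stats import extract_blups
        blups = extract_blups(fg)
        age = small_study.covariates.set_index("individual_id")["age_at_darting_months"]
        counts = small_study.counts.subset_sites(np.arange(60))
        res1, _ = run_ewas(counts, blups, age, small_study.cub_kinship())
        order = counts.individuals[::-1]
        counts_perm = counts.reorder_individuals(order)
        kin_perm = small_study.cub_kinship().loc[order, order]
        res2, _ = run_ewas(counts_perm, blups, age, kin_perm)
        pd.testing.assert_frame_equal(res1, res2)

    def test_missing_individual_errors(self, small_study):
        fg = small_study.fgcm
        age = small_study.covariates.set_index("individual_id")["age_at_darting_months"]
        blups = pd.Series(0.1, index=small_study.counts.individuals[:-1])
        with pytest.raises(ValueError, match="missing"):
            run_ewas(small_study.counts, blups, age, small_study.cub_kinship())

    def test_dms_flag_consistent_with_q(self, small_study):
        fg = small_study.fgcm.copy()
        fg["log_fgcm"] = np.log(fg["fgcm_ng_g"])
        from socioepi.stats import extract_blups
        blups = extract_blups(fg)
        age = small_study.covariates.set_index("individual_id")["age_at_darting_months"]
        res, log = run_ewas(small_study.counts, blups, age, small_study.cub_kinship())
        called = res[res["is_dms"]]
        assert (called["q_bh"] <= 0.05).all()
        assert (res["q_bh"].dropna() >= res["p_corrected"].dropna() - 1e-12).all()
        assert log["n_dms"] == int(res["is_dms"].sum())


class TestAnnotation:
    TRACK_CPG = pd.DataFrame({
        "chrom": ["s1", "s1"],
        "start": [100, 50],
        "end": [200, 400],
        "name": ["island", "shore"],
    })
    TRACK_GENIC = pd.DataFrame({
        "chrom": ["s1"], "start": [120], "end": [500], "name": ["exon"],
    })

    def _sites(self, starts):
        return pd.DataFrame({"chrom": "s1", "start": starts,
                             "end": np.asarray(starts) + 1})

    def test_island_precedence_over_shore(self):
        labels, _ = annotate_sites(self._sites([150]), cpg_track=self.TRACK_CPG)
        assert labels["cpg_context"].iloc[0] == "island"

    def test_uncovered_site_open_sea_intergenic(self):
        labels, _ = annotate_sites(self._sites([900]), cpg_track=self.TRACK_CPG,
                                   genic_track=self.TRACK_GENIC)
        assert labels["cpg_context"].iloc[0] == "open_sea"
        assert labels["genic_context"].iloc[0] == "intergenic"

    def test_toy_genome_hand_enumeration(self):
        """Three intervals, five sites: labels match manual interval overlap."""
        sites = self._sites([60, 150, 250, 450, 900])
        labels, enrich = annotate_sites(
            sites, cpg_track=self.TRACK_CPG, genic_track=self.TRACK_GENIC,
            is_dms=[True, True, False, False, False])
        assert labels["cpg_context"].tolist() == [
            "shore", "island", "shore", "open_sea", "open_sea"]
        assert labels["genic_context"].tolist() == [
            "intergenic", "exon", "exon", "exon", "intergenic"]
        row = enrich[(enrich["track"] == "cpg_context")
                     & (enrich["label"] == "island")].iloc[0]
        assert row["frac_all_sites"] == 0.2
        assert row["frac_dms"] == 0.5

    def test_malformed_interval_errors(self):
        bad = pd.DataFrame({"chrom": ["s1"], "start": [100], "end": [100],
                            "name": ["island"]})
        with pytest.raises(ValueError, match="malformed"):
            annotate_sites(self._sites([10]), cpg_track=bad)
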