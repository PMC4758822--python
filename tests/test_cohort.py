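"""Synthetic cohort generation and the end-to-end pipeline plumbing."""

import logging

import numpy as np
import pandas as pd
import pytest

import rovingdcm as rd


def small_cfg(**kw):
    spec = rd.NetworkSpec(regions=("R1", "R2"))
    names = rd.ParameterPacker(spec).names
    means = {nm: 0.0 for nm in names}
    means.update({"A(R1<-R1)": -0.5, "A(R2<-R2)": -0.5, "A(R2<-R1)": 0.25,
                  "A(R1<-R2)": 0.15, "B1(R2<-R1)": 0.35, "B1(R1<-R2)": 0.2,
                  "C(R1<-u0)": 0.8})
    defaults = dict(spec=spec, n_subjects=3, group_means=means,
                    between_subject_sd=0.1, n_trains=10, n_volumes=40,
                    substeps=8, rating_parameter="B1(R1<-R2)", master_seed=1)
    defaults.update(kw)
    return rd.CohortConfig(**defaults)


class TestParameterSampling:
    def test_zero_sd_returns_group_means(self):
        cfg = small_cfg(between_subject_sd=0.0)
        packer = rd.ParameterPacker(cfg.spec)
        p = rd.sample_subject_parameters(cfg, 0)
        theta = packer.pack(p)
        expected = np.array([cfg.group_means[nm] for nm in packer.names])
        assert np.allclose(theta, expected)

    def test_moments_of_sampled_parameter(self):
        # weak mean couplings so the stability rejection never truncates
        # the Gaussian (rejection bias is exercised separately below)
        spec = rd.NetworkSpec(regions=("R1", "R2"))
        names = rd.ParameterPacker(spec).names
        means = {nm: 0.0 for nm in names}
        means.update({"A(R1<-R1)": -0.5, "A(R2<-R2)": -0.5,
                      "B1(R2<-R1)": 0.15, "C(R1<-u0)": 0.8})
        cfg = small_cfg(group_means=means)
        packer = rd.ParameterPacker(cfg.spec)
        j = list(packer.names).index("B1(R2<-R1)")
        draws = np.array([
            packer.pack(rd.sample_subject_parameters(cfg, 0, seed=s))[j]
            for s in range(10_000)])
        se_mean = 0.1 / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.15) < 3 * se_mean
        # SD of the sample SD ~ sd / sqrt(2n)
        assert abs(draws.std(ddof=1) - 0.1) < 3 * 0.1 / np.sqrt(2 * draws.size)

    def test_rejection_keeps_draws_stable(self):
        cfg = small_cfg(between_subject_sd=0.4)
        for s in range(20):
            p = rd.sample_subject_parameters(cfg, 0, seed=s)
            assert rd.check_stability(p) < 0

    def test_default_full_model_populates_all_modulations(self):
        cfg = rd.CohortConfig()
        packer = rd.ParameterPacker(cfg.spec)
        b_names = [nm for nm in packer.names if nm.startswith("B1")]
        assert len(b_names) == 25
        p = rd.sample_subject_parameters(cfg, 0, seed=0)
        assert cfg.group_means["B1(AIC<-MFG)"] == 0.0  # designated rating parameter
        assert rd.check_stability(p) < 0

    def test_unattainable_stability_raises(self):
        cfg = small_cfg()
        cfg.group_means = dict(cfg.group_means)
        cfg.group_means["A(R2<-R1)"] = 5.0
        cfg.group_means["A(R1<-R2)"] = 5.0
        with pytest.raises(ValueError, match="stable"):
            rd.sample_subject_parameters(cfg, 0, seed=0, max_attempts=5)


class TestRatings:
    def make_truth(self, cfg, n=200, seed=0):
        packer = rd.ParameterPacker(cfg.spec)
        rng = np.random.default_rng(seed)
        data = {nm: rng.normal(cfg.group_means.get(nm, 0.0), cfg.sd_for(nm), n)
                for nm in packer.names}
        return pd.DataFrame(data)

    def test_noiseless_limit_gives_r2_one(self):
        cfg = small_cfg(target_r_squared=0.999)
        truth = self.make_truth(cfg)
        ratings = rd.generate_ratings(cfg, truth, seed=1)
        r = rd.tukey_regression(truth[cfg.rating_parameter].to_numpy(),
                                ratings["difficulty"].to_numpy())
        assert r.r_squared > 0.99

    def test_negative_coupling_sign(self):
        cfg = small_cfg()
        neg = 0
        for rep in range(50):
            truth = self.make_truth(cfg, n=25, seed=rep)
            ratings = rd.generate_ratings(cfg, truth, seed=1000 + rep)
            r = rd.tukey_regression(truth[cfg.rating_parameter].to_numpy(),
                                    ratings["difficulty"].to_numpy())
            neg += r.slope < 0
        assert neg > 40  # large majority of cohorts recover the negative slope

    def test_control_outcome_is_null(self):
        """With no coupling to the control outcome, FDR flags on the
        intensity-difference regressions stay at the nominal rate."""
        cfg = small_cfg()
        flagged = 0
        n_rep = 100
        for rep in range(n_rep):
            truth = self.make_truth(cfg, n=25, seed=rep)
            ratings = rd.generate_ratings(cfg, truth, seed=2000 + rep)
            y = ratings["intensity_difference"].to_numpy()
            p = [rd.tukey_regression(truth[nm].to_numpy(), y).p
                 for nm in truth.columns if rd.group.is_extrinsic(nm)]
            _, flags = rd.bh_fdr(np.array(p), q=0.05)
            flagged += flags.any()
        assert flagged / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_clipping_logged(self, caplog):
        cfg = small_cfg(rating_intercept=99.0)
        truth = self.make_truth(cfg, n=50)
        with caplog.at_level(logging.INFO, logger="rovingdcm.cohort"):
            ratings = rd.generate_ratings(cfg, truth, seed=3)
        assert ratings["difficulty"].max() <= 100.0
        assert any("clipped" in r.message for r in caplog.records)

    def test_missing_designated_parameter(self):
        cfg = small_cfg()
        with pytest.raises(ValueError):
            rd.generate_ratings(cfg, pd.DataFrame({"x": [1.0, 2.0]}))


class TestCohortPipeline:
    def test_bit_exact_reproducibility(self):
        cfg = small_cfg()
        s1, truth1, ratings1 = rd.generate_cohort(cfg)
        s2, truth2, ratings2 = rd.generate_cohort(cfg)
        assert truth1.equals(truth2)
        assert ratings1.equals(ratings2)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.timeseries.values, b.timeseries.values)

    def test_snr_ladder_improves_recovery(self):
        """Less observation noise never hurts parameter recovery (checked on
        a seeded 3-point SNR ladder with two inverted subjects per rung)."""
        corrs = []
        for snr in (0.5, 2.0, 8.0):
            cfg = small_cfg(snr=snr, n_subjects=2, n_volumes=120, n_trains=18,
                            master_seed=7)
            subjects, truth, _ = rd.generate_cohort(cfg)
            packer = rd.ParameterPacker(cfg.spec)
            bidx = [i for i, nm in enumerate(packer.names)
                    if nm.startswith("B1")]
            t_all, e_all = [], []
            for s in subjects:
                u = rd.build_input_sticks(s.sequence, cfg.n_volumes, cfg.TR,
                                          substeps=cfg.substeps)
                post = rd.variational_laplace(
                    s.timeseries, cfg.spec, u, substeps=cfg.substeps,
                    settings=rd.InversionSettings(max_iterations=32))
                t_all.extend(packer.pack(s.params)[bidx])
                e_all.extend(post.mean[bidx])
            corrs.append(np.corrcoef(t_all, e_all)[0, 1])
        assert corrs[0] <= corrs[1] + 0.05
        assert corrs[1] <= corrs[2] + 0.05

    def test_full_analysis_smoke(self):
        """End-to-end: generate, invert, reduce, pool, group stats."""
        cfg = small_cfg(n_volumes=60, n_trains=9)
        fam = {"B_extrinsic": [5, 6], "B_self": [4, 7], "C_drive": [8]}
        space = rd.ModelSpace(families=fam)
        switch_idx = np.array([i for m in fam.values() for i in m])
        res = rd.run_full_analysis(
            cfg, space=space, switch_idx=switch_idx,
            settings=rd.InversionSettings(max_iterations=16))
        assert len(res.posteriors) == 3
        assert res.comparison.posterior_probability.sum() == pytest.approx(1.0)
        assert res.comparison.bayes_factor >= 1.0
        assert len(res.group.ttests) == 4  # 2x2 modulations in this network
        assert 0 <= res.recovery.winner_id < 8

    def test_config_validation(self):
        with pytest.raises(ValueError):
            small_cfg(n_subjects=1)
        with pytest.raises(ValueError):
            small_cfg(target_r_squared=1.5)
        with pytest.raises(ValueError):
            small_cfg(rating_parameter="B1(nope<-nope)")
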