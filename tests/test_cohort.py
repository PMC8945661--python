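import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from tempodisc import (
    CohortConfig,
    generate_choice_responses,
    generate_cohort,
    generate_dataset,
    generate_time_probes,
    true_logk,
)
from tempodisc.cohort import DEFAULT_HORIZONS


class TestConfig:
    def test_invalid_moments_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(group_sizes=(0, 54, 104))
        with pytest.raises(ValueError):
            CohortConfig(age_sds=(0.0, 2.71, 3.53))
        with pytest.raises(ValueError):
            CohortConfig(probe_outlier_rate=1.0)
        with pytest.raises(ValueError):
            CohortConfig(u_shape=(0.1, 0.2))  # slope_young must be <= 0

    def test_null_config_zeroes_structure(self):
        cfg = CohortConfig.null()
        assert cfg.beta_lhs == 0.0
        assert cfg.u_shape == (0.0, 0.0)
        assert cfg.bias_slope_older == 0.0
        assert cfg.sex_logk_offset_young == 0.0


class TestGenerateCohort:
    def test_default_sizes(self):
        subjects, truth = generate_cohort(CohortConfig(seed=1))
        assert len(subjects) == 242
        counts = subjects["group_label"].value_counts()
        assert (counts["young"], counts["middle"], counts["older"]) == \
            (84, 54, 104)
        assert len(truth) == 242

    def test_seeded_determinism(self):
        cfg = CohortConfig(group_sizes=(2, 2, 2), sex_counts_m=(1, 1, 1),
                           seed=9)
        s1, t1 = generate_cohort(cfg)
        s2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_age_bias_exact(self):
        subjects, _ = generate_cohort(CohortConfig(seed=2))
        np.testing.assert_allclose(
            subjects["age_bias"],
            subjects["physical_age"] - subjects["chronological_age"])

    def test_ses_lhs_tau_near_target(self):
        cfg = CohortConfig(group_sizes=(1000, 1000, 1000),
                           sex_counts_m=(400, 400, 400), seed=3)
        subjects, _ = generate_cohort(cfg)
        # pool within groups to avoid between-group confounding
        taus = [
            kendalltau(g["childhood_ses"], g["lhs"]).statistic
            for _, g in subjects.groupby("group_label")
        ]
        assert np.mean(taus) == pytest.approx(0.22, abs=0.05)

    def test_marginal_fidelity(self):
        cfg = CohortConfig(group_sizes=(1000, 1000, 1000),
                           sex_counts_m=(400, 400, 400), seed=4)
        subjects, _ = generate_cohort(cfg)
        young = subjects[subjects["group_label"] == "young"]
        assert young["lhs"].mean() == pytest.approx(5.18, rel=0.05)
        assert young["lhs"].std() == pytest.approx(0.80, rel=0.08)
        assert young["chronological_age"].mean() == pytest.approx(
            24.0, rel=0.05)

    def test_structural_signs(self):
        cfg = CohortConfig(group_sizes=(1000, 400, 1000),
                           sex_counts_m=(400, 150, 400), seed=5)
        subjects, truth = generate_cohort(cfg)
        df = subjects.merge(truth, on="subject_id")
        df["logk_true"] = np.log(df["k_true"])
        assert kendalltau(df["lhs"], df["logk_true"]).statistic < 0
        young = df[df["group_label"] == "young"]
        older = df[df["group_label"] == "older"]
        assert kendalltau(young["chronological_age"],
                          young["logk_true"]).statistic < 0
        assert kendalltau(older["chronological_age"],
                          older["logk_true"]).statistic > 0
        # poorer health -> feels older
        assert kendalltau(df["age_bias"],
                          df["physical_health"]).statistic < 0


class TestTrueLogk:
    def test_null_structure(self):
        cfg = CohortConfig.null()
        vals = [true_logk(lhs, age, g, cfg)
                for lhs in (3.0, 5.0) for age, g in
                ((20, "young"), (40, "middle"), (60, "older"))]
        assert np.allclose(vals, cfg.baseline_logk)

    def test_linearity_in_lhs(self):
        cfg = CohortConfig()
        d = true_logk(5.8, 40, "middle", cfg) - true_logk(5.0, 40, "middle",
                                                          cfg)
        assert d == pytest.approx(cfg.beta_lhs * 0.8)

    def test_age_slope_evaluation(self):
        cfg = CohortConfig(u_shape=(-0.05, 0.15))
        d = true_logk(5.0, 20, "young", cfg) - true_logk(5.0, 30, "young",
                                                         cfg)
        assert d == pytest.approx(0.5)

    def test_unknown_group(self):
        with pytest.raises(KeyError):
            true_logk(5.0, 40, "elder", CohortConfig())


class TestChoices:
    def _truth(self, k=0.02, sigma=0.05, random=False):
        return pd.DataFrame([{
            "subject_id": 0, "k_true": k, "sigma_true": sigma,
            "alpha_true": 1.0, "beta_true": 1.0,
            "is_random_responder": random, "is_probe_corrupt": False}])

    def test_zero_sensitivity_half(self, items):
        truth = pd.concat([self._truth(sigma=0.0)] * 5000, ignore_index=True)
        truth["subject_id"] = np.arange(5000)
        c = generate_choice_responses(truth, items, seed=17)
        assert c["chose_ss"].mean() == pytest.approx(0.5, abs=0.02)

    def test_deterministic_limit(self, items):
        truth = self._truth(k=0.5, sigma=50.0)  # SS > SV everywhere
        c = generate_choice_responses(truth, items, seed=0)
        assert c["chose_ss"].eq(1).all()

    def test_monte_carlo_matches_closed_form(self, items):
        from scipy.special import expit

        one_item = items.iloc[[3]]
        truth = pd.concat([self._truth()] * 10000, ignore_index=True)
        truth["subject_id"] = np.arange(10000)
        c = generate_choice_responses(truth, one_item, seed=11)
        sv = one_item["ll_amount"].iloc[0] / (
            1 + 0.02 * one_item["delay_days"].iloc[0])
        p = expit(0.05 * (one_item["ss_amount"].iloc[0] - sv))
        assert c["chose_ss"].mean() == pytest.approx(p, abs=0.02)

    def test_random_responder_half(self, items):
        truth = pd.concat([self._truth(k=0.5, sigma=50.0, random=True)]
                          * 2000, ignore_index=True)
        truth["subject_id"] = np.arange(2000)
        c = generate_choice_responses(truth, items, seed=12)
        assert c["chose_ss"].mean() == pytest.approx(0.5, abs=0.02)

    def test_empty_items_rejected(self, items):
        with pytest.raises(ValueError):
            generate_choice_responses(self._truth(), items.iloc[:0])


class TestTimeProbes:
    def _truth(self, alpha, beta, corrupt=False, n=1):
        df = pd.DataFrame([{
            "subject_id": 0, "k_true": 0.01, "sigma_true": 0.01,
            "alpha_true": alpha, "beta_true": beta,
            "is_random_responder": False, "is_probe_corrupt": corrupt}] * n)
        df["subject_id"] = np.arange(n)
        return df

    def test_identity_parameters_noiseless(self):
        probes = generate_time_probes(self._truth(1.0, 1.0), seed=0,
                                      noise_sd=0.0)
        np.testing.assert_allclose(probes["slider_mm"],
                                   probes["horizon_months"])

    def test_arithmetic(self):
        probes = generate_time_probes(self._truth(2.0, 0.5),
                                      horizons_months=[9.0], seed=0,
                                      noise_sd=0.0)
        assert probes["slider_mm"].iloc[0] == pytest.approx(6.0)

    def test_monte_carlo_mean(self):
        probes = generate_time_probes(
            self._truth(2.0, 0.8, n=10000), horizons_months=[12.0],
            seed=1, noise_sd=5.0)
        assert probes["slider_mm"].mean() == pytest.approx(
            2.0 * 12.0 ** 0.8, abs=0.2)

    def test_corrupt_probes_uniform(self):
        probes = generate_time_probes(
            self._truth(1.0, 1.0, corrupt=True, n=4000),
            horizons_months=[3.0], seed=2, noise_sd=0.0)
        assert probes["slider_mm"].mean() == pytest.approx(75.0, rel=0.05)
        assert probes["slider_mm"].max() > 140

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError):
            generate_time_probes(self._truth(1.0, 1.0),
                                 horizons_months=[0.0], seed=0)


class TestDataset:
    def test_byte_identical_given_seed(self, small_config):
        d1 = generate_dataset(small_config)
        d2 = generate_dataset(small_config)
        for name in d1:
            pd.testing.assert_frame_equal(d1[name], d2[name])

    def test_horizons_span_instrument(self, small_dataset):
        h = small_dataset["time_probes"]["horizon_months"].unique()
        assert len(h) == 10 and h.min() == 3.0 and h.max() == 60.0
        assert small_dataset["time_probes"]["slider_mm"].between(
            0, 150).all()
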