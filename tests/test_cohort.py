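import io

import numpy as np
import pandas as pd
import pytest
import yaml
from scipy.stats import chisquare

from fitbmi.cohort import (REFERENCE_CLASS_COUNTS, REFERENCE_CORR, VARIABLES,
                           Cohort, GeneratorConfig, Perturbation,
                           default_config, empirical_correlations,
                           latent_correlation, simulate_cohort,
                           single_feature_config)


class TestDefaultConfig:
    def test_class_proportions_normalized_counts(self):
        cfg = default_config()
        expected = np.array(REFERENCE_CLASS_COUNTS) / 6698
        np.testing.assert_allclose(cfg.class_proportions, expected,
                                   atol=1e-12)
        np.testing.assert_allclose(
            cfg.class_proportions, (0.0530, 0.7451, 0.1896, 0.0122),
            atol=1e-4)

    def test_correlation_targets(self):
        cfg = default_config()
        assert cfg.corr_target[0, 1] == pytest.approx(0.200954)
        assert cfg.corr_target[0, 2] == pytest.approx(-0.278618)
        assert cfg.corr_target[1, 2] == pytest.approx(-0.405648)
        np.testing.assert_array_equal(np.diag(cfg.corr_target), np.ones(5))
        assert cfg.n == 6698

    def test_dict_yaml_roundtrip(self):
        cfg = default_config(n=50, seed=3, perturb=Perturbation())
        text = yaml.safe_dump(cfg.to_dict())
        back = GeneratorConfig.from_dict(yaml.safe_load(text))
        np.testing.assert_allclose(back.corr_target, cfg.corr_target)
        assert back.n == 50 and back.seed == 3
        assert back.perturb == cfg.perturb
        assert back.marginals == cfg.marginals


class TestConfigValidation:
    def test_asymmetric_rejected(self):
        cfg = default_config()
        bad = cfg.corr_target.copy()
        bad[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            GeneratorConfig(n=10, corr_target=bad, marginals=cfg.marginals,
                            class_proportions=cfg.class_proportions)

    def test_proportions_must_sum_to_one(self):
        cfg = default_config()
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(n=10, corr_target=cfg.corr_target,
                            marginals=cfg.marginals,
                            class_proportions=np.array([0.3, 0.3, 0.3, 0.3]))

    def test_nonpositive_n_rejected(self):
        cfg = default_config()
        with pytest.raises(ValueError):
            GeneratorConfig(n=0, corr_target=cfg.corr_target,
                            marginals=cfg.marginals,
                            class_proportions=cfg.class_proportions)


class TestLatentCalibration:
    def test_psd_repair_of_infeasible_target(self):
        cfg = default_config()
        bad = np.eye(5)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9  # jointly infeasible triple
        cfg2 = GeneratorConfig(n=10, corr_target=bad,
                               marginals=cfg.marginals,
                               class_proportions=cfg.class_proportions)
        latent = latent_correlation(cfg2)
        assert np.linalg.eigvalsh(latent).min() > 0
        np.testing.assert_allclose(np.diag(latent), 1.0, atol=1e-12)

    def test_latent_close_to_target_for_near_normal_marginals(self):
        latent = latent_correlation(default_config())
        # monotone marginal transforms only attenuate mildly
        assert abs(latent[0, 1] - 0.200954) < 0.03
        assert abs(latent[1, 2] - (-0.405648)) < 0.03


class TestSimulation:
    def test_seeded_determinism_including_perturbation(self):
        cfg = default_config(n=300, seed=9, perturb=Perturbation())
        a = simulate_cohort(cfg).df
        b = simulate_cohort(cfg).df
        pd.testing.assert_frame_equal(a, b)

    def test_identity_copula_gives_independence(self):
        cfg = default_config(n=10000, seed=2)
        cfg.corr_target = np.eye(5)
        r = empirical_correlations(simulate_cohort(cfg))
        off = np.abs(r[np.triu_indices(5, 1)])
        assert off.max() < 0.05

    def test_bmi_consistency_before_perturbation(self):
        df = simulate_cohort(default_config(n=500, seed=4)).df
        recomputed = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
        np.testing.assert_allclose(df["bmi"], recomputed, atol=1e-9)

    def test_perturbation_is_bounded_and_labels_stay_true(self):
        base = simulate_cohort(default_config(n=500, seed=4)).df
        pert = simulate_cohort(
            default_config(n=500, seed=4, perturb=Perturbation())).df
        assert np.abs(pert["height_cm"] - base["height_cm"]).max() <= 0.5
        assert np.abs(pert["weight_kg"] - base["weight_kg"]).max() <= 1.0
        # labels reflect the true (pre-jitter) BMI
        assert (pert["bmi_category"] == base["bmi_category"]).all()

    def test_class_mix_within_multinomial_band(self):
        """Generated category frequencies sit inside the multinomial 99%
        band; checked over 10 seeds, allowing the ~1% expected exceedance."""
        inside = 0
        for seed in range(10):
            df = simulate_cohort(default_config(n=6698, seed=seed)).df
            observed = df["bmi_category"].value_counts().reindex(
                list("ABCD")).to_numpy()
            _, p = chisquare(observed,
                             f_exp=np.array(REFERENCE_CLASS_COUNTS))
            inside += int(p >= 0.01)
        assert inside >= 9

    def test_calibration_band_over_twenty_seeds(self):
        """Off-diagonal empirical r stays within 3/sqrt(n) of target across
        seeds (allowing the ~1% expected exceedances)."""
        n = 6698
        band = 3.0 / np.sqrt(n)
        failures = 0
        for seed in range(20):
            cfg = default_config(n=n, seed=seed)
            r = empirical_correlations(simulate_cohort(cfg))
            diff = np.abs(r - cfg.corr_target)[np.triu_indices(5, 1)]
            failures += int((diff > band).sum())
        assert failures <= 2  # 200 checks, 99% band


class TestEmpiricalCorrelations:
    def test_perfect_linear_relation(self):
        df = simulate_cohort(default_config(n=50, seed=0)).df
        df["pullups"] = 2.0 * df["run_3000m_s"] + 1.0
        r = empirical_correlations(df)
        i, j = VARIABLES.index("run_3000m_s"), VARIABLES.index("pullups")
        assert r[i, j] == pytest.approx(1.0, abs=1e-12)

    def test_hand_table_matches_brute_force_pearson(self):
        vals = {
            "bmi": [20.0, 22.0, 25.0, 19.0],
            "run_3000m_s": [800.0, 830.0, 900.0, 780.0],
            "pullups": [12.0, 9.0, 4.0, 14.0],
            "situps": [40.0, 42.0, 33.0, 45.0],
            "shuttle_60m_s": [9.9, 10.2, 11.0, 9.7],
        }
        df = pd.DataFrame(vals)
        r = empirical_correlations(df)

        def pearson(a, b):  # brute-force covariance / sd formula
            a, b = np.asarray(a), np.asarray(b)
            am, bm = a - a.mean(), b - b.mean()
            return (am * bm).sum() / np.sqrt((am ** 2).sum()
                                             * (bm ** 2).sum())

        for i, vi in enumerate(VARIABLES):
            for j, vj in enumerate(VARIABLES):
                assert r[i, j] == pytest.approx(
                    pearson(vals[vi], vals[vj]), abs=1e-12)

    def test_zero_variance_column_named(self):
        df = simulate_cohort(default_config(n=20, seed=0)).df
        df["situps"] = 40
        with pytest.raises(ValueError, match="situps"):
            empirical_correlations(df)

    def test_too_few_records(self):
        df = simulate_cohort(default_config(n=2, seed=0)).df
        with pytest.raises(ValueError):
            empirical_correlations(df)


class TestCsvDialect:
    def test_roundtrip(self):
        cohort = simulate_cohort(default_config(n=40, seed=6))
        buf = io.StringIO(cohort.to_csv())
        back = Cohort.from_csv(buf)
        assert back.provenance == "file"
        assert list(back.df.columns) == list(cohort.df.columns)
        np.testing.assert_allclose(back.df["bmi"], cohort.df["bmi"],
                                   atol=1e-6)
        assert (back.df["bmi_category"] == cohort.df["bmi_category"]).all()

    def test_missing_column_rejected(self):
        buf = io.StringIO("id,pullups\n1,10\n")
        with pytest.raises(ValueError, match="missing"):
            Cohort.from_csv(buf)


def test_single_feature_config_plants_one_dependence():
    cfg = single_feature_config("run_3000m_s", strength=0.8, n=100, seed=0)
    expected = np.eye(5)
    expected[0, 1] = expected[1, 0] = 0.8
    np.testing.assert_array_equal(cfg.corr_target, expected)
    with pytest.raises(ValueError):
        single_feature_config("not_a_test")
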