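import numpy as np
import pandas as pd
import pytest

from wheatdecay.decay import (LN2, DecayModel, NormalizedProfile, _aicc,
                              compare_decay_curves,
                              decay_abundance_correlation, fit_decay,
                              format_half_life, half_life,
                              normalize_profiles, select_decay_factor_genes)


def make_profile(alpha, times=(0, 15, 30, 60, 120, 240, 480), replicates=3,
                 beta=None, noise=0.0, seed=0):
    t = np.asarray(times, dtype=float)
    if beta is None:
        log_mean = -alpha * t
    else:
        log_mean = -(alpha / beta) * (1.0 - np.exp(-beta * t))
    rng = np.random.default_rng(seed)
    rel = np.exp(log_mean)[:, None] * np.exp(
        rng.normal(0, noise, (len(t), replicates))
    )
    rel[0, :] = 1.0
    return NormalizedProfile("g", t, rel, np.ones((len(t), replicates)))


class TestHalfLife:
    def test_identity_in_hours(self):
        assert half_life(0.693147 / 60.0) == pytest.approx(1.0, abs=1e-6)

    def test_known_value(self):
        # alpha chosen so that ln2/alpha = 6.15 h
        alpha_per_min = LN2 / (6.15 * 60)
        assert half_life(alpha_per_min) == pytest.approx(6.15)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)

    def test_beyond_horizon_reporting(self):
        assert format_half_life(100.0) == "> 72 h"
        assert format_half_life(6.15) == "6.15 h"


class TestDecayFactorSelection:
    def test_constant_high_abundance_genes_win(self, make_table):
        # 5 stable genes at high abundance among decaying genes
        alphas = [0.0] * 5 + [0.005] * 20
        t0 = [1000.0] * 5 + [100.0] * 20
        table = make_table(alphas, t0=t0)
        assert set(select_decay_factor_genes(table, 5)) == {
            "g1", "g2", "g3", "g4", "g5"
        }

    def test_equal_decay_tie_break_is_deterministic(self, make_table):
        table = make_table([0.01] * 6, t0=[100.0] * 6)
        first = select_decay_factor_genes(table, 3)
        second = select_decay_factor_genes(table, 3)
        assert first == second  # documented tie-break: gene id order

    def test_planted_stable_set_recovery_under_noise(self):
        from wheatdecay.simulate import SimulationConfig, generate_decay_counts

        config = SimulationConfig(n_genes=800, seed=21, dispersion=0.01)
        table, truth = generate_decay_counts(config)
        planted = set(truth.loc[truth["is_stable_reference"], "gene"])
        selected = set(select_decay_factor_genes(table, len(planted)))
        jaccard = len(planted & selected) / len(planted | selected)
        assert jaccard >= 0.9

    def test_n_validation(self, make_table):
        table = make_table([0.01])
        with pytest.raises(ValueError):
            select_decay_factor_genes(table, 0)


class TestNormalization:
    def test_depth_change_absorbed_by_factors(self, make_table, times):
        drift = np.ones((7, 3))
        drift[3, :] = 0.5  # global depth halves at t=60
        table = make_table([0.0, 0.0, 0.01], t0=[1000, 900, 100], drift=drift)
        profiles = normalize_profiles(table, ["g1", "g2"])
        np.testing.assert_allclose(
            profiles["g1"].correction_factors[3, :], 0.5
        )
        # corrected stable profile is flat at 1
        np.testing.assert_allclose(
            profiles["g1"].relative_abundance, 1.0, atol=1e-12
        )

    def test_unit_factors_identity_up_to_t0(self, make_table):
        table = make_table([0.0, 0.004], t0=[500, 80])
        profiles = normalize_profiles(table, ["g1"])
        np.testing.assert_allclose(profiles["g1"].correction_factors, 1.0)
        np.testing.assert_allclose(
            profiles["g2"].relative_abundance[:, 0],
            table.gene_profile("g2")[:, 0] / table.gene_profile("g2")[0, 0],
        )

    def test_noiseless_exponential_under_drift_is_exact(self, make_table,
                                                        times):
        rng = np.random.default_rng(3)
        drift = np.exp(rng.normal(0, 0.3, (7, 3)))
        drift[0, :] = 1.0
        alpha = 0.003
        table = make_table([0.0, alpha], t0=[2000, 50], drift=drift)
        profiles = normalize_profiles(table, ["g1"])
        expected = np.exp(-alpha * times)
        np.testing.assert_allclose(
            profiles["g2"].relative_abundance,
            expected[:, None] * np.ones((1, 3)),
            rtol=1e-10,
        )

    def test_zero_abundance_factor_excluded_then_error(self, make_table):
        table = make_table([0.0, 0.0], t0=[100, 100])
        table.abundance[0, 2, 1] = 0.0
        with pytest.warns(UserWarning, match="excluded"):
            profiles = normalize_profiles(table, ["g1", "g2"])
        assert profiles  # g2 still usable
        table.abundance[1, 2, 1] = 0.0
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no usable"):
                normalize_profiles(table, ["g1", "g2"])

    def test_invariant_t0_is_one(self, make_table):
        table = make_table([0.002, 0.01], t0=[300, 30])
        for prof in normalize_profiles(table, ["g1"]).values():
            np.testing.assert_array_equal(prof.relative_abundance[0, :], 1.0)


class TestFitDecay:
    def test_noiseless_const_rate_recovery(self):
        fit = fit_decay(make_profile(0.01))
        assert fit.model == "const_rate"
        assert fit.alpha == pytest.approx(0.01, abs=1e-6)

    def test_noiseless_decaying_rate_recovery(self):
        fit = fit_decay(make_profile(0.02, beta=0.01))
        assert fit.model == "decaying_rate"
        assert fit.alpha == pytest.approx(0.02, rel=1e-4)
        assert fit.beta == pytest.approx(0.01, rel=1e-4)

    def test_half_life_identity_machine_precision(self):
        for alpha in (0.0005, 0.003, 0.05):
            fit = fit_decay(make_profile(alpha, noise=0.1, seed=4))
            assert np.exp(-fit.alpha * fit.half_life_minutes) == pytest.approx(
                0.5, abs=1e-12
            )

    def test_too_few_time_points_rejected(self):
        prof = make_profile(0.01, times=(0, 15, 30))
        with pytest.raises(ValueError, match="time points"):
            fit_decay(prof)

    def test_all_zero_profile_rejected(self):
        prof = make_profile(0.01)
        prof.relative_abundance[1:, :] = 0.0
        with pytest.raises(ValueError, match="all zero"):
            fit_decay(prof)

    def test_raw_scale_noiseless_recovery(self):
        fit = fit_decay(make_profile(0.005), log_scale=False)
        assert fit.alpha == pytest.approx(0.005, rel=1e-4)


class TestAicc:
    def test_large_n_reduces_to_aic(self):
        # the correction term 2k(k+1)/(n-k-1) vanishes as n grows
        logL = -10.0
        for k in (2, 3):
            aic = -2 * logL + 2 * k
            assert _aicc(logL, k, 10_000_000) == pytest.approx(aic, abs=1e-4)
            assert _aicc(logL, k, 18) > aic

    def test_small_n_guard(self):
        assert _aicc(-1.0, 3, 4) == np.inf


class TestCompareDecayCurves:
    def test_identical_profiles_not_significant(self):
        a = make_profile(0.005, noise=0.05, seed=1)
        b = NormalizedProfile("h", a.times, a.relative_abundance.copy(),
                              a.correction_factors.copy())
        _, p = compare_decay_curves(a, b, "a_faster")
        assert p >= 0.5

    def test_separated_curves_significant(self):
        a = make_profile(0.02, noise=0.02, seed=2)
        b = make_profile(0.001, noise=0.02, seed=3)
        _, p = compare_decay_curves(a, b, "a_faster")
        assert p < 0.001
        # the opposite direction is correspondingly non-significant
        _, p_rev = compare_decay_curves(b, a, "a_faster")
        assert p_rev > 0.5

    def test_single_replicate_rejected(self):
        a = make_profile(0.01, replicates=1)
        with pytest.raises(ValueError, match="replicates"):
            compare_decay_curves(a, a)

    def test_mismatched_grids_rejected(self):
        a = make_profile(0.01)
        b = make_profile(0.01, times=(0, 30, 60, 120, 240))
        with pytest.raises(ValueError, match="grids"):
            compare_decay_curves(a, b)


class TestDecayAbundanceCorrelation:
    def test_functional_dependence_gives_r_minus_one(self):
        alphas = np.geomspace(1e-4, 1e-2, 50)
        fits = pd.DataFrame({"gene": [f"g{i}" for i in range(50)],
                             "alpha_per_min": np.log10(alphas)})
        # abundance = c/alpha: log-abundance is affine in the stored rate
        abundance = pd.Series(100.0 / alphas,
                              index=[f"g{i}" for i in range(50)])
        r, _ = decay_abundance_correlation(fits, abundance)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        fits = pd.DataFrame({"gene": ["a", "b", "c"],
                             "alpha_per_min": [0.01, 0.01, 0.01]})
        abundance = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="variance"):
            decay_abundance_correlation(fits, abundance)

    def test_planted_anticorrelation_recovered(self):
        rng = np.random.default_rng(8)
        n = 5000
        target = -0.3
        z = rng.multivariate_normal(
            [0, 0], [[1, target], [target, 1]], size=n
        )
        genes = [f"g{i}" for i in range(n)]
        fits = pd.DataFrame({"gene": genes, "alpha_per_min": z[:, 0]})
        abundance = pd.Series(np.exp(z[:, 1]), index=genes)
        (r, _) = decay_abundance_correlation(fits, abundance)
        assert abs(r - target) < 0.05


class TestDecayModelResults:
    def test_fit_pipeline_and_summary(self, make_table):
        alphas = [0.0, 0.0, 0.003, 0.01, 0.0006, 0.002]
        table = make_table(alphas, t0=[2000, 1500, 100, 50, 80, 60])
        model = DecayModel(table, decay_factors=["g1", "g2"])
        results = model.fit()
        assert len(results.fits) == 6
        merged = results.rates[["g3", "g4", "g5", "g6"]]
        np.testing.assert_allclose(
            merged.to_numpy(), [0.003, 0.01, 0.0006, 0.002], rtol=1e-4
        )
        text = results.summary()
        assert "median half-life" in text

    def test_rate_deciles_are_balanced(self, make_table):
        rng = np.random.default_rng(5)
        alphas = rng.uniform(1e-4, 1e-2, 43)
        table = make_table(alphas)
        results = DecayModel(table, decay_factors="auto", n_factors=3).fit()
        deciles = results.rate_deciles()
        sizes = deciles.value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_per_replicate_rates_match_truth_noiselessly(self, make_table):
        table = make_table([0.0, 0.004], t0=[1000, 100])
        model = DecayModel(table, decay_factors=["g1"])
        rates = model.fit_per_replicate()
        np.testing.assert_allclose(rates.loc["g2"], 0.004, rtol=1e-4)
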