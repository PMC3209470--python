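"""2^-ddCt quantification, CV summaries, analytic power, validation summary."""

import numpy as np
import pytest
from scipy import stats

from senseq.qpcr import (
    PowerSpec,
    cv_summary,
    delta_delta_ct,
    genotype_ratio_test,
    load_validation_table,
    primer_efficiency,
    qpcr_gene_table,
    t_test_power,
    validation_summary,
)


class TestDeltaDeltaCt:
    def test_calibrator_maps_to_one(self):
        assert delta_delta_ct(24.0, 20.0, 4.0) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert delta_delta_ct(20.0, 15.0, 4.0) == pytest.approx(0.5)

    def test_one_cycle_doubles_expression(self):
        base = delta_delta_ct(22.0, 18.0, 0.0)
        assert delta_delta_ct(21.0, 18.0, 0.0) == pytest.approx(2.0 * base)

    def test_shared_reference_shift_cancels(self):
        a = delta_delta_ct(np.array([20.0, 22.0]), np.array([15.0, 15.0]), 3.0)
        b = delta_delta_ct(np.array([25.0, 27.0]), np.array([20.0, 20.0]), 3.0)
        np.testing.assert_allclose(a, b)

    def test_non_finite_input_is_an_error(self):
        with pytest.raises(ValueError):
            delta_delta_ct(np.nan, 20.0, 0.0)


class TestPrimerEfficiency:
    DILUTIONS = [1, 1 / 4, 1 / 16, 1 / 64, 1 / 256]

    def test_perfect_doubling_is_100pct(self):
        cts = 20.0 - np.log2(np.asarray(self.DILUTIONS))  # one cycle per 2-fold
        assert primer_efficiency(self.DILUTIONS, cts) == pytest.approx(100.0, abs=1e-9)

    def test_slope_minus_3_6_gives_89_5pct(self):
        cts = 20.0 - 3.6 * np.log10(np.asarray(self.DILUTIONS))
        # slope of Ct on log10(dilution) is -3.6 -> 10^(1/3.6) - 1
        assert primer_efficiency(self.DILUTIONS, cts) == pytest.approx(89.5, abs=0.1)

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError):
            primer_efficiency([1, 0.25], [20, 22])

    def test_non_negative_slope_is_an_error(self):
        with pytest.raises(ValueError, match="standard curve"):
            primer_efficiency(self.DILUTIONS, [20, 19, 18, 17, 16])


class TestGenotypeRatioTest:
    def test_identical_groups_give_unit_ratio_and_p_one(self):
        ratio, p = genotype_ratio_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert ratio == 1.0
        assert p == 1.0

    def test_label_swap_inverts_ratio_and_preserves_p(self):
        wt = [2.1, 2.5, 1.8, 2.2]
        rnai = [1.0, 1.2, 0.9, 1.1]
        r1, p1 = genotype_ratio_test(wt, rnai)
        r2, p2 = genotype_ratio_test(rnai, wt)
        assert r1 * r2 == pytest.approx(1.0)
        assert p1 == pytest.approx(p2)

    def test_zero_rnai_mean_is_an_error(self):
        with pytest.raises(ValueError):
            genotype_ratio_test([1.0, 2.0], [0.0, 0.0])

    def test_rejection_rate_matches_analytic_power(self):
        """Simulated fold 2, CV 0.5, n = 10: the empirical rejection fraction
        over 2000 draws agrees with the noncentral-t power within 2%."""
        rng = np.random.default_rng(17)
        n_sim, n = 2000, 10
        a = rng.normal(1.0, 0.5, size=(n_sim, n))
        b = rng.normal(2.0, 1.0, size=(n_sim, n))
        pooled = np.sqrt((a.var(1, ddof=1) + b.var(1, ddof=1)) / 2.0)
        t_stat = (b.mean(1) - a.mean(1)) / (pooled * np.sqrt(2.0 / n))
        crit = stats.t.ppf(0.975, 2 * n - 2)
        empirical = float((np.abs(t_stat) > crit).mean())
        assert empirical == pytest.approx(
            t_test_power(PowerSpec(2.0, 0.5, 10, 0.05)), abs=0.02
        )


class TestCvSummary:
    def test_constant_cvs_have_degenerate_interval(self):
        out = cv_summary([0.44, 0.44, 0.44])
        assert out["mean_cv"] == pytest.approx(0.44)
        assert out["ci_low"] == pytest.approx(0.44)
        assert out["ci_high"] == pytest.approx(0.44)

    def test_two_value_hand_interval(self):
        # mean 0.4, SE 0.1, t(0.975, df=1) = 12.706
        out = cv_summary([0.3, 0.5])
        assert out["mean_cv"] == pytest.approx(0.4)
        assert out["ci_low"] == pytest.approx(0.4 - 12.7062 * 0.1, abs=1e-3)
        assert out["ci_high"] == pytest.approx(0.4 + 12.7062 * 0.1, abs=1e-3)

    def test_mean_always_inside_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            cvs = rng.uniform(0.2, 0.7, size=rng.integers(2, 12))
            out = cv_summary(cvs)
            assert out["ci_low"] <= out["mean_cv"] <= out["ci_high"]

    def test_single_value_is_an_error(self):
        with pytest.raises(ValueError):
            cv_summary([0.4])


class TestPower:
    def test_null_fold_change_has_power_alpha(self):
        assert t_test_power(PowerSpec(1.0, 0.44, 10, 0.05)) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_n_fold_and_cv(self):
        base = PowerSpec(2.0, 0.44, 10, 0.05)
        assert t_test_power(PowerSpec(2.0, 0.44, 14, 0.05)) > t_test_power(base)
        assert t_test_power(PowerSpec(2.5, 0.44, 10, 0.05)) > t_test_power(base)
        assert t_test_power(PowerSpec(2.0, 0.55, 10, 0.05)) < t_test_power(base)

    def test_monte_carlo_agreement_across_grid(self):
        """Analytic power tracks a 2000-replicate Monte-Carlo within 2%."""
        rng = np.random.default_rng(5)
        for fold, cv, n in [(1.5, 0.4, 10), (2.0, 0.38, 10), (2.0, 0.5, 6)]:
            a = rng.normal(1.0, cv, size=(2000, n))
            b = rng.normal(fold, cv * fold, size=(2000, n))
            pooled = np.sqrt((a.var(1, ddof=1) + b.var(1, ddof=1)) / 2.0)
            t_stat = (b.mean(1) - a.mean(1)) / (pooled * np.sqrt(2.0 / n))
            crit = stats.t.ppf(0.975, 2 * n - 2)
            empirical = float((np.abs(t_stat) > crit).mean())
            assert empirical == pytest.approx(
                t_test_power(PowerSpec(fold, cv, n, 0.05)), abs=0.02
            )

    @pytest.mark.parametrize(
        "kwargs", [{"fold_change": 0}, {"cv": 0}, {"n_per_group": 1}, {"alpha": 1.0}]
    )
    def test_invalid_specs_are_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PowerSpec(**{"fold_change": 2.0, "cv": 0.44, "n_per_group": 10,
                         "alpha": 0.05, **kwargs})


class TestValidationSummary:
    def test_published_panel_counts(self):
        table = load_validation_table()
        out = validation_summary(table)
        assert out["n_tested"] == 22
        assert out["n_sig_12daa"] == 9
        assert out["n_large"] == 14
        assert out["n_sig_among_large"] == 9
        assert out["rate_among_large_pct"] == 64.0
        assert out["n_rescued_22daa"] == 2

    def test_significance_threshold_is_inclusive(self):
        # one panel gene sits exactly at p = 0.050 and must count as significant
        table = load_validation_table()
        at_boundary = table[table["p_12daa"] == 0.050]
        assert len(at_boundary) == 1
        strict = validation_summary(table, p_max=0.0499)
        assert strict["n_sig_12daa"] == 8

    def test_all_null_pvalues_give_zero_counts(self):
        table = load_validation_table().copy()
        table["p_12daa"] = 1.0
        table["p_22daa"] = 1.0
        out = validation_summary(table)
        assert out["n_tested"] == 22
        assert out["n_sig_12daa"] == 0
        assert out["n_sig_among_large"] == 0
        assert out["n_rescued_22daa"] == 0

    def test_missing_columns_are_an_error(self):
        table = load_validation_table().drop(columns=["p_22daa"])
        with pytest.raises(ValueError, match="missing"):
            validation_summary(table)


class TestQpcrGeneTable:
    def test_ratios_and_cvs_from_simulated_panel(self):
        from senseq.synthetic import simulate_qpcr

        table = simulate_qpcr(10, 10, cv=0.44, fold_change=2.0, seed=30)
        genes = qpcr_gene_table(table)
        assert len(genes) == 10
        assert genes["ratio"].median() == pytest.approx(2.0, rel=0.25)
        summary = cv_summary(genes["cv"])
        assert summary["ci_low"] < 0.44 < summary["ci_high"]
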