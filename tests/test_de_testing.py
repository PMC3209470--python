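"""The three DE tests, BH adjustment, fold change and the consensus caller.

The NB conditional tests are checked against an independent enumeration
oracle built from scipy's frozen distributions; the rank test against full
enumeration and scipy; BH against a brute-force step-up oracle and
statsmodels.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from senseq.detest import (
    ConsensusThresholds,
    bh_adjust,
    consensus_call,
    estimate_common_dispersion,
    fit_local_variance,
    fold_change,
    mww_test,
    nb_exact_test_pooled,
    nb_test_local,
    run_de_tests,
)
from senseq.normalization import VarianceFunction


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_conditional_p(total, observed_a, factors_a, factors_b, alpha):
    """Conditional two-sided NB p via scipy frozen distributions."""
    factors_a, factors_b = np.asarray(factors_a, float), np.asarray(factors_b, float)
    s_a, s_b = factors_a.sum(), factors_b.sum()
    mu_a, mu_b = total * s_a / (s_a + s_b), total * s_b / (s_a + s_b)
    eff_a = alpha * (factors_a**2).sum() / s_a**2
    eff_b = alpha * (factors_b**2).sum() / s_b**2

    def pmf(k, mu, a):
        if a == 0:
            return stats.poisson.pmf(k, mu)
        r = 1.0 / a
        return stats.nbinom.pmf(k, r, r / (r + mu))

    k = np.arange(total + 1)
    probs = pmf(k, mu_a, eff_a) * pmf(total - k, mu_b, eff_b)
    probs = probs / probs.sum()
    p_obs = probs[observed_a]
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def oracle_bh(p):
    """Brute-force step-up: for each p, the smallest level at which it is rejected."""
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        candidates = []
        for t in p[p >= pi - 1e-15]:
            rank = int((p <= t + 1e-15).sum())
            candidates.append(t * m / rank)
        q[i] = min(1.0, min(candidates))
    return q


class TestNbTests:
    def test_poisson_single_samples_reduce_to_binomial(self):
        """(0, 10) with one sample per group and equal factors: conditional law
        Binomial(10, 1/2), p = P(0) + P(10) = 2/1024."""
        p = nb_exact_test_pooled([0], [10], [1.0], [1.0], alpha=0.0)
        assert p == pytest.approx(2 / 1024, rel=1e-12)

    def test_modal_balanced_split_has_p_one(self):
        assert nb_exact_test_pooled([5], [5], [1.0], [1.0], alpha=0.0) == 1.0

    def test_zero_total_has_p_one(self):
        assert nb_exact_test_pooled([0, 0], [0, 0], [1, 1], [1, 1], 0.3) == 1.0

    @pytest.mark.parametrize("alpha", [0.0, 0.1, 0.5])
    @pytest.mark.parametrize(
        "counts_a,counts_b,factors_a,factors_b",
        [
            ([3, 7], [20, 1], [1.0, 1.2], [0.8, 1.1]),
            ([0, 2, 5], [30], [1.0, 1.0, 1.0], [1.0]),
            ([30, 25, 40, 35], [15, 20, 10], [1.1, 0.9, 1.0, 1.2], [0.95, 1.05, 1.0]),
        ],
    )
    def test_pooled_test_matches_enumeration_oracle(
        self, alpha, counts_a, counts_b, factors_a, factors_b
    ):
        total = int(np.sum(counts_a) + np.sum(counts_b))
        assert total <= 200
        expected = oracle_conditional_p(
            total, int(np.sum(counts_a)), factors_a, factors_b, alpha
        )
        observed = nb_exact_test_pooled(counts_a, counts_b, factors_a, factors_b, alpha)
        assert observed == pytest.approx(expected, abs=1e-10)

    def test_local_test_with_identity_variance_reduces_to_poisson(self):
        varfun = VarianceFunction.from_callable(lambda m: m, (1e-3, 1e4))
        p = nb_test_local([0], [10], [1.0], [1.0], varfun)
        assert p == pytest.approx(2 / 1024, rel=1e-9)

    def test_local_test_matches_enumeration_oracle(self):
        alpha = 0.25
        varfun = VarianceFunction.from_callable(
            lambda m: m + alpha * m**2, (1e-3, 1e4)
        )
        counts_a, counts_b = [12, 18], [40, 55, 30]
        factors_a, factors_b = [1.0, 1.1], [0.9, 1.2, 1.0]
        total = int(np.sum(counts_a) + np.sum(counts_b))
        # the local fit hands the test an effective alpha at the common-scale mean
        q = total / (np.sum(factors_a) + np.sum(factors_b))
        eff_alpha = (varfun(q) - q) / q**2
        expected = oracle_conditional_p(
            total, int(np.sum(counts_a)), factors_a, factors_b, float(eff_alpha)
        )
        observed = nb_test_local(counts_a, counts_b, factors_a, factors_b, varfun)
        assert observed == pytest.approx(expected, abs=1e-10)

    def test_group_label_swap_leaves_p_unchanged(self):
        args = ([3, 9], [25, 14], [1.0, 1.3], [0.9, 1.1])
        p_ab = nb_exact_test_pooled(args[0], args[1], args[2], args[3], 0.15)
        p_ba = nb_exact_test_pooled(args[1], args[0], args[3], args[2], 0.15)
        assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_negative_dispersion_is_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test_pooled([1], [2], [1.0], [1.0], alpha=-0.1)


class TestMww:
    def test_extreme_split_exact_p_is_2_over_35(self):
        assert mww_test([1, 2, 3], [4, 5, 6, 7], "exact") == pytest.approx(2 / 35)

    def test_normal_mode_matches_closed_form(self):
        # U = 0, mean 6, var 3*4*8/12 = 8 -> z = -6/sqrt(8)
        p = mww_test([1, 2, 3], [4, 5, 6, 7], "normal")
        assert p == pytest.approx(2 * stats.norm.sf(6 / np.sqrt(8)), rel=1e-12)
        assert p == pytest.approx(0.0339, abs=2e-4)

    def test_continuity_corrected_extreme_p_exceeds_005(self):
        # why the consensus default is the uncorrected normal mode: at 3 vs 4
        # neither the exact (2/35) nor the corrected normal variant can reach 0.05
        assert mww_test([1, 2, 3], [4, 5, 6, 7], "normal_cc") > 0.05
        assert mww_test([1, 2, 3], [4, 5, 6, 7], "exact") > 0.05
        assert mww_test([1, 2, 3], [4, 5, 6, 7], "normal") <= 0.05

    def test_constant_groups_give_p_one(self):
        assert mww_test([2, 2], [2, 2, 2], "exact") == 1.0
        assert mww_test([2, 2], [2, 2, 2], "normal") == 1.0

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_exact_mode_matches_scipy_enumeration(self, data):
        n_a = data.draw(st.integers(2, 4))
        n_b = data.draw(st.integers(2, 6 - (n_a - 2)))
        pool = data.draw(
            st.lists(st.integers(0, 8), min_size=n_a + n_b, max_size=n_a + n_b)
        )
        a, b = np.array(pool[:n_a], float), np.array(pool[n_a:], float)
        ours = mww_test(a, b, "exact")
        if len(np.unique(np.concatenate([a, b]))) == len(a) + len(b):
            # scipy's exact method only covers the tie-free case
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours == pytest.approx(ref.pvalue, rel=1e-9)
        assert 0.0 <= ours <= 1.0

    def test_swapping_groups_preserves_p(self):
        a, b = [1.0, 5.0, 2.0], [4.0, 8.0, 3.0, 9.0]
        for mode in ("exact", "normal", "normal_cc"):
            assert mww_test(a, b, mode) == pytest.approx(mww_test(b, a, mode))


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_equal_ps_are_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=10)
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_brute_force_and_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(p)
        np.testing.assert_allclose(ours, oracle_bh(p), atol=1e-12)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        assert (ours >= np.asarray(p) - 1e-15).all()

    def test_out_of_range_p_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFoldChange:
    def test_simple_ratio(self):
        assert fold_change(20.0, 10.0) == (2.0, 1.0)

    def test_zero_mean_uses_pseudocounts(self):
        ratio, log2fc = fold_change(10.0, 0.0)
        assert ratio == pytest.approx(21.0)  # (10 + 0.5) / 0.5

    def test_both_zero_is_excluded(self):
        ratio, log2fc = fold_change(0.0, 0.0)
        assert np.isnan(ratio) and np.isnan(log2fc)

    def test_label_swap_inverts_ratio(self):
        r, _ = fold_change(15.0, 6.0)
        r_swapped, _ = fold_change(6.0, 15.0)
        assert r * r_swapped == pytest.approx(1.0)


class TestConsensus:
    def row(self, q_pooled, q_local, p_mww, fold):
        return pd.Series(
            {"q_pooled": q_pooled, "q_local": q_local, "p_mww": p_mww,
             "fold_change": fold}
        )

    def test_all_criteria_met_calls_up(self):
        assert consensus_call(self.row(0.009, 0.009, 0.049, 2.1)) == "up"

    def test_failing_one_nb_test_blocks_the_call(self):
        assert consensus_call(self.row(0.009, 0.02, 0.01, 3.0)) == "none"

    def test_down_direction(self):
        assert consensus_call(self.row(0.005, 0.005, 0.04, 0.3)) == "down"

    def test_thresholds_are_inclusive(self):
        assert consensus_call(self.row(0.01, 0.01, 0.05, 2.0)) == "up"

    def test_fold_filter_is_two_sided(self):
        assert consensus_call(self.row(0.001, 0.001, 0.01, 1.8)) == "none"
        assert consensus_call(self.row(0.001, 0.001, 0.01, 0.5)) == "down"

    def test_call_set_shrinks_as_thresholds_tighten(self, small_experiment):
        result = run_de_tests(small_experiment.counts, small_experiment.samples)
        loose = (result["consensus"] != "none")
        for tighter in (
            ConsensusThresholds(q_pooled_max=0.005),
            ConsensusThresholds(q_local_max=0.005),
            ConsensusThresholds(p_mww_max=0.04),
            ConsensusThresholds(min_fold=3.0),
        ):
            calls = result.apply(lambda r: consensus_call(r, tighter), axis=1)
            tight = calls != "none"
            assert tight.sum() <= loose.sum()
            assert (tight & ~loose).sum() == 0  # strictly nested


class TestDispersionEstimation:
    def test_poisson_data_estimates_near_zero(self, poisson_experiment):
        experiment, factors = poisson_experiment
        alpha = estimate_common_dispersion(experiment.counts, factors, experiment.samples)
        assert alpha < 0.02

    def test_alpha_02_recovered_within_005(self, alpha02_experiment):
        experiment, factors = alpha02_experiment
        alpha = estimate_common_dispersion(experiment.counts, factors, experiment.samples)
        assert alpha == pytest.approx(0.2, abs=0.05)

    def test_single_sample_group_is_an_error(self, small_experiment):
        samples = small_experiment.samples.copy()
        samples.loc[["WT2", "WT3"], "included"] = False
        with pytest.raises(ValueError):
            estimate_common_dispersion(
                small_experiment.counts, small_experiment.size_factors, samples
            )


class TestLocalVarianceFit:
    def test_poisson_variance_recovered_within_15pct(self, poisson_experiment):
        experiment, factors = poisson_experiment
        varfun = fit_local_variance(experiment.counts, factors, experiment.samples)
        assert float(varfun(100.0)) == pytest.approx(100.0, rel=0.15)

    def test_nb_variance_recovered_within_15pct(self, alpha01_experiment):
        experiment, factors = alpha01_experiment
        varfun = fit_local_variance(experiment.counts, factors, experiment.samples)
        assert float(varfun(100.0)) == pytest.approx(1100.0, rel=0.15)

    def test_fit_is_non_decreasing(self, alpha01_experiment):
        experiment, factors = alpha01_experiment
        varfun = fit_local_variance(experiment.counts, factors, experiment.samples)
        grid = np.logspace(np.log10(varfun.domain[0]), np.log10(varfun.domain[1]), 200)
        w = varfun(grid)
        assert (np.diff(w) >= -1e-9 * w[:-1]).all()

    def test_too_few_features_is_an_error(self):
        from senseq.counts import make_sample_table

        counts = pd.DataFrame(
            np.random.default_rng(0).poisson(10, size=(5, 4)),
            columns=["a", "b", "c", "d"],
        )
        samples = make_sample_table(counts.columns, ["WT", "WT", "RNAi", "RNAi"])
        factors = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError, match="20"):
            fit_local_variance(counts, factors, samples)


class TestResultTable:
    def test_result_table_invariants(self, small_experiment):
        result = run_de_tests(small_experiment.counts, small_experiment.samples)
        for col in ("p_pooled", "p_local", "p_mww", "q_pooled", "q_local"):
            assert result[col].between(0, 1).all()
        assert (result["q_pooled"] >= result["p_pooled"] - 1e-12).all()
        assert (result["q_local"] >= result["p_local"] - 1e-12).all()
        called = result[result["consensus"] != "none"]
        assert ((called["consensus"] == "up") == (called["fold_change"] > 1)).all()

    def test_effect_recovery_with_fourfold_changes(self):
        """|log2FC| = 2, mean ~100, alpha = 0.1, 4 vs 3: the consensus caller
        recovers > 70% of true features with > 95% direction accuracy."""
        from senseq.synthetic import (
            DispersionModel,
            LfcDistribution,
            SimulationConfig,
            simulate_counts,
        )

        config = SimulationConfig(
            n_features=2000, frac_de=0.1, seed=3,
            lfc=LfcDistribution(location=2.0, scale=0.0),
            dispersion=DispersionModel(0.1, 0.0),
        )
        e = simulate_counts(config)
        result = run_de_tests(e.counts, e.samples)
        called = result["consensus"] != "none"
        recall = (called & e.truth.is_de).sum() / e.truth.is_de.sum()
        assert recall > 0.70
        hits = called & e.truth.is_de
        direction_accuracy = (
            result.loc[hits, "consensus"] == e.truth.loc[hits, "direction"]
        ).mean()
        assert direction_accuracy > 0.95
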