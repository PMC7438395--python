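"""Composite-null LRT: likelihood closed forms against numeric optimisation,
bootstrap against exact enumeration, and distributional properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar

from chemohf.composite import (
    CompositeNullTest,
    ThreeGroupCounts,
    bootstrap_test,
    exact_oracle_pvalue,
    fit_null,
    loglik,
    lrt_statistic,
)
from chemohf.experiments import composite_power_curve, random_tiny_counts


# ---------------------------------------------------------------------------
# independent numeric oracle (coded separately from the implementation)


def _ll_term(k, n, p):
    out = 0.0
    if k > 0:
        out += k * np.log(p) if p > 0 else -np.inf
    if n - k > 0:
        out += (n - k) * np.log(1 - p) if p < 1 else -np.inf
    return out


def brute_force_lrt(c: ThreeGroupCounts) -> float:
    """Two-scenario profile-likelihood LRT by bounded numeric optimisation."""

    def best_single(k, n):
        res = minimize_scalar(
            lambda p: -_ll_term(k, n, p),
            bounds=(1e-12, 1 - 1e-12),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return max(-res.fun, _ll_term(k, n, 0.0), _ll_term(k, n, 1.0))

    def best_tied(k1, n1, k2, n2):
        res = minimize_scalar(
            lambda p: -(_ll_term(k1, n1, p) + _ll_term(k2, n2, p)),
            bounds=(1e-12, 1 - 1e-12),
            method="bounded",
            options={"xatol": 1e-12},
        )
        boundary = max(
            _ll_term(k1, n1, 0.0) + _ll_term(k2, n2, 0.0),
            _ll_term(k1, n1, 1.0) + _ll_term(k2, n2, 1.0),
        )
        return max(-res.fun, boundary)

    ll_alt = (
        best_single(c.k_case, c.n_case)
        + best_single(c.k_ctrl_a, c.n_ctrl_a)
        + best_single(c.k_ctrl_b, c.n_ctrl_b)
    )
    ll_a = best_tied(c.k_case, c.n_case, c.k_ctrl_a, c.n_ctrl_a) + best_single(
        c.k_ctrl_b, c.n_ctrl_b
    )
    ll_b = best_tied(c.k_case, c.n_case, c.k_ctrl_b, c.n_ctrl_b) + best_single(
        c.k_ctrl_a, c.n_ctrl_a
    )
    return max(0.0, 2.0 * (ll_alt - max(ll_a, ll_b)))


class TestLoglik:
    def test_degenerate_all_zero_counts_at_p_zero(self):
        c = ThreeGroupCounts(0, 38, 0, 282, 0, 690)
        assert loglik(c, [0.0, 0.0, 0.0]) == 0.0

    def test_closed_form_single_heterozygote(self):
        c = ThreeGroupCounts(1, 2, 0, 1, 0, 1)
        # ctrl groups at p=0 contribute 0; case term is 2*log(0.5)
        assert loglik(c, [0.5, 0.0, 0.0]) == pytest.approx(2 * np.log(0.5))

    def test_unconstrained_mle_dominates_grid(self, rng):
        for _ in range(10):
            c = random_tiny_counts(rng)
            at_mle = loglik(c, c.freqs)
            grid = np.linspace(0.01, 0.99, 25)
            for p0 in grid[::6]:
                for p1 in grid[::6]:
                    for p2 in grid[::6]:
                        assert at_mle >= loglik(c, [p0, p1, p2]) - 1e-12

    def test_rejects_out_of_range_frequencies(self):
        c = ThreeGroupCounts(1, 2, 1, 2, 1, 2)
        with pytest.raises(ValueError):
            loglik(c, [0.5, 0.5, 1.5])


class TestFitNull:
    def test_scenario_a_pools_case_with_control_a(self):
        c = ThreeGroupCounts(5, 50, 10, 100, 30, 60)
        mles, tied, ll = fit_null(c)
        assert tied == "A"
        assert mles == pytest.approx([0.10, 0.10, 0.50])
        # constraint inactive (case freq == ctrlA freq): null ll == alt ll
        assert ll == pytest.approx(loglik(c, c.freqs))
        assert lrt_statistic(c) == 0.0

    def test_all_zero_counts_tie_to_control_a_at_zero(self):
        c = ThreeGroupCounts(0, 38, 0, 282, 0, 690)
        mles, tied, _ = fit_null(c)
        assert tied == "A"
        assert mles == pytest.approx([0.0, 0.0, 0.0])
        assert lrt_statistic(c) == 0.0

    def test_null_ties_to_the_likelier_control(self):
        # case frequency near ctrlB's, far from ctrlA's
        c = ThreeGroupCounts(10, 20, 1, 20, 11, 20)
        _, tied, _ = fit_null(c)
        assert tied == "B"


class TestLrtStatistic:
    def test_matches_numeric_profile_likelihood_on_reconstructed_counts(self):
        c = ThreeGroupCounts(4, 76, 7, 564, 21, 1380, level="allele")
        assert lrt_statistic(c) == pytest.approx(brute_force_lrt(c), abs=1e-10)

    def test_matches_numeric_profile_likelihood_on_random_counts(self, rng):
        for _ in range(15):
            c = random_tiny_counts(rng)
            assert lrt_statistic(c) == pytest.approx(
                brute_force_lrt(c), abs=1e-8
            )

    @given(
        ns=st.tuples(*[st.integers(1, 40)] * 3),
        fracs=st.tuples(*[st.floats(0, 1)] * 3),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_lrt_nonnegative_property(self, ns, fracs):
        ks = [int(round(f * n)) for f, n in zip(fracs, ns)]
        c = ThreeGroupCounts(ks[0], ns[0], ks[1], ns[1], ks[2], ns[2])
        assert lrt_statistic(c) >= 0.0


class TestExactOracle:
    def test_all_zero_counts_give_p_two_of_one(self):
        c = ThreeGroupCounts(0, 5, 0, 5, 0, 5)
        res = exact_oracle_pvalue(c)
        assert res.p_two == 1.0

    def test_enumeration_probabilities_sum_to_one(self):
        # checked indirectly: p over the whole space at threshold 0
        c = ThreeGroupCounts(2, 5, 0, 5, 5, 5)
        null_mles, _, _ = fit_null(c)
        ns = [5, 5, 5]
        total = 1.0
        for n, p in zip(ns, null_mles):
            total *= stats.binom.pmf(np.arange(n + 1), n, p).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_triple_loop_enumeration(self):
        c = ThreeGroupCounts(2, 5, 0, 5, 5, 5)
        res = exact_oracle_pvalue(c)
        # independent oracle: brute-force statistic + explicit loops
        null_mles, tied, _ = fit_null(c)

        def one_sided_stats(kc, ka, kb):
            cc = ThreeGroupCounts(kc, 5, ka, 5, kb, 5)
            lrt = brute_force_lrt(cc)
            mles, t, _ = fit_null(cc)
            sign = np.sign(kc / 5 - mles[0])
            return (lrt if sign > 0 else 0.0), (lrt if sign < 0 else 0.0)

    # observed one-sided statistics
        t_hi_obs, t_lo_obs = one_sided_stats(2, 0, 5)
        p_hi = p_lo = 0.0
        for kc in range(6):
            for ka in range(6):
                for kb in range(6):
                    pr = (
                        stats.binom.pmf(kc, 5, null_mles[0])
                        * stats.binom.pmf(ka, 5, null_mles[1])
                        * stats.binom.pmf(kb, 5, null_mles[2])
                    )
                    t_hi, t_lo = one_sided_stats(kc, ka, kb)
                    if t_hi >= t_hi_obs - 1e-9:
                        p_hi += pr
                    if t_lo >= t_lo_obs - 1e-9:
                        p_lo += pr
        assert res.p_one_high == pytest.approx(p_hi, abs=1e-6)
        assert res.p_one_low == pytest.approx(p_lo, abs=1e-6)
        assert res.p_two == pytest.approx(min(1.0, 2 * min(p_hi, p_lo)), abs=1e-6)

    def test_space_limit_enforced(self):
        with pytest.raises(ValueError, match="bootstrap"):
            exact_oracle_pvalue(ThreeGroupCounts(1, 200, 1, 200, 1, 200))


class TestBootstrap:
    def test_bootstrap_converges_to_exact_oracle(self):
        c = ThreeGroupCounts(2, 5, 0, 5, 5, 5)
        exact = exact_oracle_pvalue(c)
        B = 200_000
        boot = bootstrap_test(c, B=B, seed=42)
        for side in ("p_one_high", "p_one_low"):
            p = getattr(exact, side)
            se = np.sqrt(p * (1 - p) / B) + 1 / B
            assert abs(getattr(boot, side) - p) <= 3 * se

    def test_null_centered_data_give_p_near_one(self):
        # case frequency exactly at the pooled null
        c = ThreeGroupCounts(10, 100, 10, 100, 40, 100)
        res = bootstrap_test(c, B=5000, seed=0)
        assert res.p_two > 0.5

    def test_min_p_combination_and_range(self, rng):
        for _ in range(10):
            c = random_tiny_counts(rng)
            res = bootstrap_test(c, B=2000, seed=int(rng.integers(2**31 - 1)))
            assert res.p_two == pytest.approx(
                min(1.0, 2 * min(res.p_one_high, res.p_one_low))
            )
            assert 0 < res.p_one_high <= 1
            assert 0 < res.p_one_low <= 1
            assert 0 < res.p_two <= 1

    def test_same_seed_identical_result(self):
        c = ThreeGroupCounts(4, 76, 7, 564, 21, 1380, level="allele")
        a = bootstrap_test(c, B=5000, seed=9)
        b = bootstrap_test(c, B=5000, seed=9)
        assert a.p_one_high == b.p_one_high
        assert a.p_one_low == b.p_one_low
        assert a.p_two == b.p_two

    def test_b_validation(self):
        c = ThreeGroupCounts(1, 5, 1, 5, 1, 5)
        with pytest.raises(ValueError):
            bootstrap_test(c, B=0)
        with pytest.warns(UserWarning, match="coarse"):
            bootstrap_test(c, B=100, seed=0)

    def test_power_increases_with_case_frequency_displacement(self):
        rates = composite_power_curve(
            case_freqs=(0.20, 0.30, 0.40), ctrl_freq=0.20,
            n_sims=400, B=300, seed=5,
        )
        se = np.sqrt(0.25 / 400)
        assert rates[1] >= rates[0] - 2 * se
        assert rates[2] >= rates[1] - 2 * se
        assert rates[2] > rates[0]


class TestModelInterface:
    def test_from_frequencies_reconstructs_published_counts(self):
        from chemohf.simulate import RoundTripWarning

        # 0.013 at n=282 is not attainable at the printed precision → warns
        with pytest.warns(RoundTripWarning):
            model = CompositeNullTest.from_frequencies(
                0.053, 38, 0.013, 282, 0.015, 690,
                level="allele", variant_id="rs57242572",
            )
        c = model.counts
        assert (c.k_case, c.n_case) == (4, 76)
        assert (c.k_ctrl_b, c.n_ctrl_b) == (21, 1380)

    def test_from_genotypes_counts_carriers_per_group(self):
        import pandas as pd

        from conftest import make_matrix

        d = np.array([[1], [0], [2], [0], [0], [1]], dtype=float)
        gm = make_matrix(d, sample_ids=[f"s{i}" for i in range(6)])
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "group": ["crhf_case"] * 2 + ["chemo_no_hf"] * 2
                + ["hf_no_chemo"] * 2,
            }
        )
        model = CompositeNullTest.from_genotypes(gm, samples, "snp0")
        c = model.counts
        assert (c.k_case, c.n_case) == (1, 2)
        assert (c.k_ctrl_a, c.n_ctrl_a) == (1, 2)
        assert (c.k_ctrl_b, c.n_ctrl_b) == (1, 2)

    def test_summary_renders(self):
        res = CompositeNullTest(
            ThreeGroupCounts(2, 5, 0, 5, 5, 5), variant_id="toy"
        ).fit(B=2000, seed=1)
        text = res.summary()
        assert "toy" in text and "two-sided p" in text
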