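"""The top-fraction set statistic and its Monte-Carlo null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirwin.annotations import MirnaWindow, WindowSnpSet
from mirwin.ld import LDMatrix
from mirwin.settest import (SetTestConfig, empirical_p, p_to_chisq,
                            simulate_null_stats, top_fraction_stat,
                            window_rng)
from mirwin.settest import test_window as run_set_test

from conftest import ar1_matrix


@pytest.mark.parametrize("p, expected", [
    (1.0, 0.0),
    (0.05, 3.8415),  # chi2(1) 5% critical value
    (0.5, 0.4549),
])
def test_p_to_chisq_quantiles(p, expected):
    assert p_to_chisq(p) == pytest.approx(expected, abs=1e-4)


def test_p_to_chisq_roundtrip_and_validation():
    p = np.array([1e-8, 1e-3, 0.2, 1.0])
    np.testing.assert_allclose(stats.chi2.sf(p_to_chisq(p), 1), p, rtol=1e-10)
    for bad in (0.0, -0.1, 1.1):
        with pytest.raises(ValueError):
            p_to_chisq(bad)


@pytest.mark.parametrize("values, f, exp_k, exp_stat", [
    ([3.0], 0.1, 1, 3.0),
    ([9.0] + [1.0] * 9, 0.1, 1, 9.0),
    (list(range(25)), 0.1, 3, 24 + 23 + 22),  # ceil(2.5) = 3
    ([1.0, 2.0, 3.0], 1.0, 3, 6.0),
])
def test_top_fraction_stat(values, f, exp_k, exp_stat):
    k, stat = top_fraction_stat(values, f)
    assert k == exp_k and stat == pytest.approx(exp_stat)


def test_top_fraction_stat_empty_rejected():
    with pytest.raises(ValueError, match="empty"):
        top_fraction_stat([], 0.1)


@given(st.lists(st.floats(0.0, 100.0), min_size=1, max_size=60),
       st.floats(0.01, 1.0))
@settings(max_examples=200, deadline=None)
def test_top_fraction_stat_matches_sorted_sum(values, f):
    """Property: stat equals the sum of the k largest, k = max(1, ceil(f*m))."""
    k, stat = top_fraction_stat(values, f)
    expected_k = min(len(values), max(1, int(np.ceil(f * len(values)))))
    assert k == expected_k
    assert stat == pytest.approx(sum(sorted(values)[-k:]), rel=1e-12)


def test_single_snp_null_is_chisq1():
    sims = simulate_null_stats(np.eye(1), f=0.1, nsim=10_000, rng=0)
    _, pval = stats.kstest(sims, stats.chi2(df=1).cdf)
    assert pval > 0.01


def test_independent_full_sum_is_chisq4():
    sims = simulate_null_stats(np.eye(4), f=1.0, nsim=10_000, rng=1)
    _, pval = stats.kstest(sims, stats.chi2(df=4).cdf)
    assert pval > 0.01


def test_simulation_deterministic_for_seed():
    R = ar1_matrix(6, 0.5)
    a = simulate_null_stats(R, 0.1, 500, rng=42)
    b = simulate_null_stats(R, 0.1, 500, rng=42)
    np.testing.assert_array_equal(a, b)


def test_non_psd_matrix_rejected():
    R = np.array([[1.0, 0.9, 0.4], [0.9, 1.0, 0.8], [0.4, 0.8, 1.0]])
    with pytest.raises(ValueError, match="PSD"):
        simulate_null_stats(R, 0.1, 10, rng=0)


@pytest.mark.parametrize("n_above, nsim, expected", [
    (3, 999, 0.004),
    (0, 999, 0.001),
])
def test_empirical_p_add_one_rule(n_above, nsim, expected):
    sims = np.concatenate([np.full(n_above, 10.0), np.full(nsim - n_above, 0.0)])
    assert empirical_p(5.0, sims) == pytest.approx(expected)


def test_empirical_p_observed_below_all_is_one():
    assert empirical_p(-1.0, np.zeros(999)) == pytest.approx(1.0)


def test_empirical_p_monotone_in_observed():
    sims = np.random.default_rng(3).chisquare(1, size=2_000)
    grid = np.linspace(0, 10, 50)
    ps = [empirical_p(x, sims) for x in grid]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def _window_set(snp_ids, positions, name="mir-test"):
    win = MirnaWindow(name=name, chrom="1", tx_start=positions[0],
                      tx_end=positions[-1], win_start=positions[0] - 1,
                      win_end=positions[-1] + 1)
    return WindowSnpSet(window=win, snp_ids=list(snp_ids),
                        positions=list(positions))


def _sumstats(snp_ids, positions, pvals):
    return pd.DataFrame({"SNP": snp_ids, "CHR": "1", "BP": positions,
                         "P": pvals})


def test_single_snp_window_recovers_snp_p():
    """With one SNP the set test reduces to the SNP test itself."""
    ws = _window_set(["rsA"], [100])
    ss = _sumstats(["rsA"], [100], [0.02])
    R = LDMatrix(snp_ids=["rsA"], R=np.eye(1))
    cfg = SetTestConfig(sim_stages=(100_000,))
    res = run_set_test(ws, ss, R, cfg, rng=np.random.default_rng(5))
    se = np.sqrt(0.02 * 0.98 / 100_000)
    assert res.empirical_p == pytest.approx(0.02, abs=3 * se)
    assert res.top_snp_id == "rsA" and res.top_snp_p == 0.02


def test_full_fraction_identity_ld_matches_chisq_tail():
    pvals = [0.3, 0.05, 0.6, 0.1]
    ws = _window_set([f"rs{i}" for i in range(4)], [100, 200, 300, 400])
    ss = _sumstats([f"rs{i}" for i in range(4)], [100, 200, 300, 400], pvals)
    R = LDMatrix(snp_ids=[f"rs{i}" for i in range(4)], R=np.eye(4))
    cfg = SetTestConfig(top_fraction=1.0, sim_stages=(200_000,))
    res = run_set_test(ws, ss, R, cfg, rng=np.random.default_rng(6))
    expected = stats.chi2.sf(res.observed_stat, df=4)
    se = np.sqrt(expected * (1 - expected) / 200_000)
    assert res.empirical_p == pytest.approx(expected, abs=3 * se)


def test_top_snp_selection_and_sim_count():
    """Top SNP is the smallest p; escalation stops once exceedances suffice."""
    ids = [f"rs{i}" for i in range(10)]
    pos = list(range(100, 1100, 100))
    pvals = [0.5] * 10
    pvals[3] = 0.2
    ws = _window_set(ids, pos)
    ss = _sumstats(ids, pos, pvals)
    R = LDMatrix(snp_ids=ids, R=np.eye(10))
    cfg = SetTestConfig(sim_stages=(1_000, 10_000))
    res = run_set_test(ws, ss, R, cfg, rng=np.random.default_rng(7))
    assert res.top_snp_id == "rs3" and res.top_snp_p == 0.2
    assert res.n_sims_used == 1_000  # p ~ 0.87, no escalation
    assert res.n_snps_tested == 10


def test_escalation_on_small_p():
    ids = ["rsA", "rsB"]
    ws = _window_set(ids, [100, 200])
    ss = _sumstats(ids, [100, 200], [1e-7, 0.5])
    R = LDMatrix(snp_ids=ids, R=np.eye(2))
    cfg = SetTestConfig(sim_stages=(1_000, 10_000))
    res = run_set_test(ws, ss, R, cfg, rng=np.random.default_rng(8))
    assert res.n_sims_used == 10_000
    assert res.empirical_p == pytest.approx(1 / 10_001, abs=2e-4)


def test_window_rng_independent_of_order():
    a1 = window_rng(1, "mir-a").standard_normal(3)
    b1 = window_rng(1, "mir-b").standard_normal(3)
    b2 = window_rng(1, "mir-b").standard_normal(3)
    a2 = window_rng(1, "mir-a").standard_normal(3)
    np.testing.assert_array_equal(a1, a2)
    np.testing.assert_array_equal(b1, b2)
    assert not np.allclose(a1, b1)


def test_untestable_window_flagged():
    ws = _window_set(["rsA"], [100])
    ss = _sumstats(["rsA"], [100], [0.5])
    R = LDMatrix(snp_ids=[], R=np.empty((0, 0)))
    res = run_set_test(ws, ss, R, SetTestConfig())
    assert res.untestable
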