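"""Ascertainment bound, enrichment tests, FDR, CIs, cohort comparison,
transmission power."""

import numpy as np
import pytest
from scipy import stats

from cesscan.discovery import (
    AscertainmentModel,
    bh_fdr,
    compare_cohorts,
    enrichment_with_ci,
    gof_variant_test,
    lof1_gene_test,
    lof2_select,
    transmission_power,
)


def test_ascertainment_bound_is_inverse_prevalence():
    assert AscertainmentModel(0.01).max_fold == 100.0
    assert AscertainmentModel(1.0).max_fold == 1.0
    with pytest.raises(ValueError):
        AscertainmentModel(0.0)
    with pytest.raises(ValueError):
        AscertainmentModel(1.5)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


def _bh_oracle(p):
    """Hand step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


def test_bh_single_p_is_identity():
    assert bh_fdr([0.03]) == pytest.approx([0.03])


def test_bh_hand_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_all_ones():
    assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_bh_matches_step_up_oracle(rng):
    p = rng.uniform(0, 1, 200)
    np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), rtol=1e-12)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


# ---------------------------------------------------------------------------
# GoF variant test
# ---------------------------------------------------------------------------


def _nb_tail_oracle(obs, mean, gamma):
    """Upper tail by explicit pmf summation to a far cutoff."""
    r = mean / gamma
    p = 1.0 / (1.0 + gamma)
    ks = np.arange(0, obs)
    return 1.0 - stats.nbinom.pmf(ks, r, p).sum()


def test_gof_observed_zero_has_p_one():
    res = gof_variant_test([0], [0.5], AscertainmentModel(0.01), 0.004, 10)
    assert res["p_value"].iloc[0] == pytest.approx(1.0)


def test_gof_gamma_zero_equals_poisson_tail():
    ascert = AscertainmentModel(0.01)
    obs = np.array([3, 7, 0, 12])
    lam = np.array([0.01, 0.02, 0.005, 0.03])
    res = gof_variant_test(obs, lam, ascert, 0.0, 100)
    expected = stats.poisson.sf(obs - 1, lam * 100)
    np.testing.assert_allclose(res["p_value"], expected, rtol=1e-12)


@pytest.mark.parametrize("obs", [1, 3, 8])
@pytest.mark.parametrize("mean", [0.5, 2.0])
@pytest.mark.parametrize("gamma", [0.004, 0.5])
def test_gof_tail_matches_summation_oracle(obs, mean, gamma):
    ascert = AscertainmentModel(1.0)  # max_fold 1: null mean = expected
    res = gof_variant_test([obs], [mean], ascert, gamma, 1)
    assert res["p_value"].iloc[0] == pytest.approx(
        _nb_tail_oracle(obs, mean, gamma), rel=1e-9
    )


def test_gof_skips_nonpositive_expectation():
    res = gof_variant_test([1, 2], [0.0, 1.0], AscertainmentModel(0.01),
                           0.004, 10)
    assert len(res) == 1
    assert res.attrs["n_skipped"] == 1


def test_gof_bonferroni_uses_external_test_count():
    res = gof_variant_test([5], [0.001], AscertainmentModel(0.01), 0.004,
                           n_tests=1_000_000)
    assert res["p_bonferroni"].iloc[0] == pytest.approx(
        min(1.0, res["p_value"].iloc[0] * 1_000_000)
    )


# ---------------------------------------------------------------------------
# LoF-1 / LoF-2
# ---------------------------------------------------------------------------


def test_lof1_null_mean_is_hundredfold_expectation():
    res = lof1_gene_test([10], [0.2], AscertainmentModel(0.01), 100)
    assert res["expected"].iloc[0] == pytest.approx(20.0)
    assert res["p_value"].iloc[0] == pytest.approx(
        stats.poisson.sf(9, 20.0)
    )


def test_lof1_central_observation_never_genome_significant():
    mean = 20.0
    res = lof1_gene_test([int(np.ceil(mean))], [mean],
                         AscertainmentModel(1.0), 17_791)
    assert 0.2 < res["p_value"].iloc[0] < 0.8
    assert not res["bonferroni_significant"].iloc[0]


def test_lof2_loeuf_boundary():
    obs = np.array([50, 50, 0])
    lam = np.array([1.0, 1.0, 1.0])
    loeuf = np.array([0.4, 0.51, 0.9])
    res = lof2_select(obs, lam, loeuf, units=np.array(["a", "b", "c"]))
    sel = set(res[res["selected"]]["unit"])
    assert sel == {"b"}  # q tiny for a and b, but a fails LOEUF > 0.5


def test_lof2_missing_loeuf_excluded_and_tallied():
    res = lof2_select([50], [1.0], [np.nan])
    assert not res["selected"].iloc[0]
    assert res.attrs["n_missing_loeuf"] == 1


# ---------------------------------------------------------------------------
# enrichment CI
# ---------------------------------------------------------------------------


def test_enrichment_ci_brackets_ratio():
    est = enrichment_with_ci(10, 10.0)
    assert est.ratio == pytest.approx(1.0)
    assert est.ci_low < 1.0 < est.ci_high


def test_enrichment_ci_zero_observed():
    est = enrichment_with_ci(0, 5.0)
    assert est.ratio == 0.0
    assert est.ci_low == 0.0
    assert est.ci_high > 0.0


def test_enrichment_ci_wald_limit():
    est = enrichment_with_ci(10_000, 1_000.0)
    wald = 2 * 1.959964 * np.sqrt(10_000) / 1_000.0
    width = est.ci_high - est.ci_low
    assert width == pytest.approx(wald, rel=0.05)


def test_enrichment_ci_coverage(rng):
    """95% coverage of the Gamma-conjugate interval over Poisson draws."""
    mean = 7.0
    obs = rng.poisson(mean, 2000)
    lo = np.where(obs == 0, 0.0, stats.gamma.ppf(0.025, obs + 0.5))
    hi = stats.gamma.ppf(0.975, obs + 0.5)
    cover = np.mean((lo <= mean) & (mean <= hi))
    assert 0.93 <= cover <= 0.97


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------


def test_compare_cohorts_symmetric_null():
    res = compare_cohorts(5, 5, 1.0, 1.0, 1)
    assert res["p_excess_sperm"] >= 0.5
    assert res["p_excess_trio"] >= 0.5


def test_compare_cohorts_matches_enumeration_oracle():
    n_trio, m_sperm = 4, 9
    lam_t, lam_s = 0.3, 0.5
    res = compare_cohorts(n_trio, m_sperm, lam_t, lam_s, 5)
    p = lam_s / (lam_s + lam_t)
    trials = n_trio + m_sperm
    # enumerate the binomial pmf directly
    pmf = [
        stats.binom.pmf(k, trials, p) for k in range(trials + 1)
    ]
    assert res["p_excess_sperm"] == pytest.approx(
        sum(pmf[m_sperm:]), rel=1e-9
    )
    assert res["p_excess_trio"] == pytest.approx(
        sum(pmf[: trials - n_trio + 1]), rel=1e-9
    )
    assert res["p_excess_sperm_bonferroni"] == pytest.approx(
        min(1.0, res["p_excess_sperm"] * 5)
    )


def test_compare_cohorts_requires_counts_in_both():
    with pytest.raises(ValueError):
        compare_cohorts(0, 3, 1.0, 1.0, 1)
    with pytest.raises(ValueError):
        compare_cohorts(3, 3, 0.0, 0.0, 1)


def test_sperm_excess_detected_for_lethal_like_gene():
    # strong sperm excess with trio deficit (embryonic deleteriousness)
    res = compare_cohorts(1, 30, 1.0, 1.0, 5)
    assert res["p_excess_sperm_bonferroni"] < 0.05
    assert res["p_excess_trio"] > 0.5


# ---------------------------------------------------------------------------
# transmission power
# ---------------------------------------------------------------------------


def test_power_size_at_null_kappa():
    for alpha in (0.05, 0.01, 0.001):
        for n in (5, 20, 50, 100):
            assert transmission_power(1.0, n, alpha) <= alpha


def test_power_rejects_kappa_below_one():
    with pytest.raises(ValueError):
        transmission_power(0.5, 10, 0.05)


def test_power_alpha_ordering():
    for n in (10, 30, 80):
        for kappa in (2, 5, 20):
            p05 = transmission_power(kappa, n, 0.05)
            p01 = transmission_power(kappa, n, 0.01)
            p001 = transmission_power(kappa, n, 0.001)
            assert p05 >= p01 >= p001


def test_power_matches_enumeration_oracle():
    kappa, n, alpha, b = 5.0, 12, 0.05, 0.75
    p_alt = b * kappa / (b * kappa + (1 - b))
    # oracle: smallest c with P(X>=c|b) <= alpha, then P(X>=c|p_alt)
    c = next(
        c for c in range(n + 2)
        if sum(stats.binom.pmf(k, n, b) for k in range(c, n + 1)) <= alpha
    )
    oracle = sum(stats.binom.pmf(k, n, p_alt) for k in range(c, n + 1))
    assert transmission_power(kappa, n, alpha) == pytest.approx(
        oracle, rel=1e-9
    )
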