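"""Discovery of CES driver candidates from de novo counts.

The central idea: in a cohort ascertained for a disease of prevalence
``P(D)``, disease ascertainment can inflate observed de novo counts over
mutational expectation by at most ``1/P(D)``.  With a conservative
prevalence lower bound ``P*(D)`` the maximal ascertainment fold is
``1/P*(D)`` (100 at the 1% default).  Genes or variants whose observed
counts significantly exceed expectation times this bound cannot be
explained by ascertainment and point to an elevated effective mutation
rate — the signature of clonal expansion in spermatogonia (CES).

Three candidate sets are built:

* GoF: per-missense-variant Negative Binomial test against
  ``lambda_v / P*(D)`` (overdispersion factor ``gamma`` from the
  dispersion module);
* LoF-1: per-gene exact Poisson test of LoF counts against
  ``lambda_g / P*(D)``;
* LoF-2: per-gene Poisson test against plain ``lambda_g`` (no
  prevalence scaling) at FDR < 0.1, intersected with weak population
  constraint (LOEUF > 0.5) — genes tolerated in the population yet
  LoF-hypermutable in trios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AscertainmentModel",
    "bh_fdr",
    "gof_variant_test",
    "lof1_gene_test",
    "lof2_select",
    "enrichment_with_ci",
    "compare_cohorts",
    "transmission_power",
    "EnrichmentEstimate",
]


@dataclass(frozen=True)
class AscertainmentModel:
    """Upper bound on fold-enrichment attributable to ascertainment.

    ``max_fold = 1 / prevalence_lower_bound`` per the ascertainment
    inequality #obs/#exp <= 1/P(D).
    """

    prevalence_lower_bound: float

    def __post_init__(self):
        p = self.prevalence_lower_bound
        if not (0 < p <= 1):
            raise ValueError("prevalence_lower_bound must be in (0, 1]")

    @property
    def max_fold(self) -> float:
        return 1.0 / self.prevalence_lower_bound


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _negbin_sf(observed: np.ndarray, mean: np.ndarray, gamma: float):
    """Upper tail P(K >= observed) for NegBin(mean, var=mean*(1+gamma))."""
    r = mean / gamma
    p_success = 1.0 / (1.0 + gamma)
    return stats.nbinom.sf(observed - 1, r, p_success)


def _poisson_sf(observed: np.ndarray, mean: np.ndarray):
    return stats.poisson.sf(observed - 1, mean)


def _result_frame(units, observed, expected_null, p, n_tests, alpha=0.05):
    q = bh_fdr(p)
    p_bonf = np.minimum(1.0, p * n_tests)
    return pd.DataFrame(
        {
            "unit": units,
            "observed": observed,
            "expected": expected_null,
            "fold": observed / expected_null,
            "p_value": p,
            "q_value": q,
            "p_bonferroni": p_bonf,
            "bonferroni_significant": p_bonf < alpha,
        }
    )


def gof_variant_test(
    observed,
    expected,
    ascert: AscertainmentModel,
    gamma: float,
    n_tests: int,
    units=None,
) -> pd.DataFrame:
    """Per-variant Negative Binomial test against maximal ascertainment.

    The null mean is ``expected * ascert.max_fold``; ``expected`` is the
    cohort-scaled per-site expectation ``lambda_v``.  ``gamma`` is the
    single-site overdispersion factor (0 falls back to the exact Poisson
    tail).  Bonferroni correction uses ``n_tests`` (the full number of
    candidate missense variants genome-wide, not just those passed in);
    BH q-values are computed across the variants tested here.  Sites
    with nonpositive expectation are skipped and reported in the
    attribute ``.attrs["n_skipped"]``.
    """
    observed = np.asarray(observed, dtype=np.int64)
    expected = np.asarray(expected, dtype=float)
    if units is None:
        units = np.arange(observed.size)
    units = np.asarray(units)
    keep = expected > 0
    n_skipped = int((~keep).sum())
    observed, expected, units = observed[keep], expected[keep], units[keep]
    null_mean = expected * ascert.max_fold
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma == 0:
        p = _poisson_sf(observed, null_mean)
    else:
        p = _negbin_sf(observed, null_mean, gamma)
    out = _result_frame(units, observed, null_mean, p, n_tests)
    out.attrs["n_skipped"] = n_skipped
    return out


def lof1_gene_test(
    observed,
    expected_gene,
    ascert: AscertainmentModel,
    n_tests: int,
    units=None,
) -> pd.DataFrame:
    """Per-gene exact Poisson test of LoF counts against
    ``lambda_g * max_fold``.

    Bonferroni-significant genes (0.05 over ``n_tests``) form the core
    LoF-1 set; the BH q-value column supports the looser FDR < 0.1 call.
    """
    observed = np.asarray(observed, dtype=np.int64)
    expected = np.asarray(expected_gene, dtype=float)
    if units is None:
        units = np.arange(observed.size)
    units = np.asarray(units)
    keep = expected > 0
    n_skipped = int((~keep).sum())
    observed, expected, units = observed[keep], expected[keep], units[keep]
    null_mean = expected * ascert.max_fold
    p = _poisson_sf(observed, null_mean)
    out = _result_frame(units, observed, null_mean, p, n_tests)
    out.attrs["n_skipped"] = n_skipped
    return out


def lof2_select(
    observed,
    expected_gene,
    loeuf,
    units=None,
    fdr: float = 0.1,
    loeuf_threshold: float = 0.5,
) -> pd.DataFrame:
    """LoF-2 candidate selection.

    Exact Poisson test of observed LoF counts against the *unscaled*
    expectation ``lambda_g`` (no prevalence factor), BH-corrected across
    all tested genes; candidates are the genes with ``q < fdr`` and
    ``LOEUF > loeuf_threshold``.  Genes lacking a LOEUF score cannot be
    selected and are tallied in ``.attrs["n_missing_loeuf"]``.
    """
    observed = np.asarray(observed, dtype=np.int64)
    expected = np.asarray(expected_gene, dtype=float)
    loeuf = np.asarray(loeuf, dtype=float)
    if units is None:
        units = np.arange(observed.size)
    units = np.asarray(units)
    keep = expected > 0
    observed, expected = observed[keep], expected[keep]
    units, loeuf = units[keep], loeuf[keep]
    p = _poisson_sf(observed, expected)
    q = bh_fdr(p)
    missing = np.isnan(loeuf)
    selected = (q < fdr) & ~missing & (loeuf > loeuf_threshold)
    out = pd.DataFrame(
        {
            "unit": units,
            "observed": observed,
            "expected": expected,
            "fold": observed / expected,
            "p_value": p,
            "q_value": q,
            "loeuf": loeuf,
            "selected": selected,
        }
    )
    out.attrs["n_missing_loeuf"] = int((missing & (q < fdr)).sum())
    return out


@dataclass(frozen=True)
class EnrichmentEstimate:
    """Observed/expected ratio with a 95% Gamma-conjugate interval."""

    ratio: float
    ci_low: float
    ci_high: float


def enrichment_with_ci(
    observed: int, expected: float, level: float = 0.95
) -> EnrichmentEstimate:
    """Poisson-conjugate (Gamma) confidence interval for an
    observed/expected ratio.

    A Jeffreys Gamma(1/2, 0) prior on the Poisson mean gives posterior
    Gamma(observed + 1/2, 1); the interval is its central quantile range
    divided by ``expected``.  At ``observed = 0`` the lower limit is 0.
    """
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if observed < 0:
        raise ValueError("observed must be >= 0")
    a = observed + 0.5
    tail = (1.0 - level) / 2.0
    lo = 0.0 if observed == 0 else stats.gamma.ppf(tail, a) / expected
    hi = stats.gamma.ppf(1.0 - tail, a) / expected
    return EnrichmentEstimate(
        ratio=observed / expected, ci_low=float(lo), ci_high=float(hi)
    )


def compare_cohorts(
    n_trio: int,
    m_sperm: int,
    lambda_trio: float,
    lambda_sperm: float,
    n_genes_tested: int,
    gene_id: str = "",
) -> dict:
    """Binomial comparison of LoF excess between a trio cohort and
    sperm sequencing for one gene.

    Conditional on the total ``n_trio + m_sperm`` observed LoF variants,
    the number arising in sperm is Binomial with success probability
    ``lambda_sperm / (lambda_sperm + lambda_trio)`` under equal
    enrichment.  Both one-sided exact tails are reported (excess in
    sperm, e.g. embryonic-lethal variants depleted from trios; excess in
    trios, e.g. disease ascertainment), Bonferroni-corrected over
    ``n_genes_tested``.  Only genes with at least one LoF variant in
    both datasets are tested.
    """
    if lambda_trio <= 0 and lambda_sperm <= 0:
        raise ValueError("both expectations are zero")
    if n_trio < 1 or m_sperm < 1:
        raise ValueError(
            "tested only with at least one LoF variant in both datasets"
        )
    p_sperm = lambda_sperm / (lambda_sperm + lambda_trio)
    if not (0 < p_sperm < 1):
        raise ValueError("expected fraction must lie strictly in (0, 1)")
    trials = n_trio + m_sperm
    p_excess_sperm = float(stats.binom.sf(m_sperm - 1, trials, p_sperm))
    p_excess_trio = float(stats.binom.sf(n_trio - 1, trials, 1.0 - p_sperm))
    return {
        "gene_id": gene_id,
        "n_trio": int(n_trio),
        "m_sperm": int(m_sperm),
        "expected_fraction_sperm": float(p_sperm),
        "p_excess_sperm": p_excess_sperm,
        "p_excess_trio": p_excess_trio,
        "p_excess_sperm_bonferroni": min(1.0, p_excess_sperm * n_genes_tested),
        "p_excess_trio_bonferroni": min(1.0, p_excess_trio * n_genes_tested),
    }


def transmission_power(
    kappa: float,
    n_variants: int,
    alpha: float,
    baseline: float = 0.75,
) -> float:
    """Exact power of the one-sided binomial test for paternal
    overtransmission.

    Under CES the odds of paternal origin are inflated kappa-fold over
    the baseline paternal fraction, giving the alternative fraction
    ``p = baseline*kappa / (baseline*kappa + 1 - baseline)``.  The test
    rejects when the observed paternal count reaches the smallest
    critical value whose null upper tail is <= alpha; power is the
    alternative upper tail at that critical value, by enumeration.
    At ``kappa = 1`` this returns the realised test size (<= alpha).
    """
    if kappa < 1:
        raise ValueError("kappa must be >= 1 (inflation-only model)")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if not (0 < baseline < 1):
        raise ValueError("baseline must be in (0, 1)")
    p_alt = baseline * kappa / (baseline * kappa + (1.0 - baseline))
    k = np.arange(n_variants + 2)
    null_tail = stats.binom.sf(k - 1, n_variants, baseline)
    crit = np.argmax(null_tail <= alpha)
    if null_tail[crit] > alpha:  # no achievable rejection region
        return 0.0
    return float(stats.binom.sf(crit - 1, n_variants, p_alt))
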