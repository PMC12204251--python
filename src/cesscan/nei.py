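"""Mutation-selection-drift decomposition of population allele counts.

Under recurrent mutation and strong heterozygote selection ``s``, the
population frequency ``q`` of a derived LoF allele follows a Gamma
distribution with shape ``4*Ne*mu`` and scale ``1/(4*Ne*s)`` (the Nei
approximation); a sample of ``n`` haploid genomes then yields a
Gamma-Poisson (negative binomial) allele count ``k``.  A CES-driven
mutation-rate inflation ``kappa`` multiplies the shape but not the
scale, so across the sites of a gene:

    E(k)   = kappa * n * E(mu) / s
    Var(k) = kappa * n*E(mu)/s * (1 + n/(4*Ne*s))
             + kappa^2 * (n/s)^2 * Var(mu)

Two per-gene estimators follow.  The mean-based estimator
``kappa/s = mean(k) / (n * mean(mu))`` responds linearly to CES; the
variance-based drift estimator
``(E_mu[Var(k|mu)] - E(k)) / E(k) = n/(4*Ne*s)`` does not depend on
``kappa``.  Comparing the two across genes (log-log regression) makes
CES genes stand out as positive residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "NeiGeneEstimate",
    "filter_nei_genes",
    "nei_decompose",
    "ces_residuals",
    "rate_linearity_regression",
    "NEI_MIN_MU",
    "NEI_MIN_SITES",
]

#: Site retention: unscaled baseline rate strictly above this (CpG-like).
NEI_MIN_MU = 1.0
#: Gene retention: at least this many qualifying sites.
NEI_MIN_SITES = 10


def filter_nei_genes(
    table: pd.DataFrame,
    min_mu: float = NEI_MIN_MU,
    min_sites: int = NEI_MIN_SITES,
) -> pd.DataFrame:
    """Retain sites with ``mu > min_mu`` in genes having at least
    ``min_sites`` such sites.

    The high-rate (CpG-like) sites carry nearly all of the information
    about recurrent-mutation frequencies; low-rate sites only add
    sampling noise to the per-gene moments.
    """
    high = table[table["mu"] > min_mu]
    sizes = high.groupby("gene_id")["mu"].transform("size")
    return high[sizes >= min_sites].copy()


@dataclass
class NeiGeneEstimate:
    """Per-gene decomposition of allele-count moments."""

    gene_id: str
    kappa_over_s: float  # mean(k) / (n * mean(mu)); responds to CES
    drift_term: float  # n/(4*Ne*s) estimate; kappa-invariant
    var_mu_term: float  # rate-heterogeneity variance component
    n_sites: int
    drift_nonpositive: bool = False


def nei_decompose(table: pd.DataFrame, n: int) -> Optional[NeiGeneEstimate]:
    """Moment estimators for one gene's allele-count table.

    Parameters
    ----------
    table
        Sites of a single gene with columns ``gene_id``, ``k``
        (observed derived allele count) and ``mu`` (baseline rate, in
        the same units used when generating/observing the counts).
    n
        Haploid sample size.

    Returns
    -------
    ``NeiGeneEstimate``, or ``None`` when ``mean(k) = 0`` (no
    information about selection).

    Notes
    -----
    The rate-heterogeneity term is estimated as ``slope^2 * Var(mu)``
    with the slope from the through-origin Poisson regression of ``k``
    on ``mu`` (MLE ``sum(k)/sum(mu)``); the drift term is estimated by
    subtracting it from the total sample variance of ``k`` and then
    removing Poisson sampling noise (equal to the mean).  Sampling noise
    can exceed the remainder in finite samples, giving a nonpositive
    drift estimate; it is reported as-is and flagged.
    """
    gene_ids = table["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ValueError("nei_decompose expects a single-gene table")
    k = table["k"].to_numpy(dtype=float)
    mu = table["mu"].to_numpy(dtype=float)
    if np.any(k < 0) or np.any(mu <= 0):
        raise ValueError("k must be >= 0 and mu > 0")
    kbar = k.mean()
    if kbar == 0:
        return None
    mubar = mu.mean()
    kappa_over_s = kbar / (n * mubar)

    slope = k.sum() / mu.sum()  # Poisson MLE of the proportional model
    var_mu = mu.var(ddof=1) if mu.size > 1 else 0.0
    var_mu_term = slope**2 * var_mu

    var_k = k.var(ddof=1) if k.size > 1 else 0.0
    e_var_k_given_mu = var_k - var_mu_term
    var_sampling = kbar  # Poisson noise = E(k)
    drift = (e_var_k_given_mu - var_sampling) / var_sampling
    return NeiGeneEstimate(
        gene_id=str(gene_ids[0]),
        kappa_over_s=float(kappa_over_s),
        drift_term=float(drift),
        var_mu_term=float(var_mu_term),
        n_sites=int(k.size),
        drift_nonpositive=bool(drift <= 0),
    )


def decompose_all(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """Apply :func:`nei_decompose` gene by gene; skipped genes tallied
    in ``.attrs``."""
    rows = []
    n_skipped = 0
    for gene_id, sub in table.groupby("gene_id", sort=True):
        est = nei_decompose(sub, n)
        if est is None:
            n_skipped += 1
            continue
        rows.append(est.__dict__)
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "kappa_over_s",
            "drift_term",
            "var_mu_term",
            "n_sites",
            "drift_nonpositive",
        ],
    )
    out.attrs["n_genes_skipped_zero_mean"] = n_skipped
    return out


def ces_residuals(estimates: pd.DataFrame) -> pd.DataFrame:
    """Residuals of log(kappa_over_s) on log(drift_term) across genes.

    ``log(kappa/s)`` and ``log(n/(4*Ne*s))`` differ by a constant offset
    plus ``log(kappa)``, so genes with CES-inflated mutation rates sit
    above the least-squares line.  Genes with nonpositive drift or mean
    estimates cannot enter the log-log regression and are excluded
    (tallied in ``.attrs``).
    """
    ok = (estimates["drift_term"] > 0) & (estimates["kappa_over_s"] > 0)
    sub = estimates[ok]
    n_excluded = int((~ok).sum())
    if len(sub) < 10:
        raise ValueError(
            "need >= 10 genes with positive drift and mean estimates"
        )
    x = np.log(sub["drift_term"].to_numpy())
    y = np.log(sub["kappa_over_s"].to_numpy())
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: drift terms identical")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    out = pd.DataFrame(
        {
            "gene_id": sub["gene_id"].to_numpy(),
            "log_drift": x,
            "log_kappa_over_s": y,
            "residual": resid,
        }
    )
    out.attrs["slope"] = float(slope)
    out.attrs["intercept"] = float(intercept)
    out.attrs["n_excluded_nonpositive"] = n_excluded
    return out


def rate_linearity_regression(
    table: pd.DataFrame,
    n_bins: int = 10,
    min_bin_sites: int = 10,
):
    """Through-origin Poisson regression of ``k`` on ``mu`` for one
    gene, with rate-binned mean frequencies for display.

    The slope is the Poisson MLE ``sum(k)/sum(mu)`` of the proportional
    model ``k ~ Poisson(c * mu)`` — under CES the allele frequency stays
    linear in the baseline rate, so a straight line through the origin
    fits both CES and non-CES genes, differing only in slope.  Sites are
    binned by ``mu`` (equal-width on the observed range); bins with
    fewer than ``min_bin_sites`` sites are merged into the next-highest
    bin, the final (highest-rate) bin merging downward if needed.

    Returns ``(slope, bins)`` where ``bins`` has columns
    ``mean_mu``, ``mean_k``, ``n_sites``.
    """
    k = table["k"].to_numpy(dtype=float)
    mu = table["mu"].to_numpy(dtype=float)
    if mu.sum() <= 0:
        raise ValueError("sum of mu must be > 0")
    slope = float(k.sum() / mu.sum())

    lo, hi = mu.min(), mu.max()
    if lo == hi:
        bins_df = pd.DataFrame(
            {"mean_mu": [mu.mean()], "mean_k": [k.mean()],
             "n_sites": [mu.size]}
        )
        return slope, bins_df
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(mu, edges[1:-1]), 0, n_bins - 1)

    # merge small bins upward (into the next-highest occupied bin)
    groups: list[list[int]] = [
        list(np.flatnonzero(idx == b)) for b in range(n_bins)
    ]
    groups = [g for g in groups if g]
    merged: list[list[int]] = []
    carry: list[int] = []
    for g in groups:
        g = carry + g
        if len(g) < min_bin_sites:
            carry = g
        else:
            merged.append(g)
            carry = []
    if carry:  # leftover small top bin merges downward
        if merged:
            merged[-1].extend(carry)
        else:
            merged.append(carry)

    bins_df = pd.DataFrame(
        {
            "mean_mu": [mu[g].mean() for g in merged],
            "mean_k": [k[g].mean() for g in merged],
            "n_sites": [len(g) for g in merged],
        }
    )
    return slope, bins_df
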