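"""Synthetic cohorts with the statistical structure the analyses assume.

Every generator mirrors the generative model of the corresponding
analysis stage:

* per-site baseline rates with a heavy-tailed (log-normal) body plus a
  CpG-like point mass of high-rate sites (``mu > 1``);
* de novo counts per site drawn Poisson or Gamma-Poisson (negative
  binomial) around ``lambda_v * kappa_gene * ascertainment_gene``,
  where ``kappa`` is the CES mutation-rate inflation and the
  ascertainment fold is capped at the inverse prevalence bound;
* subcohort labels allocated multinomially (or Dirichlet-multinomially)
  with per-subcohort synonymous-count weights;
* population allele counts from the Gamma-Poisson
  mutation-selection-drift model (Gamma frequency with shape
  ``4*Ne*kappa*mu``, scale ``1/(4*Ne*s)``; Poisson sampling of ``n``
  alleles);
* sperm-sequencing-like per-gene Poisson counts with CES inflation but
  no disease ascertainment.

All generators are deterministic under a fixed seed: a single study
seed expands into fixed per-stage child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import ExpectationTable

__all__ = [
    "SyntheticConfig",
    "gen_sites",
    "gen_denovo_cohort",
    "gen_population_afs",
    "gen_sperm_counts",
]

# fixed child-stream indices of the study seed
_STREAMS = {
    "sites": 0,
    "denovo": 1,
    "popgen": 2,
    "sperm": 3,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a large neurodevelopmental-disorder trio cohort:
    synonymous scaler ``ns_count`` of 8000 events, three subcohorts with
    weights proportional to their synonymous counts, single-site
    overdispersion ``gamma = 0.004``, disease prevalence bounded below
    at 1% (maximal ascertainment fold 100), and a gnomAD-scale
    population sample of 1.6 million haploid genomes with effective
    population size 10,000 and heterozygote selection 0.05 on LoF
    variants.  ``rate_scale`` converts the unscaled per-site rate
    (CpG-like transitions sit at ``mu`` of roughly 10-30) to a
    per-generation mutation probability.
    """

    seed: int = 0
    n_genes: int = 100
    lof_sites_per_gene: int = 60
    syn_sites_per_gene: int = 120
    mis_sites_per_gene: int = 180
    # mutation-rate distribution (unscaled, dimensionless)
    mu_log_mean: float = np.log(0.3)
    mu_log_sigma: float = 0.8
    cpg_fraction: float = 0.2
    cpg_mu_low: float = 2.0
    cpg_mu_high: float = 30.0
    # cohort structure
    ns_count: int = 8000
    subcohort_names: tuple = ("DDD-like", "GeneDx-like", "RUMC-like")
    subcohort_weights: tuple = (0.32, 0.60, 0.08)
    dirichlet_concentration: Optional[float] = None  # None -> multinomial
    gamma: float = 0.004
    prevalence_lower_bound: float = 0.01
    # per-gene effects; keys are gene ids, everything else gets default
    gene_kappa: dict = field(default_factory=dict)
    gene_ascertainment: dict = field(default_factory=dict)
    gene_loeuf: dict = field(default_factory=dict)
    default_kappa: float = 1.0
    default_ascertainment: float = 1.0
    # fraction of genes generated as overlapping pairs, to exercise
    # non-overlap selection
    overlap_pair_fraction: float = 0.05
    # per-gene selection-against-heterozygotes used by the SFS stage
    gene_shet: dict = field(default_factory=dict)
    default_shet: float = 0.1
    # population-genetic sampling
    ne: float = 1.0e4
    gene_s: dict = field(default_factory=dict)
    default_s: float = 0.05
    n_haploid: int = 1_600_000
    # converts unscaled mu to a per-generation rate; chosen so CpG-like
    # sites (mu of 2-30) recur enough in a biobank-scale sample to carry
    # information (expected allele counts of order 10-100), the regime
    # the mean/variance decomposition targets
    rate_scale: float = 1.5e-7
    # sperm sequencing
    sperm_scale: float = 1.0
    embryonic_lethal_genes: tuple = ()
    embryonic_lethal_deflation: float = 0.2

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not (0 <= self.cpg_fraction <= 1):
            raise ValueError("cpg_fraction must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.prevalence_lower_bound <= 1):
            raise ValueError("prevalence_lower_bound must be in (0, 1]")
        max_fold = 1.0 / self.prevalence_lower_bound
        for g, a in self.gene_ascertainment.items():
            if not (1.0 <= a <= max_fold + 1e-9):
                raise ValueError(
                    f"ascertainment fold {a} for {g} outside [1, 1/P(D)]"
                )
        for g, k in self.gene_kappa.items():
            if k < 1.0:
                raise ValueError(f"kappa {k} for {g} must be >= 1")
        if len(self.subcohort_weights) != len(self.subcohort_names):
            raise ValueError("subcohort weights/names length mismatch")
        if min(self.subcohort_weights) <= 0:
            raise ValueError("subcohort weights must be positive")
        if self.default_s <= 0 or any(s <= 0 for s in self.gene_s.values()):
            raise ValueError("selection coefficients must be > 0")

    def gene_ids(self) -> list:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def kappa_of(self, gene_id: str) -> float:
        return float(self.gene_kappa.get(gene_id, self.default_kappa))

    def ascertainment_of(self, gene_id: str) -> float:
        return float(
            self.gene_ascertainment.get(gene_id, self.default_ascertainment)
        )

    def s_of(self, gene_id: str) -> float:
        return float(self.gene_s.get(gene_id, self.default_s))

    def shet_of(self, gene_id: str) -> float:
        return float(self.gene_shet.get(gene_id, self.default_shet))


def _draw_mu(rng: np.random.Generator, size: int,
             config: SyntheticConfig) -> np.ndarray:
    """Heavy-tailed body plus CpG-like point mass above mu = 1."""
    mu = rng.lognormal(config.mu_log_mean, config.mu_log_sigma, size)
    is_cpg = rng.random(size) < config.cpg_fraction
    # log-uniform over the CpG range keeps a realistic spread of
    # high-rate transitions
    mu[is_cpg] = np.exp(
        rng.uniform(np.log(config.cpg_mu_low), np.log(config.cpg_mu_high),
                    int(is_cpg.sum()))
    )
    return mu


_BASES = np.array(["A", "C", "G", "T"])


def gen_sites(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the per-site variant table and the BED-like gene table.

    A configurable fraction of genes is laid down as overlapping pairs
    so that non-overlap gene selection is exercised; site positions fall
    inside their gene's CDS interval.
    """
    config.validate()
    rng = _rng(config.seed, "sites")
    gene_ids = config.gene_ids()
    per_gene = (
        config.lof_sites_per_gene
        + config.syn_sites_per_gene
        + config.mis_sites_per_gene
    )

    gene_rows = []
    cursor = 10_000
    i = 0
    n = len(gene_ids)
    while i < n:
        span = max(3 * per_gene, 300)
        make_pair = (
            i + 1 < n and rng.random() < config.overlap_pair_fraction
        )
        gene_rows.append(("chr1", cursor, cursor + span, gene_ids[i]))
        if make_pair:
            # shorter gene overlapping the previous one
            start2 = cursor + span // 2
            gene_rows.append(
                ("chr1", start2, start2 + span // 3, gene_ids[i + 1])
            )
            i += 2
        else:
            i += 1
        cursor += span + 1_000
    genes_df = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "gene_id"]
    )

    lof_cons = np.array(
        ["stop_gained", "splice_donor_variant", "splice_acceptor_variant"]
    )
    frames = []
    for _, grow in genes_df.iterrows():
        gid = grow["gene_id"]
        start, end = int(grow["start"]), int(grow["end"])
        n_lof = config.lof_sites_per_gene
        n_syn = config.syn_sites_per_gene
        n_mis = config.mis_sites_per_gene
        n_sites = min(n_lof + n_syn + n_mis, end - start)
        if n_sites == 0:
            continue
        pos = np.sort(
            rng.choice(end - start, size=n_sites, replace=False)
        ) + start + 1  # 1-based site coordinates
        mu = _draw_mu(rng, n_sites, config)
        ref_idx = rng.integers(0, 4, n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
        labels = np.array(
            ["LoF"] * n_lof + ["synonymous"] * n_syn + ["missense"] * n_mis
        )[:n_sites]
        cons = np.empty(n_sites, dtype=object)
        is_lof = labels == "LoF"
        cons[is_lof] = lof_cons[
            rng.choice(3, size=int(is_lof.sum()), p=[0.6, 0.2, 0.2])
        ]
        cons[labels == "synonymous"] = "synonymous_variant"
        is_mis = labels == "missense"
        cons[is_mis] = "missense_variant"
        score = np.full(n_sites, np.nan)
        n_mis_actual = int(is_mis.sum())
        mis_score = rng.uniform(0.11, 1.0, n_mis_actual)
        # a minority below the 0.1 admissibility threshold
        low = rng.random(n_mis_actual) < 0.1
        mis_score[low] = rng.uniform(0.0, 0.1, int(low.sum()))
        score[is_mis] = mis_score
        qual = np.where(rng.random(n_sites) < 0.97, "high", "other")
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gid,
                    "chrom": "chr1",
                    "pos": pos,
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "mu": mu,
                    "qual": qual,
                    "consequence": cons,
                    "lof_hc": is_lof,
                    "missense_score": score,
                }
            )
        )
    sites_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "gene_id", "chrom", "pos", "ref", "alt", "mu", "qual",
                "consequence", "lof_hc", "missense_score",
            ]
        )
    )
    return sites_df, genes_df


def gen_denovo_cohort(
    config: SyntheticConfig, expectations: ExpectationTable
) -> pd.DataFrame:
    """Draw per-site de novo counts and expand them to labelled events.

    Per-site counts are Poisson at mean
    ``lambda_v * kappa_gene * ascertainment_gene`` (functional classes;
    synonymous sites stay at ``lambda_v``) when ``gamma = 0``; with
    ``gamma > 0`` the per-site rate is first drawn from
    ``Gamma(shape=mean/gamma, scale=gamma)``, the exact mixture behind
    a Negative Binomial with variance ``mean*(1+gamma)``.  Each event is
    then assigned a subcohort label; with a Dirichlet concentration set,
    per-gene probabilities are drawn Dirichlet around the weights first.
    """
    config.validate()
    rng = _rng(config.seed, "denovo")
    sites = expectations.sites
    kappa = sites["gene_id"].map(config.kappa_of).to_numpy()
    ascert = sites["gene_id"].map(config.ascertainment_of).to_numpy()
    # CES inflation and disease ascertainment act on functional classes;
    # synonymous sites stay at baseline — they are the neutral yardstick
    # the expectation model normalises against
    functional = (sites["variant_class"] != "synonymous").to_numpy()
    mean = sites["lam"].to_numpy() * np.where(functional, kappa * ascert,
                                              1.0)
    if config.embryonic_lethal_genes:
        lethal = sites["gene_id"].isin(config.embryonic_lethal_genes)
        is_lof = sites["variant_class"] == "LoF"
        mean = np.where(
            lethal & is_lof, mean * config.embryonic_lethal_deflation, mean
        )
    if config.gamma > 0:
        # exact Poisson-Gamma mixture for NegBin(mean, var=mean*(1+gamma)):
        # per-site rate ~ Gamma(shape=mean/gamma, scale=gamma)
        pos = mean > 0
        rate = np.zeros_like(mean)
        rate[pos] = rng.gamma(mean[pos] / config.gamma, config.gamma)
        counts = rng.poisson(rate)
    else:
        counts = rng.poisson(mean)

    weights = np.asarray(config.subcohort_weights, dtype=float)
    probs = weights / weights.sum()
    names = np.asarray(config.subcohort_names)

    idx = np.repeat(np.arange(counts.size), counts)
    events = sites.iloc[idx][
        ["chrom", "pos", "ref", "alt", "gene_id", "variant_class"]
    ].reset_index(drop=True)
    n_events = len(events)
    if config.dirichlet_concentration is None:
        labels = rng.choice(len(names), size=n_events, p=probs)
    else:
        labels = np.empty(n_events, dtype=np.int64)
        gene_arr = events["gene_id"].to_numpy()
        for gid in pd.unique(gene_arr):
            sel = gene_arr == gid
            p_g = rng.dirichlet(config.dirichlet_concentration * probs)
            labels[sel] = rng.choice(len(names), size=int(sel.sum()), p=p_g)
    events.insert(4, "subcohort", names[labels])
    return events


def gen_population_afs(config: SyntheticConfig,
                       sites: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Sample population LoF allele counts from the Gamma-Poisson
    mutation-selection-drift model.

    Per site: frequency ``q ~ Gamma(shape=4*Ne*kappa*mu_rate,
    scale=1/(4*Ne*s))`` with ``mu_rate = mu * rate_scale``, then
    ``k ~ Poisson(n_haploid * q)``, clamped at ``n_haploid`` (clamps
    tallied in ``.attrs``).  Refuses parameter sets implying per-site
    expected frequencies above 0.1, where the strong-selection
    approximation breaks down.
    """
    config.validate()
    rng = _rng(config.seed, "popgen")
    if sites is None:
        sites, _ = gen_sites(config)
    lof = sites[sites["consequence"].astype(str).str.contains(
        "stop_gained|splice_donor|splice_acceptor")].copy()
    gene = lof["gene_id"].to_numpy()
    mu = lof["mu"].to_numpy(dtype=float)
    kappa = lof["gene_id"].map(config.kappa_of).to_numpy()
    s = lof["gene_id"].map(config.s_of).to_numpy()
    mu_rate = mu * config.rate_scale
    eq = kappa * mu_rate / s
    if np.any(eq > 0.1):
        raise ValueError(
            "expected allele frequency exceeds 0.1: outside the "
            "strong-selection regime of the Gamma approximation"
        )
    shape = 4.0 * config.ne * kappa * mu_rate
    scale = 1.0 / (4.0 * config.ne * s)
    q = rng.gamma(shape, scale)
    k = rng.poisson(config.n_haploid * q)
    n_clamped = int((k > config.n_haploid).sum())
    k = np.minimum(k, config.n_haploid)
    out = pd.DataFrame(
        {
            "gene_id": gene,
            "k": k,
            "mu": mu,
            "n": config.n_haploid,
        }
    ).reset_index(drop=True)
    out.attrs["n_clamped"] = n_clamped
    return out


def sample_sfs_counts(
    rng: np.random.Generator,
    mu: np.ndarray,
    beta_mu: np.ndarray,
    beta_s: Optional[np.ndarray] = None,
    shet: float | np.ndarray = 0.0,
    kappa: float | np.ndarray = 1.0,
    boundaries: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw allele counts from the multinomial SFS model.

    Per-site bin log-odds relative to the monomorphic bin are
    ``beta_mu_i * (kappa * mu) - beta_s_i * sqrt(shet)``: a CES-driven
    rate inflation ``kappa`` acts on the mutation-rate term, so a
    fitting model that only sees the annotated ``mu`` perceives the gene
    as less depleted than expected.  A bin is sampled per site and the
    returned allele count is the bin's lower boundary (the analysis is
    invariant to the within-bin position).
    """
    from . import sfs as _sfs

    if boundaries is None:
        boundaries = _sfs.SFS_BIN_BOUNDARIES
    boundaries = np.asarray(boundaries)
    mu = np.asarray(mu, dtype=float)
    beta_mu = np.asarray(beta_mu, dtype=float)
    nb = len(boundaries) - 2  # non-reference bins
    if beta_mu.size != nb:
        raise ValueError(f"beta_mu must have length {nb}")
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), mu.shape)
    eta = np.zeros((mu.size, nb + 1))
    eta[:, 1:] = (kappa * mu)[:, None] * beta_mu[None, :]
    if beta_s is not None:
        beta_s = np.asarray(beta_s, dtype=float)
        root = np.sqrt(np.broadcast_to(np.asarray(shet, dtype=float),
                                       mu.shape))
        eta[:, 1:] -= root[:, None] * beta_s[None, :]
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(mu.size)
    bins = (u[:, None] > p.cumsum(axis=1)).sum(axis=1)
    return boundaries[bins]


def gen_sperm_counts(
    config: SyntheticConfig, expectations: ExpectationTable
) -> pd.DataFrame:
    """Per-gene sperm-sequencing-like LoF counts.

    Counts are Poisson at ``sperm_scale * lambda_g(LoF) * kappa_gene``:
    CES inflates sperm counts, disease ascertainment does not, and
    embryonic lethality (which deflates trio counts) leaves sperm
    unaffected.
    """
    config.validate()
    rng = _rng(config.seed, "sperm")
    lof = expectations.gene_class_table("LoF")
    kappa = lof["gene_id"].map(config.kappa_of).to_numpy()
    mean = config.sperm_scale * lof["lam"].to_numpy() * kappa
    counts = rng.poisson(mean)
    return pd.DataFrame(
        {
            "gene_id": lof["gene_id"].to_numpy(),
            "m_sperm": counts,
            "lambda_sperm": config.sperm_scale * lof["lam"].to_numpy(),
        }
    )
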