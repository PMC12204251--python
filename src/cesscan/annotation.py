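"""Gene filtering, variant classification, and mutational expectations.

This module prepares the inputs of every downstream CES (clonal expansion
in spermatogonia) analysis:

* restrict to a maximal set of genes with non-overlapping coding sequence,
  so that every variant is unambiguously assigned to one gene;
* classify candidate SNVs into loss-of-function (LoF), synonymous and
  missense classes using upstream annotation columns;
* convert per-site baseline mutation rates ``mu`` into expected de novo
  counts ``lambda_v`` by normalising against the observed number of
  synonymous de novo mutations in the cohort:

      lambda_v = NS * mu_v / sum_{v in S} mu_v

  where ``S`` is the set of admissible synonymous sites and ``NS`` the
  observed synonymous count.  The normalisation absorbs cohort-specific
  factors (parental age, coverage, cohort size) so that ``lambda`` is on
  the scale of expected counts in *this* cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteRecord",
    "GeneModel",
    "ExpectationTable",
    "ADMISSIBLE_QUALITY_TIERS",
    "LOF_CONSEQUENCES",
    "classify_variant",
    "classify_sites",
    "select_nonoverlapping_genes",
    "compute_expectations",
]

#: Roulette-QUAL-style quality tiers at which a site is admissible.
ADMISSIBLE_QUALITY_TIERS = frozenset({"high", "TFBS"})

#: Consequence labels that, together with a high-confidence LoF flag,
#: define the loss-of-function class.
LOF_CONSEQUENCES = frozenset(
    {"stop_gained", "splice_donor_variant", "splice_acceptor_variant"}
)

VARIANT_CLASSES = ("LoF", "synonymous", "missense")

#: Strict lower bound on the missense pathogenicity score.
MISSENSE_SCORE_THRESHOLD = 0.1


@dataclass(frozen=True)
class SiteRecord:
    """One possible SNV with its baseline mutation rate and annotations."""

    gene_id: str
    position: int  # 1-based genomic coordinate
    ref: str
    alt: str
    mu: float  # unscaled baseline mutation rate, > 0
    quality_tier: str  # {"high", "TFBS", "other"}
    consequence: frozenset = frozenset()
    lof_high_confidence: bool = False
    missense_score: Optional[float] = None

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def admissible(self) -> bool:
        return self.quality_tier in ADMISSIBLE_QUALITY_TIERS


@dataclass
class GeneModel:
    """A gene as a set of half-open 0-based CDS intervals."""

    gene_id: str
    cds_intervals: list  # list of (start, end) half-open, 0-based
    loeuf: Optional[float] = None
    spermatogonia_expressed: Optional[bool] = None

    def __post_init__(self):
        ivs = sorted((int(s), int(e)) for s, e in self.cds_intervals)
        for s, e in ivs:
            if e <= s:
                raise ValueError(
                    f"gene {self.gene_id}: malformed interval [{s}, {e})"
                )
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(
                    f"gene {self.gene_id}: intervals [{s0},{e0}) and "
                    f"[{s1},{e1}) overlap within the gene"
                )
        self.cds_intervals = ivs

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


def classify_variant(site: SiteRecord) -> Optional[str]:
    """Assign a site to LoF / synonymous / missense, or ``None`` if rejected.

    Rules (checked in order, producing a partition):

    * inadmissible quality tier -> rejected;
    * high-confidence LoF flag and a stop-gained or essential-splice
      consequence -> ``"LoF"``;
    * consequence labels all synonymous with no splice involvement ->
      ``"synonymous"``;
    * missense consequence with pathogenicity score strictly above 0.1
      -> ``"missense"`` (missing score -> rejected);
    * anything else -> rejected.
    """
    if not site.admissible:
        return None
    cons = frozenset(site.consequence)
    if site.lof_high_confidence and cons & LOF_CONSEQUENCES:
        return "LoF"
    if cons and all("synonymous" in c for c in cons) and not any(
        "splice" in c for c in cons
    ):
        return "synonymous"
    if any("missense" in c for c in cons):
        if site.missense_score is None:
            return None
        if site.missense_score > MISSENSE_SCORE_THRESHOLD:
            return "missense"
    return None


def classify_sites(sites: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Vectorised classification of a site table.

    Parameters
    ----------
    sites
        DataFrame with columns ``qual``, ``consequence`` (comma-separated
        labels), ``lof_hc`` (boolean-like) and ``missense_score``
        (NaN when absent).

    Returns
    -------
    classes, diagnostics
        ``classes`` is a string Series aligned with ``sites`` holding
        "LoF"/"synonymous"/"missense" or NaN for rejected sites;
        ``diagnostics`` tallies rejection reasons.
    """
    qual = sites["qual"].astype(str)
    admissible = qual.isin(ADMISSIBLE_QUALITY_TIERS)

    cons = sites["consequence"].astype(str)
    lof_hc = sites["lof_hc"].astype(bool)
    # comma-separated labels; vectorised regex membership tests
    lof_pattern = r"(?:^|,)(?:" + "|".join(sorted(LOF_CONSEQUENCES)) \
        + r")(?:,|$)"
    has_lof_cons = cons.str.contains(lof_pattern, regex=True)
    is_lof = admissible & lof_hc & has_lof_cons

    # every comma-token mentions "synonymous", none mentions "splice"
    only_syn = cons.str.fullmatch(
        r"[^,]*synonymous[^,]*(?:,[^,]*synonymous[^,]*)*"
    ) & ~cons.str.contains("splice")
    is_syn = admissible & ~is_lof & only_syn

    has_missense = cons.str.contains("missense")
    score = pd.to_numeric(sites.get("missense_score"), errors="coerce")
    score_missing = score.isna()
    is_mis = (
        admissible
        & ~is_lof
        & ~is_syn
        & has_missense
        & ~score_missing
        & (score > MISSENSE_SCORE_THRESHOLD)
    )

    classes = pd.Series(np.nan, index=sites.index, dtype=object)
    classes[is_lof] = "LoF"
    classes[is_syn] = "synonymous"
    classes[is_mis] = "missense"

    diagnostics = {
        "n_sites": int(len(sites)),
        "n_inadmissible_quality": int((~admissible).sum()),
        "n_missense_missing_score": int(
            (admissible & has_missense & ~is_lof & ~is_syn & score_missing).sum()
        ),
        "n_rejected": int(classes.isna().sum()),
    }
    return classes, diagnostics


# ---------------------------------------------------------------------------
# Non-overlapping gene selection
# ---------------------------------------------------------------------------


def _genes_overlap(a: GeneModel, b: GeneModel) -> bool:
    """True if any CDS base is shared between the two genes."""
    ia, ib = 0, 0
    A, B = a.cds_intervals, b.cds_intervals
    while ia < len(A) and ib < len(B):
        s = max(A[ia][0], B[ib][0])
        e = min(A[ia][1], B[ib][1])
        if s < e:
            return True
        if A[ia][1] <= B[ib][1]:
            ia += 1
        else:
            ib += 1
    return False


def _mwis_component(
    genes: Sequence[GeneModel], adj: Mapping[int, set]
) -> tuple[int, tuple]:
    """Exact maximum-weight independent set on one connected component.

    Weight is CDS length.  Ties are broken toward the lexicographically
    smallest sorted tuple of gene ids, making the output reproducible.
    Memoised branch-and-bound over vertex bitmasks; component sizes in
    gene CDS overlap graphs are small in practice.
    """
    n = len(genes)
    weights = [g.cds_length for g in genes]
    ids = [g.gene_id for g in genes]
    nbr_masks = [0] * n
    for i in range(n):
        for j in adj[i]:
            nbr_masks[i] |= 1 << j

    memo: dict[int, tuple[int, tuple]] = {}

    def solve(mask: int) -> tuple[int, tuple]:
        if mask == 0:
            return 0, ()
        hit = memo.get(mask)
        if hit is not None:
            return hit
        v = (mask & -mask).bit_length() - 1  # lowest-index vertex
        # branch: exclude v
        w_ex, set_ex = solve(mask & ~(1 << v))
        # branch: include v, drop its neighbours
        w_in, set_in = solve(mask & ~(1 << v) & ~nbr_masks[v])
        w_in += weights[v]
        set_in = (v,) + set_in
        if w_in > w_ex:
            best = (w_in, set_in)
        elif w_ex > w_in:
            best = (w_ex, set_ex)
        else:  # tie on weight: lexicographically smallest gene-id set
            key_in = tuple(sorted(ids[k] for k in set_in))
            key_ex = tuple(sorted(ids[k] for k in set_ex))
            best = (w_in, set_in) if key_in <= key_ex else (w_ex, set_ex)
        memo[mask] = best
        return best

    return solve((1 << n) - 1)


def select_nonoverlapping_genes(
    genes: Iterable[GeneModel],
) -> list[GeneModel]:
    """Largest-total-CDS subset of pairwise non-overlapping genes.

    Solves the maximum-weight independent set of the CDS-overlap graph
    exactly, component by component (for a single overlapping pair this
    retains the longer gene).  The returned list preserves input order.
    """
    gene_list = list(genes)
    if not gene_list:
        return []
    ids_seen = set()
    for g in gene_list:
        if g.gene_id in ids_seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        ids_seen.add(g.gene_id)

    n = len(gene_list)
    # sweep-line over interval endpoints to find overlapping gene pairs
    events = []  # (start, end, gene_index)
    for gi, g in enumerate(gene_list):
        for s, e in g.cds_intervals:
            events.append((s, e, gi))
    events.sort()
    adj: dict[int, set] = {i: set() for i in range(n)}
    active: list[tuple[int, int]] = []  # (end, gene_index)
    for s, e, gi in events:
        active = [(ae, aj) for ae, aj in active if ae > s]
        for _, aj in active:
            if aj != gi:
                adj[gi].add(aj)
                adj[aj].add(gi)
        active.append((e, gi))

    # connected components
    comp = [-1] * n
    ncomp = 0
    for i in range(n):
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = ncomp
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp[v] < 0:
                    comp[v] = ncomp
                    stack.append(v)
        ncomp += 1

    keep: set[str] = set()
    for c in range(ncomp):
        members = [i for i in range(n) if comp[i] == c]
        if len(members) == 1:
            keep.add(gene_list[members[0]].gene_id)
            continue
        local = {gi: k for k, gi in enumerate(members)}
        local_adj = {
            local[gi]: {local[gj] for gj in adj[gi]} for gi in members
        }
        _, chosen = _mwis_component([gene_list[gi] for gi in members], local_adj)
        for k in chosen:
            keep.add(gene_list[members[k]].gene_id)

    return [g for g in gene_list if g.gene_id in keep]


# ---------------------------------------------------------------------------
# Mutational expectations
# ---------------------------------------------------------------------------


@dataclass
class ExpectationTable:
    """Synonymous-normalised expected de novo counts.

    Attributes
    ----------
    ns_count
        Observed number of synonymous de novo mutations (the NS scaler).
    sites
        Copy of the admissible classified input sites with columns
        ``variant_class`` and ``lam`` (per-site expectation lambda_v).
    lambda_gene
        DataFrame indexed by (gene_id, variant_class) with column ``lam``
        holding the per-gene, per-class expectation lambda_g.
    diagnostics
        Classification / filtering tallies.
    """

    ns_count: int
    sites: pd.DataFrame
    lambda_gene: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    def lam_gene(self, gene_id: str, variant_class: str) -> float:
        try:
            return float(self.lambda_gene.loc[(gene_id, variant_class), "lam"])
        except KeyError:
            return 0.0

    def gene_class_table(self, variant_class: str) -> pd.DataFrame:
        """Per-gene expectations for one class, columns (gene_id, lam)."""
        sub = self.lambda_gene.xs(variant_class, level="variant_class")
        return sub.reset_index()


def compute_expectations(
    sites: pd.DataFrame,
    ns_count: int,
    retained_genes: Optional[set] = None,
) -> ExpectationTable:
    """Compute lambda_v = NS * mu_v / sum_S mu_v for all admissible sites.

    Parameters
    ----------
    sites
        Site table with columns gene_id, pos, ref, alt, mu, qual,
        consequence, lof_hc, missense_score.
    ns_count
        Observed synonymous de novo count NS (>= 0).
    retained_genes
        Optional set of gene ids surviving non-overlap selection; sites
        in other genes are dropped with a logged count.
    """
    if ns_count < 0:
        raise ValueError("ns_count must be >= 0")
    df = sites.copy()
    n_dropped_genes = 0
    if retained_genes is not None:
        mask = df["gene_id"].isin(retained_genes)
        n_dropped_genes = int((~mask).sum())
        df = df[mask]

    if (pd.to_numeric(df["mu"]) <= 0).any():
        raise ValueError("all mu must be > 0")

    classes, diagnostics = classify_sites(df)
    df = df.assign(variant_class=classes)
    df = df[df["variant_class"].notna()].copy()
    diagnostics["n_sites_dropped_unretained_gene"] = n_dropped_genes

    syn = df[df["variant_class"] == "synonymous"]
    denom = float(syn["mu"].sum())
    if len(syn) == 0 or denom <= 0:
        raise ValueError(
            "no admissible synonymous sites: expectation undefined"
        )
    df["lam"] = ns_count * df["mu"].astype(float) / denom

    lambda_gene = (
        df.groupby(["gene_id", "variant_class"], sort=True)["lam"]
        .sum()
        .to_frame("lam")
    )
    return ExpectationTable(
        ns_count=int(ns_count),
        sites=df,
        lambda_gene=lambda_gene,
        diagnostics=diagnostics,
    )
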