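"""Variant classification, non-overlap gene selection, and expectations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cesscan.annotation import (
    GeneModel,
    SiteRecord,
    classify_sites,
    classify_variant,
    compute_expectations,
    select_nonoverlapping_genes,
)

from conftest import make_site


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        # high-confidence stop gain is LoF
        (dict(consequence={"stop_gained"}, lof_high_confidence=True), "LoF"),
        # essential splice with HC flag is LoF
        (dict(consequence={"splice_acceptor_variant"},
              lof_high_confidence=True), "LoF"),
        # stop gain without the high-confidence flag is rejected
        (dict(consequence={"stop_gained"}, lof_high_confidence=False), None),
        # pure synonymous
        (dict(consequence={"synonymous_variant"}), "synonymous"),
        # synonymous with splice involvement is rejected
        (dict(consequence={"synonymous_variant", "splice_region_variant"}),
         None),
        # missense above the score threshold
        (dict(consequence={"missense_variant"}, missense_score=0.11),
         "missense"),
        # score exactly 0.1 is rejected (strict inequality)
        (dict(consequence={"missense_variant"}, missense_score=0.1), None),
        # missense without a score is rejected
        (dict(consequence={"missense_variant"}, missense_score=None), None),
        # inadmissible quality tier
        (dict(consequence={"synonymous_variant"}, quality_tier="other"),
         None),
        # TFBS tier is admissible
        (dict(consequence={"synonymous_variant"}, quality_tier="TFBS"),
         "synonymous"),
    ],
)
def test_classify_variant_rules(kwargs, expected):
    defaults = dict(gene_id="G", position=1, ref="C", alt="T", mu=1.0,
                    quality_tier="high")
    defaults.update(kwargs)
    defaults["consequence"] = frozenset(defaults["consequence"])
    assert classify_variant(SiteRecord(**defaults)) == expected


def test_site_record_validates():
    with pytest.raises(ValueError):
        SiteRecord("G", 1, "C", "C", 1.0, "high")
    with pytest.raises(ValueError):
        SiteRecord("G", 1, "C", "T", 0.0, "high")


def test_classification_is_a_partition(site_table):
    classes, diag = classify_sites(site_table)
    # every site gets at most one class, and the tallies are consistent
    assert classes.isin(["LoF", "synonymous", "missense"]).sum() \
        + diag["n_rejected"] == len(site_table)


def test_classify_sites_diagnostics():
    rows = [
        make_site(consequence="missense_variant", missense_score=np.nan),
        make_site(qual="low"),
        make_site(),
    ]
    classes, diag = classify_sites(pd.DataFrame(rows))
    assert diag["n_missense_missing_score"] == 1
    assert diag["n_inadmissible_quality"] == 1
    assert diag["n_rejected"] == 2


# ---------------------------------------------------------------------------
# expectations
# ---------------------------------------------------------------------------


def test_single_synonymous_site_gets_full_ns():
    df = pd.DataFrame([make_site(mu=2.5)])
    table = compute_expectations(df, 7)
    assert table.sites["lam"].iloc[0] == pytest.approx(7.0)


def test_lambda_proportional_to_mu():
    df = pd.DataFrame([make_site(pos=1, mu=1.0), make_site(pos=2, mu=3.0)])
    table = compute_expectations(df, 8)
    assert sorted(table.sites["lam"]) == pytest.approx([2.0, 6.0])


def test_conservation_and_gene_sums(rng):
    n = 1000
    rows = []
    for i in range(n):
        cls = ("synonymous_variant", "stop_gained",
               "missense_variant")[i % 3]
        rows.append(
            make_site(
                gene_id=f"G{i % 7}",
                pos=i,
                mu=float(rng.lognormal(0, 1)),
                consequence=cls,
                lof_hc=cls == "stop_gained",
                missense_score=0.5,
            )
        )
    df = pd.DataFrame(rows)
    table = compute_expectations(df, 123)
    syn = table.sites[table.sites["variant_class"] == "synonymous"]
    assert syn["lam"].sum() == pytest.approx(123, rel=1e-9)
    # lambda_g is the sum of per-site lambdas of that gene and class
    for (gid, cls), sub in table.sites.groupby(["gene_id", "variant_class"]):
        assert table.lam_gene(gid, cls) == pytest.approx(sub["lam"].sum())


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=25, deadline=None)
def test_scale_invariance_of_lambda(scale):
    """Multiplying all mu by a constant leaves every lambda unchanged."""
    df = pd.DataFrame(
        [make_site(pos=1, mu=1.0), make_site(pos=2, mu=3.0),
         make_site(pos=3, mu=2.0, consequence="stop_gained", lof_hc=True)]
    )
    base = compute_expectations(df, 10).sites["lam"].to_numpy()
    scaled_df = df.assign(mu=df["mu"] * scale)
    scaled = compute_expectations(scaled_df, 10).sites["lam"].to_numpy()
    np.testing.assert_allclose(base, scaled, rtol=1e-9)


def test_no_synonymous_sites_is_an_error():
    df = pd.DataFrame([make_site(consequence="stop_gained", lof_hc=True)])
    with pytest.raises(ValueError, match="synonymous"):
        compute_expectations(df, 5)


def test_sites_in_unretained_genes_are_dropped(site_table):
    table = compute_expectations(site_table, 4, retained_genes={"G1"})
    assert set(table.sites["gene_id"]) == {"G1"}
    assert table.diagnostics["n_sites_dropped_unretained_gene"] == 3


# ---------------------------------------------------------------------------
# non-overlapping gene selection
# ---------------------------------------------------------------------------


def _intervals_overlap(a, b):
    return any(
        max(s1, s2) < min(e1, e2) for s1, e1 in a for s2, e2 in b
    )


def brute_force_select(genes):
    """Exhaustive maximum-weight independent set oracle with the
    lexicographic tie-break."""
    best_weight, best_ids = -1, None
    for r in range(len(genes) + 1):
        for subset in itertools.combinations(genes, r):
            ok = all(
                not _intervals_overlap(g1.cds_intervals, g2.cds_intervals)
                for g1, g2 in itertools.combinations(subset, 2)
            )
            if not ok:
                continue
            weight = sum(g.cds_length for g in subset)
            ids = tuple(sorted(g.gene_id for g in subset))
            if weight > best_weight or (
                weight == best_weight and ids < best_ids
            ):
                best_weight, best_ids = weight, ids
    return set(best_ids)


def test_disjoint_genes_all_retained():
    genes = [GeneModel("A", [(0, 100)]), GeneModel("B", [(200, 300)])]
    assert {g.gene_id for g in select_nonoverlapping_genes(genes)} == \
        {"A", "B"}


def test_longer_gene_wins_pairwise_overlap():
    genes = [GeneModel("A", [(0, 300)]), GeneModel("B", [(250, 350)])]
    assert [g.gene_id for g in select_nonoverlapping_genes(genes)] == ["A"]


def test_tie_broken_lexicographically():
    genes = [GeneModel("B", [(0, 100)]), GeneModel("A", [(50, 150)])]
    assert [g.gene_id for g in select_nonoverlapping_genes(genes)] == ["A"]


def test_overlap_on_cds_footprint_not_span():
    # spans overlap but the CDS intervals interleave without sharing bases
    genes = [
        GeneModel("A", [(0, 50), (100, 150)]),
        GeneModel("B", [(60, 90)]),
    ]
    assert {g.gene_id for g in select_nonoverlapping_genes(genes)} == \
        {"A", "B"}


def test_empty_input():
    assert select_nonoverlapping_genes([]) == []


def test_malformed_interval_rejected():
    with pytest.raises(ValueError, match="malformed"):
        GeneModel("A", [(10, 10)])
    with pytest.raises(ValueError, match="overlap within"):
        GeneModel("A", [(0, 20), (10, 30)])


def _random_instance(rng, n_genes):
    genes = []
    cursor = 0
    for i in range(n_genes):
        # chained layout: each gene may overlap its neighbourhood
        start = cursor + int(rng.integers(-30, 20))
        length = int(rng.integers(10, 120))
        start = max(start, 0)
        genes.append(GeneModel(f"g{i:02d}", [(start, start + length)]))
        cursor = start + int(rng.integers(5, length + 5))
    return genes


def test_selection_matches_brute_force_on_random_chains(rng):
    for _ in range(30):
        genes = _random_instance(rng, 12)
        got = {g.gene_id for g in select_nonoverlapping_genes(genes)}
        assert got == brute_force_select(genes)


def test_duplicate_gene_ids_rejected():
    genes = [GeneModel("A", [(0, 10)]), GeneModel("A", [(20, 30)])]
    with pytest.raises(ValueError, match="duplicate"):
        select_nonoverlapping_genes(genes)
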