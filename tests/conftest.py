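import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_site(
    gene_id="G1",
    pos=100,
    ref="C",
    alt="T",
    mu=1.0,
    qual="high",
    consequence="synonymous_variant",
    lof_hc=False,
    missense_score=np.nan,
):
    return {
        "gene_id": gene_id,
        "chrom": "chr1",
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "mu": mu,
        "qual": qual,
        "consequence": consequence,
        "lof_hc": lof_hc,
        "missense_score": missense_score,
    }


@pytest.fixture
def site_table():
    """Small classified site table: 2 genes, all three classes."""
    rows = [
        make_site("G1", 100, mu=1.0),
        make_site("G1", 101, mu=3.0),
        make_site("G1", 102, mu=2.0, consequence="stop_gained", lof_hc=True),
        make_site("G1", 103, mu=0.5, consequence="missense_variant",
                  missense_score=0.8),
        make_site("G2", 200, mu=4.0),
        make_site("G2", 201, mu=1.5, consequence="splice_donor_variant",
                  lof_hc=True),
        make_site("G2", 202, mu=0.7, consequence="missense_variant",
                  missense_score=0.3),
    ]
    return pd.DataFrame(rows)
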