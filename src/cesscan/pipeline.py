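"""End-to-end orchestration of the CES discovery stages.

``run_pipeline`` wires the stages together on in-memory tables:
expectation -> dispersion -> homogeneity -> GoF / LoF-1 / LoF-2 ->
population-genetic (Nei) decomposition -> SFS shet estimation ->
trio-vs-sperm comparison.  Each stage is guarded: a failure marks the
stage and skips its dependents, leaving the rest of the report intact.
``run_synthetic_study`` generates all inputs from a
:class:`~cesscan.simulate.SyntheticConfig` first, which makes the whole
pipeline runnable and testable without any external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    ExpectationTable,
    GeneModel,
    compute_expectations,
    select_nonoverlapping_genes,
)
from .discovery import (
    AscertainmentModel,
    compare_cohorts,
    gof_variant_test,
    lof1_gene_test,
    lof2_select,
)
from .dispersion import fit_gamma, gene_level_chi2
from .homogeneity import CohortCountMatrix, compare_homogeneity
from .nei import ces_residuals, decompose_all, filter_nei_genes
from .sfs import estimate_gene_shet, fit_neutral_sfs, fit_selection_sfs
from .simulate import (
    SyntheticConfig,
    gen_denovo_cohort,
    gen_population_afs,
    gen_sites,
    gen_sperm_counts,
    sample_sfs_counts,
)

__all__ = ["RunConfig", "PipelineInputs", "run_pipeline",
           "run_synthetic_study", "DEFAULT_BETA_MU", "DEFAULT_BETA_S"]

# generator defaults for the multinomial SFS stage: recurrence pushes
# mass toward higher allele-count bins (beta_mu rising with bin index)
# and selection depletes higher-frequency bins more strongly (beta_s
# rising too) — the same orientation real SFS data show, and the one
# that makes unmodelled rate inflation register as weaker selection
DEFAULT_BETA_MU = 0.02 * np.arange(1, 15)
DEFAULT_BETA_S = 4.0 + 1.0 * np.arange(1, 15)


@dataclass
class RunConfig:
    """Thresholds and switches of a pipeline run (defaults echoed into
    every report)."""

    prevalence_lower_bound: float = 0.01
    gamma: float = 0.004
    fdr_gene: float = 0.1
    fdr_variant: float = 0.2
    loeuf_threshold: float = 0.5
    nei_min_sites: int = 10
    nei_min_mu: float = 1.0
    gof_null: str = "lambda"  # "lambda" (cohort-scaled) or "mu" (raw rate)
    n_tests_gof: Optional[int] = None
    n_tests_gene: Optional[int] = None
    seed: int = 0


@dataclass
class PipelineInputs:
    """In-memory tables consumed by the stages (any optional table may
    be None; dependent stages are then skipped)."""

    sites: pd.DataFrame
    denovo: pd.DataFrame
    genes: Optional[list] = None  # list[GeneModel]
    loeuf: Optional[pd.DataFrame] = None  # gene_id, loeuf
    allele_counts: Optional[pd.DataFrame] = None  # gene_id, k, mu, n
    sfs_synonymous: Optional[pd.DataFrame] = None  # k, mu
    sfs_lof: Optional[pd.DataFrame] = None  # gene_id, k, mu, shet_prior
    sperm: Optional[pd.DataFrame] = None  # gene_id, m_sperm, lambda_sperm


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else repr(f)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def _match_denovo_to_sites(sites: pd.DataFrame,
                           denovo: pd.DataFrame) -> pd.DataFrame:
    """Attach site annotations to de novo events by (chrom, pos, ref,
    alt); unmatched events are dropped (tallied in ``.attrs``)."""
    key = ["chrom", "pos", "ref", "alt"]
    merged = denovo.merge(
        sites[key + ["gene_id", "mu", "variant_class"]]
        if "variant_class" in sites.columns
        else sites[key + ["gene_id", "mu"]],
        on=key,
        how="left",
        suffixes=("", "_site"),
    )
    n_unmatched = int(merged["gene_id"].isna().sum())
    out = merged[merged["gene_id"].notna()].copy()
    out.attrs["n_unmatched"] = n_unmatched
    return out


def run_pipeline(inputs: PipelineInputs, config: RunConfig) -> dict:
    """Execute all stages; returns a JSON-serialisable run report."""
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    stages = report["stages"]
    ascert = AscertainmentModel(config.prevalence_lower_bound)

    def fail(stage: str, exc: Exception):
        stages[stage] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}

    def skip(stage: str, reason: str):
        stages[stage] = {"status": "skipped", "reason": reason}

    # ---- gene selection -------------------------------------------------
    retained_ids = None
    if inputs.genes is not None:
        try:
            retained = select_nonoverlapping_genes(inputs.genes)
            retained_ids = {g.gene_id for g in retained}
            stages["gene_selection"] = {
                "status": "ok",
                "n_input": len(inputs.genes),
                "n_retained": len(retained),
                "retained": sorted(retained_ids),
            }
        except Exception as exc:  # noqa: BLE001
            fail("gene_selection", exc)

    # ---- expectations ---------------------------------------------------
    expectations = None
    matched = None
    try:
        sites = inputs.sites
        # classify first so NS counts only admissible synonymous events,
        # then rescale the per-site expectations in place
        probe = compute_expectations(sites, 0, retained_ids)
        matched = _match_denovo_to_sites(probe.sites, inputs.denovo)
        ns_count = int((matched["variant_class"] == "synonymous").sum())
        syn_mu_sum = probe.sites.loc[
            probe.sites["variant_class"] == "synonymous", "mu"
        ].sum()
        esites_scaled = probe.sites.assign(
            lam=ns_count * probe.sites["mu"].astype(float) / syn_mu_sum
        )
        expectations = ExpectationTable(
            ns_count=ns_count,
            sites=esites_scaled,
            lambda_gene=esites_scaled.groupby(
                ["gene_id", "variant_class"], sort=True
            )["lam"].sum().to_frame("lam"),
            diagnostics=probe.diagnostics,
        )
        stages["expectation"] = {
            "status": "ok",
            "ns_count": ns_count,
            "n_admissible_sites": len(expectations.sites),
            "diagnostics": expectations.diagnostics,
        }
    except Exception as exc:  # noqa: BLE001
        fail("expectation", exc)

    if expectations is None:
        for st in ("dispersion", "homogeneity", "gof", "lof1", "lof2",
                   "compare"):
            skip(st, "expectation stage failed")
    else:
        esites = expectations.sites
        key = ["chrom", "pos", "ref", "alt"]
        obs_per_site = (
            matched.groupby(key).size().rename("observed").reset_index()
        )
        esites = esites.merge(obs_per_site, on=key, how="left")
        esites["observed"] = esites["observed"].fillna(0).astype(int)

        # ---- dispersion -------------------------------------------------
        try:
            syn = esites[esites["variant_class"] == "synonymous"]
            disp = fit_gamma(syn["observed"].to_numpy(),
                             syn["lam"].to_numpy())
            gene_syn = syn.groupby("gene_id").agg(
                ng=("observed", "sum"), lam=("lam", "sum")
            )
            chi2 = gene_level_chi2(gene_syn["ng"].to_numpy(),
                                   gene_syn["lam"].to_numpy())
            stages["dispersion"] = {
                "status": "ok",
                "fit": disp.to_dict(),
                "gene_chi2": chi2.to_dict(),
            }
        except Exception as exc:  # noqa: BLE001
            fail("dispersion", exc)

        # ---- homogeneity ------------------------------------------------
        try:
            lof_events = matched[matched["variant_class"] == "LoF"]
            syn_events = matched[matched["variant_class"] == "synonymous"]
            cohorts = sorted(matched["subcohort"].dropna().unique())
            if len(cohorts) < 2:
                raise ValueError("need >= 2 subcohorts")
            counts = (
                lof_events.groupby(["gene_id", "subcohort"])
                .size()
                .unstack(fill_value=0)
                .reindex(columns=cohorts, fill_value=0)
            )
            weights = (
                syn_events.groupby("subcohort").size()
                .reindex(cohorts, fill_value=0)
                .to_numpy(dtype=float)
            )
            matrix = CohortCountMatrix(
                counts=counts.to_numpy(), weights=weights,
                subcohorts=cohorts,
            )
            hom = compare_homogeneity(matrix)
            stages["homogeneity"] = {"status": "ok", **_jsonable(hom.to_dict())}
        except Exception as exc:  # noqa: BLE001
            fail("homogeneity", exc)

        # ---- GoF (per-missense-variant NegBin test) ---------------------
        try:
            mis = esites[esites["variant_class"] == "missense"]
            expected = (
                mis["lam"] if config.gof_null == "lambda" else mis["mu"]
            ).to_numpy()
            n_tests = config.n_tests_gof or len(mis)
            gof = gof_variant_test(
                mis["observed"].to_numpy(), expected, ascert,
                config.gamma, n_tests,
                units=(mis["gene_id"] + ":" + mis["pos"].astype(str)
                       + mis["ref"] + ">" + mis["alt"]).to_numpy(),
            )
            hits_b = gof[gof["bonferroni_significant"]]
            hits_q = gof[gof["q_value"] < config.fdr_variant]
            stages["gof"] = {
                "status": "ok",
                "n_tested": len(gof),
                "n_tests_correction": n_tests,
                "total_null_mean": float(gof["expected"].sum()),
                "bonferroni_hits": hits_b["unit"].tolist(),
                "fdr_hits": hits_q["unit"].tolist(),
                "table": _jsonable(
                    gof[gof["p_value"] < 1e-3].sort_values("p_value")
                ),
            }
        except Exception as exc:  # noqa: BLE001
            fail("gof", exc)

        # ---- LoF-1 / LoF-2 ----------------------------------------------
        gene_lof = None
        try:
            lof_sites = esites[esites["variant_class"] == "LoF"]
            gene_lof = lof_sites.groupby("gene_id").agg(
                observed=("observed", "sum"), lam=("lam", "sum")
            ).reset_index()
            n_tests = config.n_tests_gene or int((gene_lof["lam"] > 0).sum())
            lof1 = lof1_gene_test(
                gene_lof["observed"].to_numpy(), gene_lof["lam"].to_numpy(),
                ascert, n_tests, units=gene_lof["gene_id"].to_numpy(),
            )
            stages["lof1"] = {
                "status": "ok",
                "n_tests_correction": n_tests,
                "bonferroni_hits": lof1[lof1["bonferroni_significant"]]
                ["unit"].tolist(),
                "fdr_hits": lof1[lof1["q_value"] < config.fdr_gene]
                ["unit"].tolist(),
                "table": _jsonable(
                    lof1[lof1["p_value"] < 1e-3].sort_values("p_value")
                ),
            }
        except Exception as exc:  # noqa: BLE001
            fail("lof1", exc)

        try:
            if gene_lof is None:
                raise ValueError("gene-level LoF counts unavailable")
            if inputs.loeuf is None:
                skip("lof2", "no LOEUF table provided")
            else:
                merged = gene_lof.merge(inputs.loeuf, on="gene_id",
                                        how="left")
                lof2 = lof2_select(
                    merged["observed"].to_numpy(), merged["lam"].to_numpy(),
                    merged["loeuf"].to_numpy(),
                    units=merged["gene_id"].to_numpy(),
                    fdr=config.fdr_gene,
                    loeuf_threshold=config.loeuf_threshold,
                )
                stages["lof2"] = {
                    "status": "ok",
                    "selected": lof2[lof2["selected"]]["unit"].tolist(),
                    "n_significant_fdr": int((lof2["q_value"]
                                              < config.fdr_gene).sum()),
                    "n_missing_loeuf": lof2.attrs["n_missing_loeuf"],
                }
        except Exception as exc:  # noqa: BLE001
            fail("lof2", exc)

        # ---- trio vs sperm comparison -----------------------------------
        try:
            if inputs.sperm is None:
                skip("compare", "no sperm count table provided")
            elif gene_lof is None:
                raise ValueError("gene-level LoF counts unavailable")
            else:
                cand = set(
                    stages.get("lof1", {}).get("bonferroni_hits", [])
                ) | set(stages.get("lof2", {}).get("selected", []))
                merged = gene_lof.merge(inputs.sperm, on="gene_id")
                merged = merged[merged["gene_id"].isin(cand)] if cand else \
                    merged.iloc[0:0]
                testable = merged[(merged["observed"] >= 1)
                                  & (merged["m_sperm"] >= 1)]
                results = [
                    compare_cohorts(
                        int(r["observed"]), int(r["m_sperm"]),
                        float(r["lam"]), float(r["lambda_sperm"]),
                        n_genes_tested=max(len(testable), 1),
                        gene_id=r["gene_id"],
                    )
                    for _, r in testable.iterrows()
                ]
                stages["compare"] = {
                    "status": "ok",
                    "n_tested": len(results),
                    "results": _jsonable(results),
                }
                # pooled sperm enrichment of the candidate set, with a
                # Poisson-conjugate 95% interval
                if len(merged) and merged["lambda_sperm"].sum() > 0:
                    from .discovery import enrichment_with_ci

                    est = enrichment_with_ci(
                        int(merged["m_sperm"].sum()),
                        float(merged["lambda_sperm"].sum()),
                    )
                    stages["compare"]["candidate_sperm_enrichment"] = {
                        "ratio": est.ratio,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                    }
        except Exception as exc:  # noqa: BLE001
            fail("compare", exc)

    # ---- Nei popgen decomposition ---------------------------------------
    try:
        if inputs.allele_counts is None:
            skip("nei", "no allele-count table provided")
        else:
            ac = inputs.allele_counts
            n = int(ac["n"].iloc[0])
            filtered = filter_nei_genes(ac, config.nei_min_mu,
                                        config.nei_min_sites)
            if filtered.empty:
                raise ValueError("no genes pass the Nei site filters")
            estimates = decompose_all(filtered, n)
            resid = ces_residuals(estimates)
            stages["nei"] = {
                "status": "ok",
                "n_genes": len(estimates),
                "estimates": _jsonable(estimates),
                "residuals": _jsonable(resid),
                "regression": {
                    "slope": resid.attrs["slope"],
                    "intercept": resid.attrs["intercept"],
                },
            }
    except Exception as exc:  # noqa: BLE001
        fail("nei", exc)

    # ---- SFS shet estimation ---------------------------------------------
    try:
        if inputs.sfs_synonymous is None or inputs.sfs_lof is None:
            skip("shet", "no SFS tables provided")
        else:
            neutral = fit_neutral_sfs(
                inputs.sfs_synonymous["k"].to_numpy(),
                inputs.sfs_synonymous["mu"].to_numpy(),
            )
            lof = inputs.sfs_lof
            selection = fit_selection_sfs(
                lof["k"].to_numpy(), lof["mu"].to_numpy(),
                lof["shet_prior"].to_numpy(), neutral,
            )
            per_gene = []
            for gid, sub in lof.groupby("gene_id", sort=True):
                est = estimate_gene_shet(
                    sub["k"].to_numpy(), sub["mu"].to_numpy(), selection,
                    gene_id=str(gid),
                )
                per_gene.append(
                    {"gene_id": est.gene_id, "shet": est.shet,
                     "shet_prior": float(sub["shet_prior"].iloc[0]),
                     "at_bound": est.at_bound}
                )
            stages["shet"] = {
                "status": "ok",
                "beta_mu": _jsonable(neutral.beta_mu),
                "beta_s": _jsonable(selection.beta_s),
                "per_gene": per_gene,
            }
    except Exception as exc:  # noqa: BLE001
        fail("shet", exc)

    report["ok"] = all(
        st.get("status") != "failed" for st in stages.values()
    )
    return report


def synthetic_inputs(config: SyntheticConfig) -> PipelineInputs:
    """Generate every pipeline input table from one study seed."""
    sites, genes_df = gen_sites(config)
    genes = [
        GeneModel(gene_id=str(gid),
                  cds_intervals=list(zip(sub["start"], sub["end"])))
        for gid, sub in genes_df.groupby("gene_id", sort=True)
    ]
    expectations = compute_expectations(sites, config.ns_count)
    denovo = gen_denovo_cohort(config, expectations)
    loeuf = pd.DataFrame(
        {
            "gene_id": config.gene_ids(),
            "loeuf": [config.gene_loeuf.get(g, 1.0)
                      for g in config.gene_ids()],
        }
    )
    allele_counts = gen_population_afs(config, sites)
    sperm = gen_sperm_counts(config, expectations)

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(17,))
    )
    syn_sites = expectations.sites.query("variant_class == 'synonymous'")
    k_syn = sample_sfs_counts(rng, syn_sites["mu"].to_numpy(),
                              DEFAULT_BETA_MU)
    sfs_syn = pd.DataFrame({"k": k_syn, "mu": syn_sites["mu"].to_numpy()})
    lof_sites = expectations.sites.query("variant_class == 'LoF'")
    shet_prior = lof_sites["gene_id"].map(config.shet_of).to_numpy()
    kappa = lof_sites["gene_id"].map(config.kappa_of).to_numpy()
    k_lof = sample_sfs_counts(
        rng, lof_sites["mu"].to_numpy(), DEFAULT_BETA_MU, DEFAULT_BETA_S,
        shet=shet_prior, kappa=kappa,
    )
    sfs_lof = pd.DataFrame(
        {
            "gene_id": lof_sites["gene_id"].to_numpy(),
            "k": k_lof,
            "mu": lof_sites["mu"].to_numpy(),
            "shet_prior": shet_prior,
        }
    )
    return PipelineInputs(
        sites=sites, denovo=denovo, genes=genes, loeuf=loeuf,
        allele_counts=allele_counts, sfs_synonymous=sfs_syn,
        sfs_lof=sfs_lof, sperm=sperm,
    )


def run_synthetic_study(config: SyntheticConfig,
                        run_config: Optional[RunConfig] = None) -> dict:
    """Generate a full synthetic study and run the pipeline on it."""
    if run_config is None:
        run_config = RunConfig(
            prevalence_lower_bound=config.prevalence_lower_bound,
            gamma=config.gamma,
            seed=config.seed,
        )
    inputs = synthetic_inputs(config)
    report = run_pipeline(inputs, run_config)
    report["synthetic_config"] = _jsonable(asdict(config))
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
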