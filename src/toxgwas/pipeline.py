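"""End-to-end pipeline: simulate -> phenotypes -> quantgen -> GWAS ->
annotation -> networks -> enrichment, with every stage's artifact written
to the output directory and a JSON summary of the headline statistics.

The pipeline is fully deterministic given the configuration seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, association, enrichment, network, phenotypes, quantgen, simulate
from .config import PipelineConfig
from .io import write_edges, write_table, write_vcf

logger = logging.getLogger(__name__)


def _pooled_phenotypes(survival: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Per line x sex pooled phenotype table with a ``p`` column."""
    if mode == "binomial":
        return phenotypes.pool_survival(survival)
    pooled = (
        survival.groupby(["line_id", "sex"])["value"].mean().rename("p").reset_index()
    )
    pooled["N"] = survival.groupby(["line_id", "sex"])["value"].size().to_numpy()
    pooled["se"] = (
        survival.groupby(["line_id", "sex"])["value"].sem().to_numpy()
    )
    return pooled


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages on a synthetic cohort; returns the summary report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    chash = config.config_hash()
    meta = {"seed": config.seed, "config_hash": chash}

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        write_table(df, outdir / name, seed=config.seed, config_hash=chash, index=index)

    # --- stage 1: synthetic cohort -------------------------------------
    cohort = simulate.simulate_cohort(sim)
    save(cohort.survival, "survival.tsv")
    save(cohort.covariates, "covariates.tsv", index=True)
    if cohort.genotypes is not None:
        write_vcf(cohort.genotypes, outdir / "genotypes.vcf")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, default=str)

    # --- stage 2: phenotypes -------------------------------------------
    pooled = _pooled_phenotypes(cohort.survival, sim.phenotype_mode)
    save(pooled, "pooled_phenotypes.tsv")
    phen = association.derive_phenotypes(pooled)
    save(phen, "derived_phenotypes.tsv", index=True)

    # --- stage 3: quantitative genetics --------------------------------
    qg = quantgen.quantgen_summary(cohort.survival, method="reml", jackknife=False)
    vc = qg.components
    qg_table = pd.DataFrame(
        {
            "statistic": [
                "sigma2_line", "sigma2_line_sex", "sigma2_resid",
                "sigma2_line_F", "sigma2_resid_F", "sigma2_line_M",
                "sigma2_resid_M", "H2_pooled", "H2_female", "H2_male",
                "r_GS", "sex_effect_p",
            ],
            "value": [
                vc.sigma2_line, vc.sigma2_line_sex, vc.sigma2_resid,
                vc.sigma2_line_F, vc.sigma2_resid_F, vc.sigma2_line_M,
                vc.sigma2_resid_M, qg.H2_pooled, qg.H2_female, qg.H2_male,
                qg.r_GS, qg.sex_effect_p,
            ],
        }
    )
    save(qg_table, "quantgen.tsv")

    report: dict = {
        **meta,
        "H2_pooled": qg.H2_pooled,
        "H2_female": qg.H2_female,
        "H2_male": qg.H2_male,
        "r_GS": qg.r_GS,
        "sex_effect_p": qg.sex_effect_p,
    }

    # --- stage 4-5: covariates + association ---------------------------
    gwas = None
    if cohort.genotypes is not None:
        filtered = association.filter_variants(
            cohort.genotypes, config.max_missing, config.min_maf
        )
        cov = cohort.covariates.copy()
        cov["wolbachia"] = association.classify_infection(
            cov["wolbachia_reads"], threshold=config.infection_reads
        )
        cov_num = cov.drop(columns=["wolbachia_reads"])
        gwas = association.run_gwas(
            phen,
            filtered,
            covariates=cov_num,
            screen_alpha=config.screen_p,
            suggestive_p=config.suggestive_p,
            bonferroni_alpha=config.bonferroni_alpha,
        )
        save(gwas, "association.tsv")
        classes = association.classify_sex_effects(gwas, config.suggestive_p)
        save(classes, "effect_classes.tsv")
        report["n_variants_tested"] = int(filtered.n_variants)
        report["bonferroni_threshold"] = association.bonferroni_threshold(
            config.bonferroni_alpha, filtered.n_variants
        )
        report["hits_per_analysis"] = {
            a: int(((gwas["analysis"] == a) & gwas["suggestive"]).sum())
            for a in association.ANALYSES
        }
        report["effect_class_counts"] = (
            classes["effect_class"].value_counts().to_dict()
        )

        # --- stage 6: candidate genes ----------------------------------
        n_genes = 3000
        genes = simulate.simulate_gene_models(n_genes, seed=sim.seed)
        hits = gwas[gwas["suggestive"]]
        var_meta = filtered.variants.set_index("variant_id")
        sig = hits.merge(
            var_meta[["chrom", "pos"]], left_on="variant_id", right_index=True
        )[["variant_id", "chrom", "pos", "analysis"]].drop_duplicates()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assignments, intergenic = annotation.assign_candidate_genes(
                sig, genes, window=config.window
            )
        save(assignments, "candidate_assignments.tsv")
        save(annotation.candidate_genes(assignments), "candidate_genes.tsv")
        report["n_candidate_genes"] = int(assignments["gene_id"].nunique())
        report["n_intergenic_hits"] = int(len(intergenic))

        # --- stage 7: interaction networks -----------------------------
        background = simulate.simulate_background_network(
            n_genes, attachment=2, seed=sim.seed
        )
        report["networks"] = {}
        for analysis in ("female", "difference"):
            cands = set(
                assignments.loc[assignments["analysis"] == analysis, "gene_id"]
            )
            if len(cands) < 2:
                report["networks"][analysis] = None
                continue
            net = network.recruit_network(cands, background, config.min_links)
            write_edges(net, outdir / f"network_{analysis}.tsv")
            test = network.permutation_test(
                net, background, n_perm=config.n_perm, seed=config.seed
            )
            report["networks"][analysis] = {
                "n_genes": net.number_of_nodes(),
                "n_candidates": sum(
                    1 for _, r in net.nodes(data="role") if r == "candidate"
                ),
                "connectivity": test.observed_connectivity,
                "p_value": test.p_value,
                "p_display": test.p_display,
            }

            # --- stage 8: enrichment on the network gene set -----------
            universe = set(genes["gene_id"])
            rng = np.random.default_rng(config.seed)
            term_sets = {
                f"TERM:{i:03d}": set(
                    rng.choice(sorted(universe), size=40, replace=False)
                )
                for i in range(25)
            }
            net_genes = set(net.nodes) & universe
            if net_genes:
                enr = enrichment.fisher_enrichment(net_genes, term_sets, universe)
                save(enr, f"enrichment_{analysis}.tsv")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
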