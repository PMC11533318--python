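"""Synthetic inbred-line cohort generator.

Generates every input the analysis pipeline consumes — homozygous biallelic
genotypes, replicate-level survival counts under the mixed model
``Y = mu + L + S + LxS + eps``, line covariates (endosymbiont infection with
raw indicator read counts, inversion karyotypes) and a scale-free background
interaction network — with the generating truth recorded so downstream
estimators can be tested against known parameter values.

All randomness is driven by ``numpy.random.default_rng`` seeded from
``SimulationConfig.seed``; each generator draws from an independent stream
derived from (seed, stream-id) so components are individually reproducible.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .containers import GenotypeMatrix, SyntheticCohort

logger = logging.getLogger(__name__)

_CHROMS = ("2L", "2R", "3L", "3R", "X")
# SNP / deletion / insertion mix of a typical resequenced fly panel
_VTYPE_PROBS = {"SNP": 0.862, "deletion": 0.092, "insertion": 0.046}
_BASES = np.array(list("ACGT"))

# fixed stream ids so each component is reproducible in isolation
_STREAM_GENO, _STREAM_SURV, _STREAM_COV, _STREAM_NET = 1, 2, 3, 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def line_ids(n_lines: int) -> list[str]:
    return [f"line_{i + 1:03d}" for i in range(n_lines)]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw homozygous biallelic genotypes for a panel of inbred lines.

    Per variant a population minor-allele frequency is drawn uniformly on
    ``[maf_min, maf_max]`` and each line is homozygous minor (code 2) with
    that probability.  Variants whose realized MAF falls below ``maf_min``
    (including monomorphic draws) are redrawn so the emitted panel respects
    the configured spectrum floor before missingness; missing calls are then
    masked at ``missing_rate``.
    """
    if config.n_lines < 2 or config.n_variants < 1:
        raise ConfigError("need n_lines >= 2 and n_variants >= 1")
    rng = _rng(config.seed, _STREAM_GENO)
    n, m = config.n_lines, config.n_variants

    pop_maf = rng.uniform(config.maf_min, config.maf_max, size=m)
    carrier = rng.random((n, m)) < pop_maf
    # floor on the *realized* MAF: redraw offending columns
    min_count = int(np.ceil(config.maf_min * n))
    min_count = max(min_count, 1)
    for _ in range(1000):
        counts = carrier.sum(axis=0)
        bad = (counts < min_count) | (counts > n - min_count)
        if not bad.any():
            break
        idx = np.flatnonzero(bad)
        carrier[:, idx] = rng.random((n, idx.size)) < pop_maf[idx]
    else:  # pragma: no cover - pathological configs only
        raise ConfigError("could not realize requested MAF floor")

    calls = carrier.astype(float) * 2.0
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        calls[mask] = np.nan

    vtypes = rng.choice(
        list(_VTYPE_PROBS), size=m, p=list(_VTYPE_PROBS.values())
    )
    chroms = np.sort(rng.choice(_CHROMS, size=m))
    pos = np.empty(m, dtype=int)
    for c in _CHROMS:
        sel = chroms == c
        k = int(sel.sum())
        draw = rng.integers(1, 25_000_000, size=k)
        while np.unique(draw).size < k:  # duplicate positions: redraw
            draw = np.unique(np.concatenate([draw, rng.integers(1, 25_000_000, size=k)]))[:k]
        pos[sel] = np.sort(draw)
    ref = rng.choice(_BASES, size=m)
    alt = np.array(
        [rng.choice(_BASES[_BASES != r]) for r in ref], dtype=object
    )
    variants = pd.DataFrame(
        {
            "variant_id": [
                f"{c}_{p}_{r}_{a}" for c, p, r, a in zip(chroms, pos, ref, alt)
            ],
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "vtype": vtypes,
        }
    )
    return GenotypeMatrix(calls=calls, line_ids=line_ids(n), variants=variants)


def _latent_line_effects(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Line main effects L and line-by-sex deviations (n_lines, 2) for (F, M)."""
    L = rng.normal(0.0, np.sqrt(config.var_line), size=config.n_lines)
    LS = rng.normal(0.0, np.sqrt(config.var_line_sex), size=(config.n_lines, 2))
    return L, LS


def _clamp(p: np.ndarray, lo: float = 0.01, hi: float = 0.99) -> np.ndarray:
    return np.clip(p, lo, hi)


def simulate_survival(
    config: SimulationConfig,
    genotypes: GenotypeMatrix | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate replicate-level survival under ``Y = mu + L + S + LxS + eps``.

    Returns a long-format table with one row per line x sex x replicate and
    the truth record of latent effects.  In ``gaussian`` mode the ``value``
    column is the latent replicate value itself (no counts); in ``binomial``
    mode the latent value is mapped to a survival probability (identity link
    clamped to [0.01, 0.99], or logistic) and ``n_survived ~ Binomial(n, p)``
    is drawn with ``value = n_survived / n_exposed``.
    """
    if config.planted_effects and genotypes is None:
        raise ConfigError("planted_effects require a genotype matrix")
    rng = _rng(config.seed, _STREAM_SURV)
    n = config.n_lines
    lids = genotypes.line_ids if genotypes is not None else line_ids(n)
    if len(lids) != n:
        raise ConfigError("genotype matrix does not match n_lines")

    L, LS = _latent_line_effects(config, rng)
    sex_shift = {"F": -config.sex_effect / 2.0, "M": +config.sex_effect / 2.0}
    dose = {"F": config.dose_female, "M": config.dose_male}

    planted_shift = {"F": np.zeros(n), "M": np.zeros(n)}
    planted_truth = []
    for pv in config.planted_effects:
        g = genotypes.calls[:, pv.variant_index]
        carrier = g == 2.0  # missing calls count as non-carrier
        planted_shift["F"] += np.where(carrier, pv.effect_female, 0.0)
        planted_shift["M"] += np.where(carrier, pv.effect_male, 0.0)
        planted_truth.append(
            {
                "variant_index": pv.variant_index,
                "variant_id": genotypes.variants["variant_id"].iloc[pv.variant_index],
                "effect_female": pv.effect_female,
                "effect_male": pv.effect_male,
                "mode": pv.mode,
                "carriers": [lid for lid, c in zip(lids, carrier) if c],
            }
        )

    if config.inversion_effect != 0.0 and covariates is not None:
        inv = covariates["inv_01"].to_numpy(dtype=float)
        planted_shift["F"] += inv * config.inversion_effect
        planted_shift["M"] -= inv * config.inversion_effect

    rows = []
    for s_idx, sex in enumerate(("F", "M")):
        cell_mean = (
            config.mu + sex_shift[sex] + L + LS[:, s_idx] + planted_shift[sex]
        )
        for rep in range(1, config.n_replicates + 1):
            eps = rng.normal(0.0, np.sqrt(config.var_resid), size=n)
            latent = cell_mean + eps
            n_flies = rng.integers(
                config.flies_min, config.flies_max + 1, size=n
            )
            if config.phenotype_mode == "binomial":
                if config.link == "identity":
                    p = _clamp(latent)
                else:
                    p = 1.0 / (1.0 + np.exp(-(latent - config.mu) * 4.0))
                surv = rng.binomial(n_flies, p)
                value = surv / n_flies
            else:
                surv = np.full(n, -1)
                value = latent
            for i, lid in enumerate(lids):
                rows.append(
                    (
                        lid,
                        sex,
                        dose[sex],
                        rep,
                        int(n_flies[i]),
                        int(surv[i]) if config.phenotype_mode == "binomial" else None,
                        float(value[i]),
                    )
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "line_id",
            "sex",
            "dose",
            "replicate",
            "n_exposed",
            "n_survived",
            "value",
        ],
    )
    if config.phenotype_mode == "gaussian":
        table = table.drop(columns=["n_exposed", "n_survived"])

    truth = {
        "config": config.to_dict(),
        "line_effects": dict(zip(lids, L.tolist())),
        "interaction_effects_F": dict(zip(lids, LS[:, 0].tolist())),
        "interaction_effects_M": dict(zip(lids, LS[:, 1].tolist())),
        "planted": planted_truth,
    }
    return table, truth


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Simulate line covariates: infection status with raw indicator read
    counts, and inversion karyotypes as 0/1 factors with MAF > 0.05.

    Read counts are bimodal on a log scale (uninfected mode ~1e2, infected
    mode ~5e4) so that the >7,000-read classification rule separates the two
    groups essentially without error.
    """
    if config.n_lines < 2:
        raise ConfigError("n_lines must be >= 2")
    rng = _rng(config.seed, _STREAM_COV)
    n = config.n_lines
    infected = rng.random(n) < config.wolbachia_prevalence
    reads = np.where(
        infected,
        rng.lognormal(np.log(50_000.0), 0.4, size=n),
        rng.lognormal(np.log(100.0), 0.4, size=n),
    ).astype(int)
    data = {
        "wolbachia": infected.astype(int),
        "wolbachia_reads": reads,
    }
    for k in range(config.n_inversions):
        freq = rng.uniform(0.05, 0.5)
        for _ in range(1000):
            geno = (rng.random(n) < freq).astype(int)
            f = geno.mean()
            if 0.05 < min(f, 1 - f):
                break
        data[f"inv_{k + 1:02d}"] = geno
    cov = pd.DataFrame(data, index=pd.Index(line_ids(n), name="line_id"))
    return cov


def simulate_background_network(
    n_genes: int,
    attachment: int = 2,
    seed: int = 0,
    gene_prefix: str = "gene",
) -> nx.Graph:
    """Scale-free-like background gene-interaction network.

    Barabási–Albert preferential attachment (connected, simple), with each
    edge labelled genetic or physical uniformly at random, standing in for a
    curated interactome.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not (1 <= attachment < n_genes):
        raise ValueError("require 1 <= attachment < n_genes")
    rng = _rng(seed, _STREAM_NET)
    g = nx.barabasi_albert_graph(n_genes, attachment, seed=int(rng.integers(2**31)))
    mapping = {i: f"{gene_prefix}_{i + 1:04d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    for u, v in g.edges:
        g.edges[u, v]["etype"] = str(rng.choice(["genetic", "physical"]))
    g.graph["provenance"] = "synthetic"
    return g


def simulate_gene_models(
    n_genes: int,
    seed: int = 0,
    chrom_length: int = 25_000_000,
    gene_prefix: str = "gene",
) -> pd.DataFrame:
    """Random non-pathological gene models on the simulated chromosomes.

    Genes are uniformly placed intervals of 1-30 kb with random strand;
    overlaps are allowed (fly genes are densely packed).  Gene identifiers
    share the prefix used by :func:`simulate_background_network` so the
    same universe serves annotation and network stages.
    """
    rng = _rng(seed, 5)
    chroms = rng.choice(_CHROMS, size=n_genes)
    starts = rng.integers(1, chrom_length - 40_000, size=n_genes)
    lengths = rng.integers(1_000, 30_000, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)
    biotypes = rng.choice(
        ["protein_coding", "lncRNA", "snoRNA", "asRNA"],
        size=n_genes,
        p=[0.8, 0.12, 0.05, 0.03],
    )
    df = pd.DataFrame(
        {
            "gene_id": [f"{gene_prefix}_{i + 1:04d}" for i in range(n_genes)],
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
            "biotype": biotypes,
        }
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate genotypes, covariates and survival as one consistent cohort."""
    genotypes = simulate_genotypes(config) if config.n_variants > 0 else None
    covariates = simulate_covariates(config)
    survival, truth = simulate_survival(config, genotypes, covariates)
    truth["wolbachia_truth"] = covariates["wolbachia"].to_dict()
    return SyntheticCohort(
        genotypes=genotypes, survival=survival, covariates=covariates, truth=truth
    )
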