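"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as minimal VCF (one sample per inbred line, GT only) or as
a plain variants x lines TSV; phenotypes, covariates, edge lists, ortholog
tables and gene sets are TSV; gene models load from BED (0-based half-open,
converted on input) or GFF3 (1-based inclusive).  Internally everything is
1-based inclusive.  Output tables carry comment headers recording package
version, seed and configuration hash so results are traceable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, VARIANT_COLUMNS

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def header_lines(seed: int | None = None, config_hash: str | None = None) -> list[str]:
    parts = [f"# toxgwas v{__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if config_hash is not None:
        parts.append(f"# config_hash={config_hash}")
    return parts


def write_table(
    df: pd.DataFrame,
    path,
    seed: int | None = None,
    config_hash: str | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines(seed, config_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2: GT-only, one sample per line, 1-based pos."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    order = genotypes.variants.sort_values(["chrom", "pos"]).index
    code = {0.0: "0/0", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=toxgwas_v{__version__}\n")
        for chrom in pd.unique(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.line_ids)
            + "\n"
        )
        for k in order:
            v = genotypes.variants.loc[k]
            gts = [
                code.get(g, "./.") if not np.isnan(g) else "./."
                for g in genotypes.calls[:, k]
            ]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['variant_id']}\t{v['ref']}\t"
                f"{v['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _vtype(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNP"
    return "insertion" if len(alt) > len(ref) else "deletion"


def read_vcf(path, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Load genotypes from VCF with the inbred-line convention.

    Homozygous reference -> 0, homozygous alternate -> 2; heterozygous
    calls are treated as missing (counted and logged) since fully inbred
    lines are expected homozygous; truly missing calls stay missing.
    Multi-allelic records raise unless ``split_multiallelic`` (then each
    ALT becomes its own biallelic pseudo-record).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    n_het = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) > 1 and not split_multiallelic:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "pass split_multiallelic=True to split"
            )
        for ai, alt in enumerate(alts, start=1):
            calls = np.full(len(samples), np.nan)
            for si, gt in enumerate(rec.genotypes):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    continue
                if a == b == 0:
                    calls[si] = 0.0
                elif a == b == ai:
                    calls[si] = 2.0
                elif a == b:
                    continue  # homozygous for a different alt allele
                else:
                    n_het += 1  # heterozygous: missing under inbred coding
            vid = rec.ID if rec.ID not in (None, ".") else (
                f"{rec.CHROM}_{rec.POS}_{rec.REF}_{alt}"
            )
            rows.append(calls)
            meta.append((vid, rec.CHROM, rec.POS, rec.REF, alt, _vtype(rec.REF, alt)))
    if n_het:
        logger.info("%d heterozygous calls treated as missing", n_het)
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    calls = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(calls=calls, line_ids=samples, variants=variants)


# ---------------------------------------------------------------------------
# genotype matrix TSV


def write_genotype_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.concat(
        [genotypes.variants.set_index("variant_id"), genotypes.to_frame()],
        axis=1,
    )
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    meta_cols = [c for c in VARIANT_COLUMNS if c != "variant_id"]
    lines = [c for c in df.columns if c not in meta_cols]
    variants = df[meta_cols].reset_index()
    calls = df[lines].to_numpy(dtype=float).T
    return GenotypeMatrix(calls=calls, line_ids=lines, variants=variants)


# ---------------------------------------------------------------------------
# graphs, orthologs, gene sets, gene models


def write_edges(graph: nx.Graph, path) -> None:
    rows = [
        (u, v, d.get("etype", "unknown")) for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "edge_type"]).to_csv(
        path, sep="\t", index=False
    )


def read_edges(path) -> nx.Graph:
    df = read_table(path)
    g = nx.Graph()
    for row in df.itertuples():
        g.add_edge(row.gene_a, row.gene_b, etype=row.edge_type)
    return g


def read_orthologs(path) -> pd.DataFrame:
    df = read_table(path)
    need = {"fly_gene", "human_gene", "score"}
    if need - set(df.columns):
        raise ValueError(f"ortholog table needs columns {sorted(need)}")
    return df


def read_gene_sets(path) -> dict[str, set]:
    """Two-column TSV (term_id, gene_id) or GMT (term, description, genes...)."""
    path = Path(path)
    sets: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = set(parts[2:])
        return sets
    df = read_table(path)
    for term, grp in df.groupby(df.columns[0]):
        sets[term] = set(grp[df.columns[1]])
    return sets


def read_bed(path) -> pd.DataFrame:
    """Gene models from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6),
    )
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(int) + 1,
            "end": df["end"].astype(int),
            "strand": df["strand"].fillna("+"),
            "biotype": "unknown",
        }
    )
    return out


def write_bed(genes: pd.DataFrame, path) -> None:
    """1-based inclusive gene models -> BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for row in genes.itertuples():
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


def _gff_attr(attrs: str, key: str) -> str | None:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith(key + "="):
            return field[len(key) + 1 :]
    return None


def read_gff3(path, feature: str = "gene") -> pd.DataFrame:
    """Gene models from GFF3 (1-based inclusive), ``gene`` features only."""
    cols = [
        "chrom", "source", "type", "start", "end", "score", "strand",
        "phase", "attributes",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    df = df[df["type"] == feature].copy()
    gene_ids = []
    for attrs in df["attributes"]:
        gid = _gff_attr(attrs, "ID") or _gff_attr(attrs, "gene_id")
        gene_ids.append(gid)
    biotype = [
        _gff_attr(a, "biotype") or _gff_attr(a, "gene_biotype") or "unknown"
        for a in df["attributes"]
    ]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": df["chrom"].astype(str).to_numpy(),
            "start": df["start"].astype(int).to_numpy(),
            "end": df["end"].astype(int).to_numpy(),
            "strand": df["strand"].to_numpy(),
            "biotype": biotype,
        }
    )
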