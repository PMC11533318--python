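"""Candidate-gene assignment for significant variants.

A variant is assigned to every gene whose body, extended by a +/-5 kb
window on each side, contains its position (coordinates 1-based inclusive).
Genes overlap freely in a compact genome, so one variant can implicate
several genes at once.  Each assignment carries a positional site class —
``genic`` (inside the gene body) or ``upstream_5kb`` / ``downstream_5kb``
relative to the gene's strand; variants hitting no window are intergenic.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def _site_class(pos: int, start: int, end: int, strand: str) -> str:
    if start <= pos <= end:
        return "genic"
    if pos < start:
        return "upstream_5kb" if strand == "+" else "downstream_5kb"
    return "downstream_5kb" if strand == "+" else "upstream_5kb"


def assign_candidate_genes(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign variants to genes within ``window`` bp of the gene body.

    Parameters
    ----------
    variants
        Columns ``variant_id, chrom, pos`` (plus optional ``analysis``).
    genes
        Columns ``gene_id, chrom, start, end, strand`` (1-based inclusive).

    Returns
    -------
    (assignments, intergenic): assignments has one row per (variant, gene)
    pair with the site class; intergenic lists variants assigned nowhere.
    """
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene start must be <= end")

    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby("chrom"):
        t = IntervalTree()
        for row in grp.itertuples():
            # interval end +1: IntervalTree is half-open, coords inclusive
            t.addi(row.start - window, row.end + window + 1, row.Index)
        trees[chrom] = t

    has_analysis = "analysis" in variants.columns
    assigned, intergenic = [], []
    for row in variants.itertuples():
        tree = trees.get(row.chrom)
        hits = tree[row.pos] if tree is not None else None
        if tree is None:
            warnings.warn(
                f"variant {row.variant_id}: chromosome {row.chrom!r} absent "
                "from gene models; intergenic"
            )
        if not hits:
            intergenic.append(
                (row.variant_id, row.chrom, row.pos)
                + ((row.analysis,) if has_analysis else ())
            )
            continue
        for iv in hits:
            g = genes.loc[iv.data]
            assigned.append(
                (
                    row.variant_id,
                    row.chrom,
                    row.pos,
                    g["gene_id"],
                    _site_class(row.pos, int(g["start"]), int(g["end"]), g["strand"]),
                )
                + ((row.analysis,) if has_analysis else ())
            )
    extra = ["analysis"] if has_analysis else []
    assignments = pd.DataFrame(
        assigned,
        columns=["variant_id", "chrom", "pos", "gene_id", "site_class"] + extra,
    )
    inter = pd.DataFrame(
        intergenic, columns=["variant_id", "chrom", "pos"] + extra
    )
    return assignments, inter


def candidate_genes(assignments: pd.DataFrame) -> pd.DataFrame:
    """Aggregate assignments into one row per candidate gene."""
    if assignments.empty:
        return pd.DataFrame(columns=["gene_id", "n_variants", "variants", "analyses"])
    agg: dict[str, object] = {"variant_id": lambda s: sorted(set(s))}
    grouped = assignments.groupby("gene_id")
    out = pd.DataFrame(
        {
            "n_variants": grouped["variant_id"].nunique(),
            "variants": grouped["variant_id"].agg(lambda s: ";".join(sorted(set(s)))),
        }
    )
    if "analysis" in assignments.columns:
        out["analyses"] = grouped["analysis"].agg(
            lambda s: ";".join(sorted(set(s)))
        )
    return out.reset_index()


def tabulate_analyses(
    sets_per_analysis: dict[str, tuple[set, set]],
) -> dict:
    """Counts and overlaps of candidate variant/gene sets across analyses.

    ``sets_per_analysis`` maps analysis name to ``(variant_set, gene_set)``.
    Returns per-analysis counts, all pairwise intersections and the global
    intersection, for variants and genes separately.
    """
    names = sorted(sets_per_analysis)
    counts = {
        a: {"n_variants": len(v), "n_genes": len(g)}
        for a, (v, g) in sets_per_analysis.items()
    }
    pairwise = defaultdict(dict)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairwise[(a, b)] = {
                "variants": sets_per_analysis[a][0] & sets_per_analysis[b][0],
                "genes": sets_per_analysis[a][1] & sets_per_analysis[b][1],
            }
    global_v = set.intersection(*(v for v, _ in sets_per_analysis.values())) if names else set()
    global_g = set.intersection(*(g for _, g in sets_per_analysis.values())) if names else set()
    union_v = set.union(*(v for v, _ in sets_per_analysis.values())) if names else set()
    union_g = set.union(*(g for _, g in sets_per_analysis.values())) if names else set()
    return {
        "counts": counts,
        "pairwise": dict(pairwise),
        "global_intersection": {"variants": global_v, "genes": global_g},
        "union": {"variants": union_v, "genes": union_g},
    }
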