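"""Gene-set over-representation analysis.

One-sided Fisher's exact test per term (equivalently the upper
hypergeometric tail) with Benjamini-Hochberg FDR control across terms.
Fold enrichment is the ratio of the observed overlap fraction to the
term's share of the universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    gene_list,
    term_sets: dict[str, set],
    universe,
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each term set.

    Term sets are intersected with the universe; the gene list must be a
    subset of the universe.  Returns one row per term with the one-sided
    Fisher P, BH-FDR and fold enrichment, sorted by P.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene list not contained in universe")
    if not genes:
        return pd.DataFrame(
            columns=[
                "term_id", "term_size", "list_size", "overlap",
                "universe_size", "fold_enrichment", "p_value", "fdr",
            ]
        )
    M, n_list = len(universe), len(genes)
    rows = []
    for term, members in term_sets.items():
        members = set(members) & universe
        k_term = len(members)
        if k_term == 0:
            continue
        overlap = len(genes & members)
        # upper hypergeometric tail: P(X >= overlap)
        p = float(stats.hypergeom.sf(overlap - 1, M, k_term, n_list))
        fold = (overlap / n_list) / (k_term / M)
        rows.append((term, k_term, n_list, overlap, M, fold, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_size", "list_size", "overlap",
            "universe_size", "fold_enrichment", "p_value",
        ],
    )
    if not out.empty:
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        out["fdr"] = []
    return out
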