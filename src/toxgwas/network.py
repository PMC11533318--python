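"""Candidate-gene interaction networks and permutation significance.

Candidate genes from an association analysis are mapped onto a background
interactome (undirected, edges labelled genetic/physical).  Non-candidate
genes connected to at least two candidates are recruited; the induced
subgraph over candidates plus recruits is the trait network.  Its
connectivity index (mean node degree, 2|E|/|V|) is compared with a Monte
Carlo null built by repeatedly sampling equally many genes uniformly from
the background and computing the same index; P = n_X / N with n_X the
number of null draws strictly exceeding the observed connectivity, shown as
"< 1/N" when none do.

Cross-species comparison maps each fly gene to its single best-scoring
human ortholog and counts fly edges whose mapped endpoint pair is also an
edge of the human network ("edge correctness").
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .containers import ConnectivityTest

logger = logging.getLogger(__name__)


def _as_simple(graph: nx.Graph) -> nx.Graph:
    """Collapse to a simple graph: drop self-loops, merge duplicate edges."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes(data=True))
    for u, v, data in graph.edges(data=True):
        if u == v:
            continue
        if g.has_edge(u, v):
            old = g.edges[u, v].get("etype")
            new = data.get("etype")
            if old and new and old != new:
                g.edges[u, v]["etype"] = "genetic+physical"
        else:
            g.add_edge(u, v, **data)
    return g


def recruit_network(
    candidates: set[str],
    background: nx.Graph,
    min_links: int = 2,
) -> nx.Graph:
    """Build the candidate network with computational recruitment.

    Node set: candidates present in the background, plus every non-candidate
    background gene adjacent to at least ``min_links`` candidates.  Edge
    set: all background edges between retained nodes.  Candidates absent
    from the background are kept as isolated candidate nodes (logged).
    """
    if not candidates:
        return nx.Graph()
    bg = _as_simple(background)
    present = {c for c in candidates if c in bg}
    absent = candidates - present
    if absent:
        logger.info("%d candidate genes absent from background", len(absent))
    recruited = set()
    for gene in bg.nodes:
        if gene in present:
            continue
        n_links = sum(1 for nb in bg.neighbors(gene) if nb in present)
        if n_links >= min_links:
            recruited.add(gene)
    nodes = present | recruited
    net = bg.subgraph(nodes).copy()
    net.add_nodes_from(absent)  # isolated candidates, kept for bookkeeping
    for n in net.nodes:
        net.nodes[n]["role"] = "candidate" if n in candidates else "recruited"
    return net


def connectivity_index(network: nx.Graph) -> float:
    """Mean node degree ``2 |E| / |V|`` of the collapsed simple graph."""
    g = _as_simple(network)
    if g.number_of_nodes() == 0:
        warnings.warn("empty network: connectivity undefined")
        return float("nan")
    return 2.0 * g.number_of_edges() / g.number_of_nodes()


def permutation_test(
    network: nx.Graph,
    background: nx.Graph,
    n_perm: int = 10000,
    seed: int = 0,
) -> ConnectivityTest:
    """Monte Carlo test of network connectivity against random gene sets.

    Each permutation draws ``|V(network)|`` genes uniformly without
    replacement from the background gene universe, takes the induced
    subgraph and records its mean degree.  Exceedance is strict (ties count
    as non-exceeding).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    bg = _as_simple(background)
    n_nodes = network.number_of_nodes()
    if n_nodes > bg.number_of_nodes():
        raise ValueError("network larger than background universe")
    if n_nodes == 0:
        raise ValueError("empty observed network")
    observed = connectivity_index(network)

    genes = list(bg.nodes)
    index = {g: i for i, g in enumerate(genes)}
    rows, cols = [], []
    for u, v in bg.edges:
        rows.append(index[u])
        cols.append(index[v])
    A = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(genes), len(genes)),
    )
    A = (A + A.T).tocsr()

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(genes), size=n_nodes, replace=False)
        sub = A[pick][:, pick]
        null[i] = sub.sum() / n_nodes  # = 2 E_induced / |S|
    n_exceed = int((null > observed).sum())
    n_ties = int((null == observed).sum())
    if n_ties:
        logger.info("%d null draws tied with observed connectivity", n_ties)
    return ConnectivityTest(
        observed_connectivity=observed,
        null_values=null,
        n_permutations=n_perm,
        n_exceed=n_exceed,
        p_value=n_exceed / n_perm,
    )


def best_orthologs(table: pd.DataFrame, min_score: int = 3) -> pd.DataFrame:
    """Best-scoring human ortholog per fly gene, thresholded on score.

    Input columns ``fly_gene, human_gene, score`` (non-negative integer
    confidence scores).  Ties on the top score break lexicographically on
    the human gene name (logged).
    """
    req = {"fly_gene", "human_gene", "score"}
    if req - set(table.columns):
        raise ValueError(f"ortholog table needs columns {sorted(req)}")
    if (table["score"] < 0).any():
        raise ValueError("scores must be non-negative")
    kept = table[table["score"] >= min_score]
    rows = []
    for fly, grp in kept.groupby("fly_gene"):
        top = grp[grp["score"] == grp["score"].max()]
        if len(top) > 1:
            logger.info(
                "fly gene %s: score tie among %s; lexicographic pick",
                fly,
                sorted(top["human_gene"]),
            )
        pick = top.sort_values("human_gene").iloc[0]
        rows.append((fly, pick["human_gene"], int(pick["score"])))
    return pd.DataFrame(rows, columns=["fly_gene", "human_gene", "score"])


def edge_correctness(
    fly_net: nx.Graph,
    human_net: nx.Graph,
    orthologs: pd.DataFrame,
) -> tuple[int, int, float]:
    """Shared-edge count and percentage between species.

    A fly edge (a, b) is shared iff both endpoints map through the ortholog
    table and the mapped pair is an edge of the human network.  Returns
    ``(shared, total_fly_edges, percent)``.
    """
    fly = _as_simple(fly_net)
    human = _as_simple(human_net)
    total = fly.number_of_edges()
    if total == 0:
        warnings.warn("fly network has no edges; edge correctness undefined")
        return 0, 0, float("nan")
    mapping = dict(zip(orthologs["fly_gene"], orthologs["human_gene"]))
    shared = 0
    for a, b in fly.edges:
        ha, hb = mapping.get(a), mapping.get(b)
        if ha is not None and hb is not None and human.has_edge(ha, hb):
            shared += 1
    return shared, total, 100.0 * shared / total
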