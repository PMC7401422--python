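"""Functional categories for significant pathways and the shared-gene network.

Significant pathways are grouped into functional categories either from a
curated mapping file (the faithful mode: category labels are human
judgment, supplied as input) or, as an automated surrogate, by
single-linkage clustering of the pathways' changed-gene sets at a Jaccard
similarity threshold. Categories become super-nodes of a gene-category
graph in which a gene is linked to every category that contains a
significant pathway listing it as changed; only genes beyond the display
fold-change cutoff appear, and a gene node's degree counts the clusters
it is shared between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class CategoryAssignment:
    """pathway_id -> category label, with provenance of how labels arose."""

    mapping: dict
    provenance: str  # 'manual_config' or 'overlap_cluster'
    warnings: list = field(default_factory=list)


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def assign_categories(
    results: pd.DataFrame,
    pathway_changed_genes: dict,
    mapping: dict | None = None,
    jaccard_threshold: float = 0.3,
    pathway_names: dict | None = None,
) -> CategoryAssignment:
    """Label each significant pathway with one functional category.

    With a curated ``mapping`` (pathway_id -> label) the labels are copied
    and unmapped pathways get ``"unassigned"``. Without one, pathways are
    single-linkage clustered on the Jaccard similarity of their
    changed-gene sets (edge when similarity >= threshold, clusters =
    connected components), and each cluster is labelled by the name of its
    largest pathway.
    """
    if results.empty:
        raise ValueError("no significant pathways to categorize")
    pids = list(results["pathway_id"])
    if mapping is not None:
        unknown = sorted(set(mapping) - set(pids))
        warns = [f"mapping refers to unknown pathway ids: {unknown}"] if unknown else []
        if unknown:
            log.warning(warns[0])
        return CategoryAssignment(
            {pid: mapping.get(pid, "unassigned") for pid in pids},
            provenance="manual_config",
            warnings=warns,
        )
    g = nx.Graph()
    g.add_nodes_from(pids)
    for i, a in enumerate(pids):
        for b in pids[i + 1 :]:
            if jaccard(set(pathway_changed_genes.get(a, ())), set(pathway_changed_genes.get(b, ()))) >= jaccard_threshold:
                g.add_edge(a, b)
    names = pathway_names or {}
    assignment = {}
    for comp in nx.connected_components(g):
        # label by the largest member pathway (ties: smallest id)
        rep = sorted(comp, key=lambda p: (-len(pathway_changed_genes.get(p, ())), p))[0]
        label = names.get(rep, rep)
        for pid in comp:
            assignment[pid] = label
    return CategoryAssignment(assignment, provenance="overlap_cluster")


def build_network(
    assignment: CategoryAssignment,
    results: pd.DataFrame,
    pathway_changed_genes: dict,
    gene_logfc: dict,
    display_cutoff: float = 0.58,
) -> nx.Graph:
    """Bipartite gene-category graph of the significant pathways.

    A gene enters iff |logFC| > ``display_cutoff`` and it is a changed
    gene of at least one significant pathway; it is linked to every
    category holding such a pathway. Gene nodes carry ``logFC``,
    ``direction`` (up/down from the sign) and ``n_clusters`` (their
    degree, the node-size attribute); categories without any retained
    gene are dropped.
    """
    g = nx.Graph()
    for _, row in results.iterrows():
        pid = row["pathway_id"]
        cat = assignment.mapping.get(pid)
        if cat is None:
            continue
        for gene in sorted(pathway_changed_genes.get(pid, ())):
            lfc = gene_logfc.get(gene)
            if lfc is None:
                raise ValueError(f"no logFC supplied for changed gene {gene}")
            if abs(lfc) > display_cutoff:
                if gene not in g:
                    g.add_node(gene, kind="gene", logFC=float(lfc),
                               direction="up" if lfc > 0 else "down")
                if cat not in g:
                    g.add_node(cat, kind="category")
                g.add_edge(gene, cat)
    for node, data in g.nodes(data=True):
        if data["kind"] == "gene":
            g.nodes[node]["n_clusters"] = g.degree(node)
    isolated = [n for n, d in g.nodes(data=True) if d["kind"] == "category" and g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    return g


def shared_gene_table(network: nx.Graph, min_clusters: int = 2) -> pd.DataFrame:
    """Genes shared between at least ``min_clusters`` functional clusters.

    Sorted by cluster count descending, then gene id; the category list
    is alphabetical.
    """
    rows = []
    for node, data in network.nodes(data=True):
        if data.get("kind") != "gene":
            continue
        k = data["n_clusters"]
        if k >= min_clusters:
            cats = sorted(network.neighbors(node))
            rows.append({"gene": node, "n_clusters": k, "categories": ", ".join(cats)})
    df = pd.DataFrame(rows, columns=["gene", "n_clusters", "categories"])
    if df.empty:
        return df
    return df.sort_values(["n_clusters", "gene"], ascending=[False, True], kind="stable").reset_index(drop=True)


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)


def write_sif(network: nx.Graph, path) -> None:
    """Topology-only SIF export: category <member> gene lines."""
    with open(path, "w") as fh:
        for a, b in sorted(network.edges()):
            cat, gene = (a, b) if network.nodes[a]["kind"] == "category" else (b, a)
            fh.write(f"{cat}\tmember\t{gene}\n")
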