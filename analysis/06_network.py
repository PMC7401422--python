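"""Cluster the significant pathways and export the shared-gene network.

Significant pathways from the integrated branch are grouped by Jaccard
overlap of their changed-gene sets (the automated surrogate for curated
functional categories); genes with |weighted LogFC| > 0.58 are linked to
every category containing them, and the genes shared between two or more
clusters are tabulated.
"""

from pathlib import Path

from tmmeta import enrichment as enr
from tmmeta import io
from tmmeta.pipeline import stage_network

ROOT = Path(__file__).resolve().parent.parent
RES = ROOT / "results"

if __name__ == "__main__":
    results = io.read_tsv(RES / "enrichment_integrated.tsv")
    coll = enr.read_gmt(RES / "data" / "pathways.gmt", source="sim")
    integrated = io.read_tsv(RES / "integrated_gene_stats.tsv", index_col=0)
    changed = set(integrated.index[integrated["is_differentially_expressed"]])
    graph, table, assignment = stage_network(
        results, coll, changed, integrated["weighted_logFC"].to_dict(), RES, seed=1
    )
    n_cat = sum(1 for _, d in graph.nodes(data=True) if d["kind"] == "category")
    print(f"network: {graph.number_of_nodes() - n_cat} genes across {n_cat} clusters, "
          f"{graph.number_of_edges()} edges ({assignment.provenance})")
    print("genes shared between >=2 clusters:")
    print(table.to_string(index=False) if len(table) else "  none")
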