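"""Normalize, QC and compute per-study differential statistics.

Each study is quantile-normalized, samples are screened by median
pairwise correlation, replicates are averaged so every individual counts
once, and a moderated t-test yields per-probe LogFC and p, which are then
mapped to genes keeping the strongest probe per gene.
"""

from pathlib import Path

from tmmeta.pipeline import stage_prep

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "prep"

if __name__ == "__main__":
    study_paths = sorted(DATA.glob("study*_expression.tsv"))
    studies = [
        (p, DATA / p.name.replace("_expression", "_metadata"), p.name.split("_")[0])
        for p in study_paths
    ]
    stats = stage_prep(studies, DATA / "probe_gene_map.tsv", OUT, seed=1)
    per_study = stats.groupby("study_id").size()
    print("genes with statistics per study:")
    print(per_study.to_string())
    print(f"total per-study gene records: {len(stats)}")
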