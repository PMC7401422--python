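"""Generate the synthetic multi-study dataset the analyses run on.

Emulates five small treated-vs-control expression studies (1, 2, 3, 5 and
6 individuals; triplicate arrays; partially overlapping gene coverage;
~30% of genes measured by two probes), 50 synthetic pathways of which
three are enriched for the planted differential signal, and a
responder/nonresponder mean-abundance table with 100 responder-specific
genes. Everything is written under results/data with a fixed seed.
"""

from pathlib import Path

from tmmeta.pipeline import stage_simulate
from tmmeta.simulate import SimulationConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

if __name__ == "__main__":
    cfg = SimulationConfig(seed=1)
    sim = stage_simulate(OUT, cfg)
    n_probes = sum(len(m.values) for m in sim.studies)
    print(f"wrote {len(sim.studies)} studies ({n_probes} probe rows total) to {OUT}")
    print(f"planted {len(sim.truth.de_gene_ids)} DE genes at |log2FC| = {cfg.effect_size_log2}")
    print(f"enriched pathways: {sorted(sim.truth.enriched_pathway_ids)}")
    print(f"per-study coverage fractions: {[round(c, 3) for c in sim.coverage_fractions]}")
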