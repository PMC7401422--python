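"""Synthetic multi-study expression data with planted pathway signal.

The generator emulates the statistical structure the integration pipeline
assumes: five small studies with 1-6 individuals each, optional
within-individual replicates, partially overlapping gene coverage,
multi-probe genes, a shared differential-expression signal concentrated in
designated pathways, and a responder/nonresponder mean-abundance table
with responder-specific effects.

Expression values are log2 intensities; the noise model is additive
Gaussian on the log2 scale. Each study draws from its own seeded
substream so adding a study never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import Pathway, PathwayCollection
from .normalize import ExpressionMatrix


class InfeasibleDesignError(ValueError):
    """Raised when study coverage is too sparse for k-of-n filtering."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic multi-study generator.

    Defaults mirror the donor structure of the real studies (1, 2, 3, 5
    and 6 individuals across five studies, triplicate arrays), with a
    1.0 log2-unit treatment effect against 0.3 log2 units of sample noise.
    """

    n_genes: int = 2000
    n_studies: int = 5
    individuals_per_study: tuple = (1, 2, 3, 5, 6)
    replicates_per_individual: int = 3
    coverage_fraction_range: tuple = (0.85, 1.0)
    multiprobe_fraction: float = 0.3
    n_pathways: int = 50
    pathway_size_range: tuple = (10, 40)
    enriched_pathway_ids: tuple = ("PW0001", "PW0002", "PW0003")
    de_fraction_background: float = 0.05
    de_fraction_enriched: float = 0.6
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.3
    responder_effect_log2: float = 1.5
    n_responder_specific: int = 100
    seed: int = 0

    def validate(self) -> None:
        for name in ("multiprobe_fraction", "de_fraction_background", "de_fraction_enriched"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        lo, hi = self.coverage_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("coverage_fraction_range must lie in (0,1] with lo<=hi")
        if len(self.individuals_per_study) != self.n_studies:
            raise ValueError("individuals_per_study length must equal n_studies")
        if self.pathway_size_range[0] < 4:
            raise ValueError("pathway_size_range minimum must be >=4")
        if self.effect_size_log2 <= 0 or self.noise_sd_log2 < 0:
            raise ValueError("effect_size_log2 must be >0 and noise_sd_log2 >=0")
        if any(k <= 0 for k in (self.n_genes, self.n_studies, self.replicates_per_individual)):
            raise ValueError("counts must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted signal: which genes/pathways carry the effect."""

    de_gene_ids: set
    true_log2fc: dict
    enriched_pathway_ids: set
    responder_specific_gene_ids: set = field(default_factory=set)


@dataclass
class SimulatedStudies:
    studies: list  # of ExpressionMatrix
    probe_gene_map: pd.DataFrame  # columns probe_id, gene_id
    truth: GroundTruth
    pathways: PathwayCollection
    coverage_fractions: list


def _gene_ids(n):
    return [f"G{i:05d}" for i in range(1, n + 1)]


def coverage_at_least_k_probability(coverages, k) -> float:
    """Poisson-binomial P(gene covered by >= k studies), by DP."""
    probs = np.zeros(len(coverages) + 1)
    probs[0] = 1.0
    for c in coverages:
        probs = probs * (1 - c) + np.concatenate([[0.0], probs[:-1]]) * c
    return float(probs[k:].sum())


def _plant_pathways(cfg: SimulationConfig, genes, de_genes, rng) -> PathwayCollection:
    """Random gene sets; enriched pathways draw most members from DE genes."""
    de = sorted(de_genes)
    non_de = [g for g in genes if g not in de_genes]
    pathways = []
    lo, hi = cfg.pathway_size_range
    enriched = set(cfg.enriched_pathway_ids)
    for i in range(1, cfg.n_pathways + 1):
        pid = f"PW{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if pid in enriched:
            n_hit = min(math.ceil(cfg.de_fraction_enriched * size), len(de))
            members = list(rng.choice(de, size=n_hit, replace=False))
            members += list(rng.choice(non_de, size=size - n_hit, replace=False))
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        pathways.append(Pathway(pid, f"synthetic pathway {i}", "sim", frozenset(members)))
    return PathwayCollection(pathways)


def simulate_studies(cfg: SimulationConfig) -> SimulatedStudies:
    """Generate per-study probe-level matrices, a probe->gene map and truth.

    Treated samples of differentially expressed genes are shifted by the
    gene's true log2 fold change; probes of a multi-probe gene share the
    gene effect plus a fixed probe-level offset. Deterministic given
    ``cfg.seed``.
    """
    cfg.validate()
    master = np.random.default_rng([cfg.seed, 0])
    genes = _gene_ids(cfg.n_genes)

    n_de = round(cfg.de_fraction_background * cfg.n_genes)
    de_genes = set(master.choice(genes, size=n_de, replace=False))
    signs = master.choice([-1.0, 1.0], size=n_de)
    true_lfc = {g: s * cfg.effect_size_log2 for g, s in zip(sorted(de_genes), signs)}

    pathways = _plant_pathways(cfg, genes, de_genes, master)

    # probes: every gene has one, a fraction get a second
    n_multi = round(cfg.multiprobe_fraction * cfg.n_genes)
    multi = set(master.choice(genes, size=n_multi, replace=False))
    probe_rows = []
    for g in genes:
        probe_rows.append((f"{g}_p1", g))
        if g in multi:
            probe_rows.append((f"{g}_p2", g))
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id"])
    probe_offsets = master.normal(0.0, 0.25, size=len(probe_map))
    baselines = pd.Series(master.normal(7.0, 1.0, size=cfg.n_genes), index=genes)

    lo, hi = cfg.coverage_fraction_range
    studies, coverages = [], []
    for s_idx in range(cfg.n_studies):
        rng = np.random.default_rng([cfg.seed, 1 + s_idx])
        cov = float(rng.uniform(lo, hi))
        coverages.append(cov)
        n_cov = max(1, round(cov * cfg.n_genes))
        covered = set(rng.choice(genes, size=n_cov, replace=False))
        mask = probe_map["gene_id"].isin(covered).to_numpy()
        probes = probe_map["probe_id"].to_numpy()[mask]
        p_genes = probe_map["gene_id"].to_numpy()[mask]
        p_off = probe_offsets[mask]

        n_ind = cfg.individuals_per_study[s_idx]
        cols, meta = [], []
        for ind in range(1, n_ind + 1):
            for cond in ("treated", "control"):
                for rep in range(1, cfg.replicates_per_individual + 1):
                    sid = f"S{s_idx + 1}_I{ind}_{cond}_r{rep}"
                    cols.append(sid)
                    meta.append((sid, f"I{ind}", cond, rep))
        base = baselines.loc[p_genes].to_numpy() + p_off
        effect = np.array([true_lfc.get(g, 0.0) for g in p_genes])
        data = np.empty((len(probes), len(cols)))
        for j, (_, _, cond, _) in enumerate(meta):
            mu = base + (effect if cond == "treated" else 0.0)
            data[:, j] = mu + rng.normal(0.0, cfg.noise_sd_log2, size=len(probes))
        values = pd.DataFrame(data, index=pd.Index(probes, name="probe_id"), columns=cols)
        metadata = pd.DataFrame(
            meta, columns=["sample_id", "individual", "condition", "replicate"]
        ).set_index("sample_id")
        studies.append(ExpressionMatrix(values, metadata, study_id=f"study{s_idx + 1}"))

    k = min(4, cfg.n_studies)
    expected = cfg.n_genes * coverage_at_least_k_probability(coverages, k)
    if expected < 1.0:
        raise InfeasibleDesignError(
            f"coverage {coverages} leaves {expected:.2f} genes expected in >= {k} studies"
        )

    truth = GroundTruth(
        de_gene_ids=de_genes,
        true_log2fc=true_lfc,
        enriched_pathway_ids=set(cfg.enriched_pathway_ids),
        responder_specific_gene_ids=set(),
    )
    return SimulatedStudies(studies, probe_map, truth, pathways, coverages)


def simulate_responder_table(cfg: SimulationConfig):
    """Gene x {A,B,C,D} mean-abundance table with responder-specific effects.

    Columns follow the responder-contrast convention: A/B are the
    responder group's treated/control mean abundances, C/D the
    nonresponder group's. Responder-specific genes carry an extra
    ``responder_effect_log2`` shift on the (abundance+1) ratio of the
    responder arm only, so the construction is pseudocount-exact at zero
    noise. Noise multiplies (abundance+1) by 2**N(0, noise_sd_log2).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 10_001])
    genes = _gene_ids(cfg.n_genes)

    n_de = round(cfg.de_fraction_background * cfg.n_genes)
    de_genes = set(rng.choice(genes, size=n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    true_lfc = {g: s * cfg.effect_size_log2 for g, s in zip(sorted(de_genes), signs)}
    n_rs = min(cfg.n_responder_specific, cfg.n_genes)
    resp_specific = set(rng.choice(genes, size=n_rs, replace=False))

    base = rng.lognormal(mean=3.0, sigma=1.0, size=cfg.n_genes)

    def noisy(x):
        if cfg.noise_sd_log2 == 0:
            return x
        eps = rng.normal(0.0, cfg.noise_sd_log2, size=len(x))
        return np.maximum(0.0, (x + 1.0) * 2.0 ** eps - 1.0)

    lfc = np.array([true_lfc.get(g, 0.0) for g in genes])
    resp = np.array([cfg.responder_effect_log2 if g in resp_specific else 0.0 for g in genes])
    b0 = base
    d0 = base
    a0 = np.maximum(0.0, (b0 + 1.0) * 2.0 ** (lfc + resp) - 1.0)
    c0 = np.maximum(0.0, (d0 + 1.0) * 2.0 ** lfc - 1.0)
    table = pd.DataFrame(
        {"A": noisy(a0), "B": noisy(b0), "C": noisy(c0), "D": noisy(d0)},
        index=pd.Index(genes, name="gene_id"),
    )
    truth = GroundTruth(
        de_gene_ids=de_genes,
        true_log2fc=true_lfc,
        enriched_pathway_ids=set(),
        responder_specific_gene_ids=resp_specific,
    )
    return table, truth
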