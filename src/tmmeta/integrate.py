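"""Cross-study integration: weighted-average LogFC and p-value.

Each gene's per-study log2 fold changes are combined with weights
``-log10(p_i)`` so that studies with stronger evidence contribute more:

    weighted LogFC = sum_i logFC_i * (-log10 p_i) / sum_i (-log10 p_i)
    average weight = sum_i (-log10 p_i) / n

The average weight back-transforms to a combined p-value
``10**(-average weight)``, the geometric mean of the study p-values.
Genes measured in fewer than ``k_min`` of the studies are dropped for
robustness (default: 4 of 5).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


@dataclass
class IntegrationConfig:
    """Filtering and significance parameters for the integrated dataset.

    ``logfc_cutoff`` of 0.58 corresponds to roughly a 1.5-fold change on
    the original scale (2**0.58 ~ 1.5). ``size_weighted`` additionally
    multiplies each study's weight by its number of individuals.
    """

    k_min: int = 4
    n_total: int = 5
    logfc_cutoff: float = 0.58
    p_cutoff: float = 0.05
    size_weighted: bool = False

    def validate(self) -> None:
        if self.k_min > self.n_total:
            raise ValueError(f"k_min={self.k_min} exceeds n_total={self.n_total}")
        if self.k_min < 1:
            raise ValueError("k_min must be >=1")
        if self.logfc_cutoff <= 0 or self.p_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


def _check_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def weighted_logfc(logfcs, pvalues) -> float:
    """Evidence-weighted average log2 fold change across studies.

    When every p equals 1 all weights vanish; the unweighted arithmetic
    mean is returned as a documented fallback.
    """
    lf = np.asarray(logfcs, dtype=float)
    p = _check_pvalues(pvalues)
    if lf.shape != p.shape:
        raise ValueError("logfcs and pvalues must have equal length")
    w = -np.log10(p)
    total = w.sum()
    if total == 0.0:
        return float(lf.mean())
    return float((lf * w).sum() / total)


def weighted_pvalue(pvalues):
    """Average weight (mean -log10 p) and its back-transformed p-value.

    The combined p is the geometric mean of the inputs, so it always lies
    between min(p) and max(p).
    """
    p = _check_pvalues(pvalues)
    avg_weight = float(-np.log10(p).mean())
    return avg_weight, float(10.0 ** (-avg_weight))


def integrate_studies(stats: pd.DataFrame, cfg: IntegrationConfig | None = None) -> pd.DataFrame:
    """Merge deduplicated per-study gene statistics into one table.

    ``stats`` needs columns ``study_id``, ``gene_id``, ``logFC``,
    ``p_value`` (and ``n_individuals`` when ``cfg.size_weighted``). Genes
    measured in fewer than ``k_min`` studies are removed; a gene is called
    differentially expressed when |weighted LogFC| > ``logfc_cutoff`` and
    combined p < ``p_cutoff`` (both strict).
    """
    cfg = cfg or IntegrationConfig()
    cfg.validate()
    if stats.duplicated(["study_id", "gene_id"]).any():
        dups = stats[stats.duplicated(["study_id", "gene_id"])][["study_id", "gene_id"]]
        raise ValueError(
            f"duplicate (study, gene) records — deduplicate per study first: "
            f"{dups.head(5).to_dict('records')}"
        )
    p = _check_pvalues(stats["p_value"].to_numpy())
    df = stats.copy()
    df["weight"] = -np.log10(p)
    if cfg.size_weighted:
        df["lfc_weight"] = df["weight"] * df["n_individuals"]
    else:
        df["lfc_weight"] = df["weight"]
    df["wlfc"] = df["logFC"] * df["lfc_weight"]

    g = df.groupby("gene_id", sort=True)
    out = pd.DataFrame(
        {
            "n_studies_measured": g.size(),
            "sum_wlfc": g["wlfc"].sum(),
            "sum_w": g["lfc_weight"].sum(),
            "mean_lfc": g["logFC"].mean(),
            "average_weight": g["weight"].mean(),
        }
    )
    out = out[out["n_studies_measured"] >= cfg.k_min].copy()
    fallback = out["sum_w"] == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out["weighted_logFC"] = np.where(
            fallback, out["mean_lfc"], out["sum_wlfc"] / out["sum_w"].where(out["sum_w"] != 0, 1.0)
        )
    out["combined_p"] = 10.0 ** (-out["average_weight"])
    out["used_fallback"] = fallback
    out["is_differentially_expressed"] = (
        (out["weighted_logFC"].abs() > cfg.logfc_cutoff) & (out["combined_p"] < cfg.p_cutoff)
    )
    out.index.name = "gene_id"
    return out[
        [
            "n_studies_measured",
            "weighted_logFC",
            "average_weight",
            "combined_p",
            "is_differentially_expressed",
            "used_fallback",
        ]
    ]
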