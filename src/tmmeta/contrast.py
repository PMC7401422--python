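"""Responder vs nonresponder fold-change contrast on mean abundances.

From a gene x {A, B, C, D} table of group-mean abundances (A/B:
responders treated/control, C/D: nonresponders treated/control) the
module derives pseudocounted log2 fold changes

    LogFC_R  = log2((A + 1) / (B + 1))
    LogFC_NR = log2((C + 1) / (D + 1))

their difference (the responder-specific contrast) and their mean (the
overall treatment effect). The +1 pseudocount keeps every quantity finite
for zero abundances. No p-values exist on this branch, so changed genes
are called on the fold-change cutoff alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COLUMNS = ("A", "B", "C", "D")


def contrast_table(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Derive the contrast quantities for every gene, preserving order.

    Raises on negative or non-finite abundances, naming the gene and
    column. The pseudocount is part of the definition and should not be
    changed in ordinary use.
    """
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"abundance table lacks columns {missing}")
    vals = table[list(COLUMNS)].to_numpy(dtype=float)
    bad = ~np.isfinite(vals) | (vals < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"negative or non-finite abundance for gene {table.index[i]} column {COLUMNS[j]}"
        )
    a, b, c, d = (vals[:, k] + pseudocount for k in range(4))
    logfc_r = np.log2(a / b)
    logfc_nr = np.log2(c / d)
    out = pd.DataFrame(
        {
            "A": vals[:, 0],
            "B": vals[:, 1],
            "C": vals[:, 2],
            "D": vals[:, 3],
            "logFC_R": logfc_r,
            "logFC_NR": logfc_nr,
            "diff_R_minus_NR": logfc_r - logfc_nr,
            "mean_effect": (logfc_r + logfc_nr) / 2.0,
        },
        index=table.index.copy(),
    )
    out.index.name = "gene_id"
    return out


def call_changed_genes(records: pd.DataFrame, which: str = "diff", logfc_cutoff: float = 0.58):
    """Split genes into up/down sets on the chosen contrast (strict cutoff).

    ``which='diff'`` targets the responder-vs-nonresponder difference,
    ``which='mean'`` the overall treatment effect.
    """
    if logfc_cutoff <= 0:
        raise ValueError("logfc_cutoff must be positive")
    col = {"diff": "diff_R_minus_NR", "mean": "mean_effect"}.get(which)
    if col is None:
        raise ValueError("which must be 'diff' or 'mean'")
    v = records[col]
    up = set(records.index[v > logfc_cutoff])
    down = set(records.index[v < -logfc_cutoff])
    return up, down
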