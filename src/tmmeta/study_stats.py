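"""Per-study differential statistics: replicate averaging, (moderated)
t-tests, probe-to-gene mapping and deduplication.

The contrast is always treated minus control on the log2 scale. Variance
moderation follows the empirical-Bayes scheme used for small expression
studies: per-probe sample variances are shrunk toward a prior variance
``s0^2`` with prior degrees of freedom ``d0``, both estimated by moment
matching on the distribution of log sample variances; the moderated t
statistic is referred to a t distribution with ``d0 + d`` degrees of
freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .normalize import ExpressionMatrix

log = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps -log10 p weights finite


@dataclass
class ModerationFit:
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance


def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate arrays to one column per (individual, condition).

    Every individual gets the same weight downstream regardless of how
    many times it was arrayed. Individuals missing either the treated or
    the control arm are excluded with a logged warning.
    """
    meta = m.metadata.loc[m.values.columns]
    groups = meta.groupby(["individual", "condition"], sort=True).groups
    by_ind: dict = {}
    for (ind, cond), samples in groups.items():
        by_ind.setdefault(ind, {})[cond] = list(samples)
    cols, new_meta = [], []
    for ind in sorted(by_ind):
        conds = by_ind[ind]
        if not {"treated", "control"} <= set(conds):
            log.warning(
                "individual %s lacks a %s arm; excluded from statistics",
                ind,
                ({"treated", "control"} - set(conds)).pop(),
            )
            continue
        for cond in ("treated", "control"):
            sid = f"{ind}:{cond}"
            cols.append((sid, m.values[conds[cond]].mean(axis=1)))
            new_meta.append((sid, ind, cond, 1))
    values = pd.DataFrame({sid: col for sid, col in cols})
    values.index = m.values.index
    metadata = pd.DataFrame(
        new_meta, columns=["sample_id", "individual", "condition", "replicate"]
    ).set_index("sample_id")
    return ExpressionMatrix(values, metadata, study_id=m.study_id)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s_sq: np.ndarray, d: float) -> ModerationFit:
    """Moment-matching fit of (d0, s0^2) on log sample variances.

    Under the scaled-chi-square model, z = log(s^2) has
    E[z] = log(s0^2) + psi(d/2) - log(d/2) - (psi(d0/2) - log(d0/2)) and
    Var[z] = psi'(d/2) + psi'(d0/2); both moments are matched empirically.
    """
    ok = s_sq > 0
    if ok.sum() < 2:
        return ModerationFit(d0=np.inf, s0_sq=float(np.median(s_sq[ok])) if ok.any() else 0.0)
    z = np.log(s_sq[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    ev = float(np.var(z, ddof=1) - special.polygamma(1, d / 2.0))
    if ev <= 0:
        return ModerationFit(d0=np.inf, s0_sq=float(np.exp(np.mean(e))))
    half_d0 = _trigamma_inverse(ev)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationFit(d0=d0, s0_sq=s0_sq)


def differential_stats(
    m: ExpressionMatrix, moderate: bool = True, paired: bool = False
) -> pd.DataFrame:
    """Treated-vs-control statistics per probe.

    Returns a DataFrame indexed by probe_id with columns ``logFC``,
    ``t_stat``, ``p_value``, ``mean_expression`` and ``flag``. logFC is
    mean(treated) - mean(control). With too few residual degrees of
    freedom the p-value is reported as 1 with flag ``no_residual_df``
    rather than NaN, so such probes carry zero weight downstream.

    ``paired=True`` runs a one-sample test on per-individual
    treated-minus-control differences (for paired-eye designs).
    """
    meta = m.metadata.loc[m.values.columns]
    tr = list(meta.index[meta["condition"] == "treated"])
    ct = list(meta.index[meta["condition"] == "control"])
    if not tr or not ct:
        raise ValueError("need at least one treated and one control column")
    vals = m.values
    mean_expr = vals[tr + ct].mean(axis=1).to_numpy()

    if paired:
        inds = sorted(set(meta.loc[tr, "individual"]) & set(meta.loc[ct, "individual"]))
        diffs = []
        for ind in inds:
            t_cols = meta.index[(meta["individual"] == ind) & (meta["condition"] == "treated")]
            c_cols = meta.index[(meta["individual"] == ind) & (meta["condition"] == "control")]
            diffs.append(vals[list(t_cols)].mean(axis=1) - vals[list(c_cols)].mean(axis=1))
        dmat = pd.concat(diffs, axis=1).to_numpy()
        logfc = dmat.mean(axis=1)
        n = dmat.shape[1]
        d = n - 1
        s_sq = dmat.var(axis=1, ddof=1) if d >= 1 else np.zeros(len(logfc))
        se_unit = 1.0 / n
    else:
        t_arr = vals[tr].to_numpy()
        c_arr = vals[ct].to_numpy()
        n1, n2 = len(tr), len(ct)
        logfc = t_arr.mean(axis=1) - c_arr.mean(axis=1)
        d = n1 + n2 - 2
        if d >= 1:
            ss = np.zeros(len(logfc))
            if n1 > 1:
                ss += t_arr.var(axis=1, ddof=1) * (n1 - 1)
            if n2 > 1:
                ss += c_arr.var(axis=1, ddof=1) * (n2 - 1)
            s_sq = ss / d
        else:
            s_sq = np.zeros(len(logfc))
        se_unit = 1.0 / n1 + 1.0 / n2

    flags = np.array([""] * len(logfc), dtype=object)
    if d < 1:
        t_stat = np.zeros(len(logfc))
        p = np.ones(len(logfc))
        flags[:] = "no_residual_df"
    else:
        if moderate:
            fit = fit_variance_prior(np.asarray(s_sq), d)
            if np.isinf(fit.d0):
                post = np.full(len(logfc), fit.s0_sq)
                df_total = 1e6
            else:
                post = (fit.d0 * fit.s0_sq + d * s_sq) / (fit.d0 + d)
                df_total = fit.d0 + d
        else:
            post = np.asarray(s_sq, dtype=float)
            df_total = d
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(post * se_unit)
            t_stat = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * stats.t.sf(np.abs(t_stat), df=min(df_total, 1e6))
        zero_var = ~(np.asarray(post) > 0)
        if zero_var.any():
            # no variance estimate: t undefined; weightless by construction
            t_stat = np.where(zero_var, 0.0, t_stat)
            p = np.where(zero_var, 1.0, p)
            flags[zero_var] = "zero_variance"
        if d < 2 and not moderate:
            p = np.ones(len(logfc))
            t_stat = np.zeros(len(logfc))
            flags[:] = "no_residual_df"
    p = np.clip(p, P_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "t_stat": t_stat,
            "p_value": p,
            "mean_expression": mean_expr,
            "flag": flags,
        },
        index=vals.index.copy(),
    )


def map_and_deduplicate(
    stats_df: pd.DataFrame,
    probe_map: pd.DataFrame,
    study_id: str = "",
    n_individuals: int = 0,
):
    """Convert probe-level stats to one record per gene.

    Probes are joined to genes via ``probe_map`` (columns ``probe_id``,
    ``gene_id``); when several probes measure one gene, the record with the
    highest |logFC x -log10(p)| is kept — the strongest combined change.
    Exact score ties keep the lexicographically smallest probe_id.

    Returns ``(gene_df, summary)`` where summary counts unmapped probes.
    """
    df = stats_df.reset_index().rename(columns={stats_df.index.name or "index": "probe_id"})
    merged = df.merge(probe_map[["probe_id", "gene_id"]], on="probe_id", how="left")
    unmapped = int(merged["gene_id"].isna().sum())
    if unmapped:
        log.warning("%d probes had no gene mapping and were dropped", unmapped)
    merged = merged.dropna(subset=["gene_id"]).copy()
    merged["dedup_score"] = (merged["logFC"] * -np.log10(merged["p_value"])).abs()
    merged = merged.sort_values(
        ["gene_id", "dedup_score", "probe_id"], ascending=[True, False, True], kind="stable"
    )
    kept = merged.drop_duplicates("gene_id", keep="first").copy()
    kept["study_id"] = study_id
    kept["n_individuals"] = n_individuals
    cols = [
        "study_id", "gene_id", "probe_id", "logFC", "p_value",
        "t_stat", "mean_expression", "n_individuals", "dedup_score",
    ]
    summary = {"n_probes": len(stats_df), "n_unmapped": unmapped, "n_genes": len(kept)}
    return kept[cols].reset_index(drop=True), summary
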