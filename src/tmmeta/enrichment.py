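"""Pathway overrepresentation: GMT handling, Z-scores, permutation p-values.

For a universe of N measured genes of which R are changed, a pathway
covering n universe genes with r of them changed is scored

    z = (r - n*R/N) / sqrt( n * (R/N) * (1 - R/N) * (1 - (n-1)/(N-1)) )

the standardized excess of changed genes under the hypergeometric
(sampling without replacement) null. Permutation p-values reshuffle the
changed-gene labels across the universe, preserving R and every pathway
size, with add-one smoothing so p is never exactly zero. A pathway is
called significantly changed when z >= 1.96, permuted p < 0.05 and more
than 3 of its genes are changed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Z_CUTOFF = 1.96
PERM_P_CUTOFF = 0.05
MIN_CHANGED = 3  # significance requires r > 3


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    source: str
    genes: frozenset


@dataclass
class PathwayCollection:
    """A merged set of pathways from one or more GMT sources."""

    pathways: list = field(default_factory=list)

    def __post_init__(self):
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate pathway ids in collection")
        for p in self.pathways:
            if not p.genes:
                raise ValueError(f"pathway {p.pathway_id} has an empty gene set")

    def __len__(self):
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def gene_sets(self) -> dict:
        return {p.pathway_id: p.genes for p in self.pathways}


def read_gmt(path, source: str = "") -> PathwayCollection:
    """Read a GMT file (set name, description, member genes per line).

    Duplicate genes within a line are collapsed; lines with fewer than
    three fields raise with the offending line number.
    """
    pathways = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has {len(fields)} fields, need >=3")
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            pathways.append(Pathway(name, desc, source, genes))
    if not pathways:
        log.warning("GMT file %s contained no pathways", path)
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.genes)]) + "\n")


def merge_collections(*collections: PathwayCollection) -> PathwayCollection:
    """Combine collections; on id collision the source tag is prepended."""
    seen: dict = {}
    for coll in collections:
        for p in coll:
            pid = p.pathway_id
            if pid in seen:
                pid = f"{p.source}:{p.pathway_id}" if p.source else f"dup:{p.pathway_id}"
            if pid in seen:
                raise ValueError(f"unresolvable pathway id collision: {p.pathway_id}")
            seen[pid] = Pathway(pid, p.name, p.source, p.genes)
    return PathwayCollection(list(seen.values()))


def zscore(N: int, R: int, n: int, r: int) -> float:
    """Overrepresentation Z with finite-population variance correction.

    Equals (r - mean) / sd of the hypergeometric(N, R, n) distribution.
    Returns 0.0 when the null variance is zero (R=0, R=N or n=N=1-like
    degenerate cases); callers treat that as 'no evidence'.
    """
    if not (0 < n <= N):
        raise ValueError(f"need 0 < n <= N, got n={n}, N={N}")
    if not (0 <= R <= N):
        raise ValueError(f"need 0 <= R <= N, got R={R}, N={N}")
    if not (0 <= r <= min(n, R)):
        raise ValueError(f"need 0 <= r <= min(n, R), got r={r}, n={n}, R={R}")
    if N < 2:
        raise ValueError("N must be >= 2")
    frac = R / N
    var = n * frac * (1.0 - frac) * (1.0 - (n - 1) / (N - 1))
    if var <= 0:
        return 0.0
    return float((r - n * frac) / math.sqrt(var))


def _pathway_counts(changed: set, universe_list: list, collection: PathwayCollection):
    """Per-pathway (n, r) restricted to the universe; n=0 pathways dropped."""
    uni = set(universe_list)
    rows = []
    for p in collection:
        members = p.genes & uni
        if not members:
            log.warning("pathway %s shares no genes with the universe; excluded", p.pathway_id)
            continue
        rows.append((p, members, len(members), len(members & changed)))
    return rows


def permutation_pvalues(
    changed: set, universe, collection: PathwayCollection, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Permutation p-value per pathway under label reshuffling.

    Changed-gene labels are permuted across the universe (R and every n
    are preserved); p = (1 + #{z* >= z_obs}) / (n_perm + 1). Because N, R
    and n are fixed under permutation, z* >= z_obs exactly when
    r* >= r_obs, which is how the tail count is evaluated.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe_list = sorted(universe)
    rows = _pathway_counts(set(changed), universe_list, collection)
    if not rows:
        return {}
    N = len(universe_list)
    idx = {g: i for i, g in enumerate(universe_list)}
    member_matrix = np.zeros((len(rows), N), dtype=np.float32)
    for k, (_, members, _, _) in enumerate(rows):
        member_matrix[k, [idx[g] for g in members]] = 1.0

    base = np.zeros(N, dtype=np.float32)
    base[[idx[g] for g in changed]] = 1.0
    rng = np.random.default_rng(seed)
    perms = np.empty((N, n_perm), dtype=np.float32)
    for b in range(n_perm):
        perms[:, b] = base[rng.permutation(N)]
    r_null = member_matrix @ perms  # pathways x permutations

    pvals = {}
    for k, (p, _, _, r_obs) in enumerate(rows):
        exceed = int((r_null[k] >= r_obs - 1e-9).sum())
        pvals[p.pathway_id] = (1 + exceed) / (n_perm + 1)
    return pvals


def run_enrichment(
    changed,
    universe,
    collection: PathwayCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every pathway against the changed/universe gene sets.

    Returns a DataFrame sorted by z descending with columns N, R, n, r,
    z_score, permuted_p, bh_q and significant (the three-part rule:
    z >= 1.96, permuted p < 0.05, r > 3). A Benjamini-Hochberg column is
    reported for transparency but does not affect the significance flag.
    """
    changed, universe = set(changed), set(universe)
    stray = changed - universe
    if stray:
        raise ValueError(f"changed genes outside the universe: {sorted(stray)[:10]}")
    universe_list = sorted(universe)
    N, R = len(universe_list), len(changed)
    rows = _pathway_counts(changed, universe_list, collection)
    pvals = permutation_pvalues(changed, universe_list, collection, n_perm=n_perm, seed=seed)

    recs = []
    for p, _, n, r in rows:
        z = zscore(N, R, n, r)
        pp = pvals[p.pathway_id]
        recs.append(
            {
                "pathway_id": p.pathway_id,
                "name": p.name,
                "N": N,
                "R": R,
                "n": n,
                "r": r,
                "z_score": z,
                "permuted_p": pp,
                "significant": (z >= Z_CUTOFF) and (pp < PERM_P_CUTOFF) and (r > MIN_CHANGED),
            }
        )
    df = pd.DataFrame(recs)
    if df.empty:
        return df
    # Benjamini-Hochberg on the permutation p-values, informational only
    m = len(df)
    order = np.argsort(df["permuted_p"].to_numpy(), kind="stable")
    ranked = df["permuted_p"].to_numpy()[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    bh = np.empty(m)
    bh[order] = np.minimum(q, 1.0)
    df["bh_q"] = bh
    df = df.sort_values(["z_score", "pathway_id"], ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)
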