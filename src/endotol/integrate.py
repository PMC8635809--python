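"""Methylation-expression integration.

Differentially methylated CpGs are linked to genes by nearest TSS (signed,
strand-aware distance; negative = upstream of the TSS on the gene strand).
Delta-beta is then correlated with expression log fold change (Pearson),
and genes associated with hypomethylated CpGs are classified into temporal
clusters by hierarchical clustering of standardized time-course profiles.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import GenomicInterval

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# nearest TSS

def nearest_tss(
    cpgs: Sequence[GenomicInterval],
    tss: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Assign each CpG to the gene whose TSS is nearest in absolute distance.

    TSS intervals are 1-bp positions with strand and gene id in ``name``.
    Ties in |distance| are broken by the lexicographically smaller gene id.
    The signed distance is (cpg - tss) for + strand genes and (tss - cpg)
    for - strand genes, so negative means upstream of the TSS. CpGs on
    chromosomes with no TSS are omitted with a log entry.
    """
    if not len(tss):
        raise ValueError("TSS table is empty")
    by_chrom: dict[str, pd.DataFrame] = {}
    rows = []
    for t in tss:
        rows.append((t.chrom, t.start, t.name, t.strand))
    tss_frame = pd.DataFrame(rows, columns=["chrom", "pos", "gene", "strand"])
    for chrom, grp in tss_frame.groupby("chrom"):
        by_chrom[chrom] = grp.sort_values(["pos", "gene"]).reset_index(drop=True)

    out = []
    n_unassigned = 0
    for c in cpgs:
        grp = by_chrom.get(c.chrom)
        if grp is None:
            n_unassigned += 1
            continue
        pos = grp["pos"].to_numpy()
        p = c.start
        i = np.searchsorted(pos, p)
        best = np.inf
        if i > 0:
            best = min(best, abs(p - pos[i - 1]))
        if i < len(pos):
            best = min(best, abs(pos[i] - p))
        # all TSS at exactly |best| from p sit at p-best and/or p+best
        candidates = []
        for target in {p - best, p + best}:
            lo = np.searchsorted(pos, target, side="left")
            hi = np.searchsorted(pos, target, side="right")
            for j in range(lo, hi):
                candidates.append(j)
        j = min(candidates, key=lambda j: grp["gene"].iloc[j])
        tss_pos = int(grp["pos"].iloc[j])
        strand = grp["strand"].iloc[j]
        signed = (p - tss_pos) if strand != "-" else (tss_pos - p)
        out.append(
            {
                "cpg": c.name,
                "chrom": c.chrom,
                "cpg_pos": p,
                "gene": grp["gene"].iloc[j],
                "tss_pos": tss_pos,
                "strand": strand,
                "distance": int(signed),
            }
        )
    if n_unassigned:
        log.info("%d CpGs on chromosomes without TSS left unassigned", n_unassigned)
    return pd.DataFrame(out)


def dedup_by_gene(assign: pd.DataFrame) -> pd.DataFrame:
    """Keep one CpG per gene: the closest by |distance| (ties: smaller CpG id)."""
    frame = assign.copy()
    frame["_absd"] = frame["distance"].abs()
    frame = frame.sort_values(["gene", "_absd", "cpg"], kind="stable")
    return frame.drop_duplicates("gene", keep="first").drop(columns="_absd").reset_index(drop=True)


# ---------------------------------------------------------------------------
# correlation

def meth_expr_correlation(
    dmps: pd.DataFrame,
    de: pd.DataFrame,
    assign: pd.DataFrame,
    per_gene: bool = True,
) -> dict:
    """Pearson correlation of delta-beta against expression log fold change.

    Pairs are CpG-gene links from ``assign`` whose CpG is in ``dmps`` and
    whose gene is in ``de``. With ``per_gene`` (default) duplicate genes are
    removed first, keeping the closest CpG. Returns n, r, p and the paired
    table. Requires n >= 3 and nonzero variance in both variables.
    """
    links = assign.loc[assign["cpg"].isin(dmps.index) & assign["gene"].isin(de.index)]
    if per_gene:
        links = dedup_by_gene(links)
    pairs = pd.DataFrame(
        {
            "cpg": links["cpg"].to_numpy(),
            "gene": links["gene"].to_numpy(),
            "delta_beta": dmps["delta_beta"].reindex(links["cpg"]).to_numpy(),
            "log_fc": de["log_fc"].reindex(links["gene"]).to_numpy(),
        }
    )
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >=3 CpG-gene pairs, got {n}")
    x, y = pairs["delta_beta"].to_numpy(), pairs["log_fc"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in delta-beta or log-fold-change")
    r, p = stats.pearsonr(x, y)
    return {"n": n, "r": float(r), "p": float(p), "pairs": pairs}


# ---------------------------------------------------------------------------
# time-course clustering

def hier_cluster_timecourse(expr: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Hierarchical clustering of standardized time-course profiles.

    Rows (genes) are standardized to mean 0 / sd 1, clustered with complete
    linkage on Euclidean distance, and the tree is cut into ``k`` clusters.
    Constant rows cannot be standardized and are dropped with a warning.
    Cluster labels C1..Ck are ordered by the cluster mean of the
    standardized final timepoint, descending, so labels are deterministic.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >=2 timepoints")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d constant rows", int((~keep).sum()))
    vals = vals[keep]
    index = expr.index[keep]
    if len(vals) < k:
        raise ValueError(f"need >={k} non-constant genes, got {len(vals)}")
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=0, keepdims=True)
    linkage = hierarchy.linkage(pdist(z, metric="euclidean"), method="complete")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    final = pd.Series(z[:, -1], index=index)
    means = final.groupby(raw).mean().sort_values(ascending=False)
    relabel = {old: f"C{i + 1}" for i, old in enumerate(means.index)}
    out = pd.DataFrame({"cluster": [relabel[r] for r in raw]}, index=index)
    out.attrs["linkage"] = linkage
    out.attrs["k"] = k
    return out
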