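"""Tolerization scoring of LPS re-stimulation time courses.

Endotoxin-tolerized genes respond less to a second LPS stimulus in cells
pre-exposed to LPS than in naive cells. On log2 expression the score is

    score = (Untreated_reexposure - Untreated) - (LPS_reexposure - LPS)

so a positive score marks a tolerized gene (blunted induction in the
pre-exposed arm) and a negative score a non-tolerized one. Top-N sets of
the highest- and lowest-scoring genes feed the GSEA stage.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .core import GeneSetCollection

CONDITIONS = ("untreated", "untreated_reexposure", "lps", "lps_reexposure")


def tolerization_scores(
    expr: pd.DataFrame,
    conditions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene tolerization score from a 4-condition log2 expression table.

    ``expr`` is genes x columns. If ``conditions`` is given it maps each
    column to one of the four canonical condition labels (replicate columns
    are averaged per condition); otherwise the columns must be exactly the
    canonical labels. Returns per-condition means plus ``score``.
    """
    if conditions is None:
        conditions = {c: c for c in expr.columns}
    means = {}
    for label in CONDITIONS:
        cols = [c for c, lab in conditions.items() if lab == label]
        if not cols:
            raise ValueError(f"missing condition column: {label!r}")
        missing = [c for c in cols if c not in expr.columns]
        if missing:
            raise ValueError(f"columns {missing} not in expression table")
        means[label] = expr[cols].mean(axis=1)
    table = pd.DataFrame(means, index=expr.index)
    if not np.isfinite(table.to_numpy()).all():
        raise ValueError("non-finite expression values")
    u, u_re, l, l_re = (table[c] for c in CONDITIONS)
    table["score"] = (u_re - u) - (l_re - l)
    return table


def top_n_sets(table: pd.DataFrame, n: int = 100) -> GeneSetCollection:
    """Top-N tolerized (highest score) and non-tolerized (lowest) gene sets.

    Boundary ties are broken by gene id for determinism. The two sets are
    disjoint, which requires 2n <= number of genes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_genes = len(table)
    if n > n_genes:
        raise ValueError(f"n={n} exceeds {n_genes} genes")
    if 2 * n > n_genes:
        raise ValueError(f"2n={2 * n} exceeds {n_genes} genes; sets would overlap")
    frame = pd.DataFrame({"score": table["score"].to_numpy(), "gene": table.index.astype(str)})
    top = frame.sort_values(["score", "gene"], ascending=[False, True], kind="stable").head(n)
    bottom = frame.sort_values(["score", "gene"], ascending=[True, True], kind="stable").head(n)
    return GeneSetCollection(
        {
            f"top{n}_tolerized": list(top["gene"]),
            f"top{n}_non_tolerized": list(bottom["gene"]),
        },
        {
            f"top{n}_tolerized": f"{n} genes with highest tolerization scores",
            f"top{n}_non_tolerized": f"{n} genes with lowest tolerization scores",
        },
    )
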