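"""Differential expression surrogate and GSEA ranking construction.

Counts are normalized by median-of-ratios size factors, log2-transformed
with a +0.5 offset, and tested with the same moderated linear model used
for methylation (donor as covariate). This is a documented divergence from
negative-binomial Wald testing: the moderated-t route shares machinery with
the methylation stage and its operating characteristics (recovery, FDR
control) are validated on synthetic negative-binomial data.

Genes are ranked for GSEA by -log10(q) * sign(logFC), with q floored at
the smallest positive q observed divided by 10 so the score is defined
everywhere, and deterministic tie-breaking (larger |logFC|, then gene id).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .core import SampleSheet
from .methylation import Design, bh_fdr, build_design, fit_probe_models, moderate_variances

log = logging.getLogger(__name__)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, normalized to geometric mean 1.

    Only genes with nonzero counts in every sample contribute; the factor for
    sample j is the median over those genes of count_gj / geometric-mean_g.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = mat[expressed]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    factors = factors / _stats.gmean(factors)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def log_cpm_display(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(normalized + 1) display transform (in place of a VST)."""
    return np.log2(normalized_counts(counts) + 1.0)


def de_moderated(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    treated: str,
    reference: str,
    donor_col: str | None = "donor",
    biotype: pd.Series | None = None,
    min_mean_count: float = 10.0,
) -> pd.DataFrame:
    """Moderated-t differential expression on log2(normalized count + 0.5).

    Returns a frame with log_fc (log2 units, treated vs reference), p, q,
    mean_expr (mean log2 normalized), and a ``coding`` flag taken from
    ``biotype`` (gene id -> biotype string; 'protein_coding' marks coding;
    absent means all genes are treated as coding).

    Genes with mean normalized count below ``min_mean_count`` are filtered
    before testing (independent filtering): without a mean-variance trend
    the moderated model overstates significance for near-zero counts, and
    low-count filtering is the standard guard.
    """
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")
    design = build_design(sheet, treated, reference, donor_col=donor_col)
    sub = counts[design.samples]
    nonzero = (sub.sum(axis=1) > 0)
    dropped = int((~nonzero).sum())
    if dropped:
        log.info("dropping %d all-zero genes", dropped)
    sub = sub.loc[nonzero]
    factors = size_factors(sub)
    if min_mean_count > 0:
        expressed = (sub / factors).mean(axis=1) >= min_mean_count
        log.info("independent filtering kept %d of %d genes", int(expressed.sum()), len(sub))
        sub = sub.loc[expressed]
    logn = np.log2(sub / factors + 0.5)
    fit = fit_probe_models(logn, design)
    mod = moderate_variances(
        fit["coef"].to_numpy(), fit["s2"].to_numpy(), float(fit["df"].iloc[0]), fit.attrs["se_unit"]
    )
    out = pd.DataFrame(
        {
            "log_fc": fit["coef"],
            "p": mod.p,
            "q": bh_fdr(mod.p),
            "mean_expr": logn.mean(axis=1),
        },
        index=sub.index,
    )
    if biotype is not None:
        out["coding"] = biotype.reindex(out.index).eq("protein_coding").fillna(False)
    else:
        out["coding"] = True
    out.attrs["treated"] = treated
    out.attrs["reference"] = reference
    out.attrs["d0"] = mod.d0
    return out


def call_degs(
    de: pd.DataFrame,
    lfc: float = 1.0,
    fdr: float = 0.05,
    coding_only: bool = True,
) -> pd.DataFrame:
    """Differentially expressed genes: |logFC| > lfc and q < fdr (strict)."""
    if lfc <= 0 or fdr <= 0:
        raise ValueError("thresholds must be positive")
    keep = (de["log_fc"].abs() > lfc) & (de["q"] < fdr)
    if coding_only and "coding" in de.columns:
        keep &= de["coding"].astype(bool)
    degs = de.loc[keep].copy()
    degs["direction"] = np.where(degs["log_fc"] > 0, "up", "down")
    degs.attrs["n_up"] = int((degs["direction"] == "up").sum())
    degs.attrs["n_down"] = int((degs["direction"] == "down").sum())
    return degs


def build_ranked_list(de: pd.DataFrame, q_col: str = "q", lfc_col: str = "log_fc") -> pd.Series:
    """Rank genes by -log10(q) * sign(logFC), descending.

    q values of 0 (or denormal) are floored at min(positive q)/10. Ties are
    broken by larger |logFC|, then lexicographic gene id, so the output
    order is a deterministic total order.
    """
    if de.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    q = de[q_col].to_numpy(dtype=float)
    lfc = de[lfc_col].to_numpy(dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q values must lie in [0, 1]")
    positive = q[q > 1e-300]
    floor = (positive.min() / 10.0) if len(positive) else 1e-300
    q = np.maximum(q, floor)
    score = -np.log10(q) * np.sign(lfc)
    order = pd.DataFrame(
        {"score": score, "abs_lfc": np.abs(lfc), "gene": de.index.astype(str)}
    ).sort_values(
        ["score", "abs_lfc", "gene"], ascending=[False, False, True], kind="stable"
    )
    ranked = pd.Series(order["score"].to_numpy(), index=order["gene"].to_numpy(), name="score")
    return ranked
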