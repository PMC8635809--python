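"""Differential methylation on M-values.

Beta values (fraction methylated, in [0,1]) are logit2-transformed to
M-values, which are approximately homoscedastic and suit linear modelling.
Each probe is fit by ordinary least squares against a design with an
intercept, a condition contrast and donor indicator columns (paired design).
Residual variances are shrunk by the standard empirical-Bayes scheme

    s~2_g = (d0 * s0^2 + d * s2_g) / (d0 + d)

with the prior (d0, s0^2) estimated by method of moments on log s2
(digamma/trigamma matching against a scaled-F model), and the moderated
t-statistic referred to a t distribution with d0 + d degrees of freedom.
DMPs are probes with BH-adjusted p below the FDR threshold and an absolute
mean beta difference above the delta threshold; delta-beta is computed on
raw (uncorrected) betas, treated minus reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import SampleSheet

log = logging.getLogger(__name__)

DEFAULT_CLIP = 1e-6


# ---------------------------------------------------------------------------
# beta <-> M

def beta_to_m(beta, clip: float = DEFAULT_CLIP):
    """M = log2(beta / (1 - beta)) with beta clipped to [clip, 1 - clip]."""
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, clip, 1.0 - clip)
    out = np.log2(clipped / (1.0 - clipped))
    if np.isscalar(beta):
        return float(out)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    if np.isscalar(m):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# design matrices

@dataclass
class Design:
    """Design matrix aligned to a sample subset, with the tested contrast.

    Columns: intercept, condition indicator (1 for the treated condition),
    then donor indicator columns (first donor as baseline).
    """

    matrix: np.ndarray
    columns: list[str]
    samples: list[str]
    contrast_index: int
    donor_indices: list[int]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def validate(self) -> None:
        n, p = self.matrix.shape
        if self.rank < p:
            raise ValueError("design matrix is rank deficient")
        if n <= p:
            raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")


def build_design(
    sheet: SampleSheet,
    treated: str,
    reference: str,
    donor_col: str | None = "donor",
) -> Design:
    """Intercept + treated indicator (+ donor dummies) for a two-group contrast."""
    sub = sheet.subset([treated, reference])
    frame = sub.frame
    cond = frame["condition"].to_numpy()
    for label in (treated, reference):
        if (cond == label).sum() < 2:
            raise ValueError(f"need >=2 samples in condition {label!r}")
    cols = [np.ones(len(frame)), (cond == treated).astype(float)]
    names = ["intercept", f"{treated}_vs_{reference}"]
    donor_idx: list[int] = []
    if donor_col is not None:
        donors = frame[donor_col].astype(str).to_numpy()
        levels = sorted(set(donors))
        for lev in levels[1:]:
            donor_idx.append(len(names))
            cols.append((donors == lev).astype(float))
            names.append(f"donor_{lev}")
    design = Design(
        matrix=np.column_stack(cols),
        columns=names,
        samples=sub.samples,
        contrast_index=1,
        donor_indices=donor_idx,
    )
    design.validate()
    return design


# ---------------------------------------------------------------------------
# per-probe OLS

def fit_probe_models(m: pd.DataFrame, design: Design) -> pd.DataFrame:
    """OLS per probe: contrast coefficient, residual variance and df.

    Returns a frame indexed by probe with columns ``coef`` (M-value units),
    ``s2`` (residual mean square), ``df`` (n - rank) and ``se_unit``
    (sqrt of the contrast diagonal of (X'X)^-1, shared across probes).
    """
    design.validate()
    X = design.matrix
    Y = m[design.samples].to_numpy(dtype=float)
    n, p = X.shape
    rank = design.rank
    d = n - rank
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = Y @ (xtx_inv @ X.T).T          # probes x p
    resid = Y - coefs @ X.T
    s2 = (resid**2).sum(axis=1) / d
    se_unit = float(np.sqrt(xtx_inv[design.contrast_index, design.contrast_index]))
    out = pd.DataFrame(
        {
            "coef": coefs[:, design.contrast_index],
            "s2": s2,
            "df": float(d),
        },
        index=m.index,
    )
    out.attrs["se_unit"] = se_unit
    out.attrs["coef_all"] = coefs
    out.attrs["columns"] = design.columns
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes moderation

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    lo, hi = 1e-8, 1e8
    t_lo = special.polygamma(1, lo)
    t_hi = special.polygamma(1, hi)
    if y >= t_lo:
        return lo
    if y <= t_hi:
        return hi
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi, xtol=1e-12))


@dataclass
class ModeratedStats:
    d0: float
    s02: float
    s2_tilde: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_total: float


def moderate_variances(
    coef: np.ndarray,
    s2: np.ndarray,
    d: float,
    se_unit: float,
) -> ModeratedStats:
    """Shrink per-probe variances toward a common prior and compute moderated t.

    The prior degrees of freedom d0 and prior variance s0^2 are estimated by
    matching the mean and variance of log s2 under the scaled-F model
    s2 ~ s0^2 * F(d, d0): Var(log s2) = trigamma(d/2) + trigamma(d0/2).
    When the empirical variance of log s2 does not exceed trigamma(d/2) the
    prior is degenerate (d0 = inf) and every probe gets the pooled variance.
    """
    s2 = np.asarray(s2, dtype=float)
    coef = np.asarray(coef, dtype=float)
    if len(s2) < 10:
        raise ValueError("need >=10 probes to estimate the variance prior")
    if d < 1:
        raise ValueError("need at least 1 residual degree of freedom")
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero (degenerate data)")
    # guard exact zeros before taking logs; they carry no variance information
    floor = s2[s2 > 0].min() * 1e-12
    z = np.log(np.maximum(s2, floor))
    e_var = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2))
    mean_z = float(np.mean(z))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        log_s02 = (
            mean_z
            - special.psi(d / 2)
            + np.log(d / 2)
            + special.psi(d0 / 2)
            - np.log(d0 / 2)
        )
        s02 = float(np.exp(log_s02))
        s2_tilde = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    else:
        d0 = np.inf
        s02 = float(np.exp(mean_z - special.psi(d / 2) + np.log(d / 2)))
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    t = coef / (np.sqrt(s2_tilde) * se_unit)
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    return ModeratedStats(float(d0), s02, s2_tilde, t, p, float(df_total))


# ---------------------------------------------------------------------------
# BH FDR

def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.isnan(p).any():
        raise ValueError("p vector contains NaN")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# full probe-level pipeline

def probe_statistics(
    betas: pd.DataFrame,
    sheet: SampleSheet,
    treated: str,
    reference: str,
    donor_col: str | None = "donor",
    clip: float = DEFAULT_CLIP,
) -> pd.DataFrame:
    """beta -> M -> per-probe OLS -> moderation -> BH, plus delta-beta.

    Probes with any missing beta are dropped before modelling (no imputation).
    Delta-beta is mean beta(treated) - mean beta(reference) on raw betas.
    """
    design = build_design(sheet, treated, reference, donor_col=donor_col)
    sub = betas[design.samples]
    complete = sub.notna().all(axis=1)
    if not complete.all():
        log.info("dropping %d probes with missing betas", int((~complete).sum()))
    sub = sub.loc[complete]
    m = pd.DataFrame(beta_to_m(sub.to_numpy(float), clip=clip), index=sub.index, columns=sub.columns)
    fit = fit_probe_models(m, design)
    mod = moderate_variances(
        fit["coef"].to_numpy(), fit["s2"].to_numpy(), float(fit["df"].iloc[0]), fit.attrs["se_unit"]
    )
    cond = np.array([sheet.frame.set_index("sample").loc[s, "condition"] for s in design.samples])
    vals = sub.to_numpy(float)
    delta = vals[:, cond == treated].mean(axis=1) - vals[:, cond == reference].mean(axis=1)
    out = pd.DataFrame(
        {
            "coef": fit["coef"],
            "s2": fit["s2"],
            "df": fit["df"],
            "s2_tilde": mod.s2_tilde,
            "t_mod": mod.t,
            "p": mod.p,
            "q": bh_fdr(mod.p),
            "delta_beta": delta,
        },
        index=sub.index,
    )
    out.attrs["d0"] = mod.d0
    out.attrs["s02"] = mod.s02
    out.attrs["treated"] = treated
    out.attrs["reference"] = reference
    return out


def call_dmps(
    stats_table: pd.DataFrame,
    fdr: float = 0.05,
    delta: float = 0.2,
) -> pd.DataFrame:
    """Select probes with q < fdr and |delta_beta| > delta (strict inequalities).

    Direction is relative to the treated condition: hypo iff delta_beta < 0.
    The hypo/hyper counts are stored in ``.attrs``.
    """
    if not (0 < fdr <= 1):
        raise ValueError("fdr threshold must lie in (0, 1]")
    if not (0 < delta < 1):
        raise ValueError("delta threshold must lie in (0, 1)")
    keep = (stats_table["q"] < fdr) & (stats_table["delta_beta"].abs() > delta)
    dmps = stats_table.loc[keep].copy()
    dmps["direction"] = np.where(dmps["delta_beta"] < 0, "hypo", "hyper")
    dmps.attrs["n_hypo"] = int((dmps["direction"] == "hypo").sum())
    dmps.attrs["n_hyper"] = int((dmps["direction"] == "hyper").sum())
    dmps.attrs.update({k: v for k, v in stats_table.attrs.items() if k in ("treated", "reference")})
    return dmps


def remove_covariate_effects(
    m: pd.DataFrame,
    design: Design,
    clip: float = DEFAULT_CLIP,
) -> pd.DataFrame:
    """Subtract fitted donor contributions on the M scale; return corrected betas.

    Intended for display: group structure is retained (intercept and condition
    columns are kept), donor columns are regressed out. The donor columns are
    centered before subtraction (sum-to-zero semantics), so the overall mean
    is preserved and, with donors balanced across groups, group means are too.
    """
    keep = [i for i in range(len(design.columns)) if i not in design.donor_indices]
    if not keep:
        raise ValueError("keep set is empty: nothing left after removing covariates")
    fit = fit_probe_models(m, design)
    coefs = fit.attrs["coef_all"]
    if not design.donor_indices:
        corrected = m[design.samples].to_numpy(float)
    else:
        X_d = design.matrix[:, design.donor_indices]
        X_d = X_d - X_d.mean(axis=0, keepdims=True)
        B_d = coefs[:, design.donor_indices]
        corrected = m[design.samples].to_numpy(float) - B_d @ X_d.T
    return pd.DataFrame(m_to_beta(corrected), index=m.index, columns=design.samples)
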