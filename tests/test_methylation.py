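import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from endotol.core import SampleSheet
from endotol.methylation import (
    beta_to_m,
    bh_fdr,
    build_design,
    call_dmps,
    fit_probe_models,
    m_to_beta,
    moderate_variances,
    probe_statistics,
    remove_covariate_effects,
)


def _paired_sheet(n_donors, conditions=("untreated", "lps")):
    rows = []
    for d in range(n_donors):
        for c in conditions:
            rows.append({"sample": f"D{d}_{c}", "condition": c, "donor": f"D{d}"})
    return SampleSheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# beta <-> M

@pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
def test_beta_to_m_known_values(beta, m):
    assert beta_to_m(beta) == pytest.approx(m)


def test_beta_to_m_domain_error():
    with pytest.raises(ValueError):
        beta_to_m(1.2)
    with pytest.raises(ValueError):
        beta_to_m(np.array([0.2, -0.1]))


@settings(max_examples=100, derandomize=True)
@given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
def test_beta_m_inverse_and_monotone(beta):
    assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-12)
    eps = 1e-7
    if beta + eps <= 1 - 1e-6:
        assert beta_to_m(beta + eps) > beta_to_m(beta)


def test_clipping_keeps_m_finite():
    assert np.isfinite(beta_to_m(0.0)) and np.isfinite(beta_to_m(1.0))


# ---------------------------------------------------------------------------
# per-probe OLS

def test_two_group_coef_is_mean_difference(rng):
    sheet = _paired_sheet(3)
    design = build_design(sheet, "lps", "untreated", donor_col=None)
    m = pd.DataFrame(rng.normal(size=(20, 6)), columns=design.samples)
    fit = fit_probe_models(m, design)
    cond = np.array([s.endswith("lps") for s in design.samples])
    expected = m.loc[:, cond].mean(axis=1) - m.loc[:, ~cond].mean(axis=1)
    np.testing.assert_allclose(fit["coef"], expected, atol=1e-12)


def test_paired_design_matches_normal_equations_oracle(rng):
    """Brute-force (X'X)^-1 X'y per probe, including donor columns."""
    sheet = _paired_sheet(4)
    design = build_design(sheet, "lps", "untreated", donor_col="donor")
    m = pd.DataFrame(rng.normal(size=(30, 8)), columns=design.samples)
    fit = fit_probe_models(m, design)
    X = design.matrix
    for i in range(len(m)):
        y = m.iloc[i].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        d = len(y) - X.shape[1]
        assert fit["coef"].iloc[i] == pytest.approx(beta[design.contrast_index], abs=1e-10)
        assert fit["s2"].iloc[i] == pytest.approx(resid @ resid / d, abs=1e-10)
    # paired contrast coefficient = mean of within-donor differences
    diffs = np.array([
        m[f"D{d}_lps"] - m[f"D{d}_untreated"] for d in range(4)
    ]).mean(axis=0)
    np.testing.assert_allclose(fit["coef"], diffs, atol=1e-10)


def test_ols_reproduces_data_from_fit(rng):
    sheet = _paired_sheet(3)
    design = build_design(sheet, "lps", "untreated")
    m = pd.DataFrame(rng.normal(size=(10, 6)), columns=design.samples)
    fit = fit_probe_models(m, design)
    coefs = fit.attrs["coef_all"]
    fitted = coefs @ design.matrix.T
    resid = m.to_numpy() - fitted
    np.testing.assert_allclose(fitted + resid, m.to_numpy(), atol=1e-12)


def test_design_errors():
    sheet = _paired_sheet(2)
    with pytest.raises(ValueError):
        build_design(sheet, "lps", "missing_condition")
    frame = sheet.frame.copy()
    frame["donor"] = frame["sample"]  # one donor level per sample: rank deficient
    with pytest.raises(ValueError):
        build_design(SampleSheet(frame), "lps", "untreated")


# ---------------------------------------------------------------------------
# empirical-Bayes moderation

def test_moderation_limits(rng):
    coef = rng.normal(size=100)
    s2 = rng.chisquare(4, 100) / 4
    mod = moderate_variances(coef, s2, d=4.0, se_unit=0.5)
    # moderated t lies between ordinary t and pooled-variance t in spread
    t_ord = coef / (np.sqrt(s2) * 0.5)
    shrunk = np.abs(mod.t) <= np.maximum(np.abs(t_ord), np.abs(coef / (np.sqrt(mod.s02) * 0.5))) + 1e-9
    assert shrunk.all()
    # all-equal variances: prior dominates, s2_tilde ~ constant
    mod2 = moderate_variances(coef, np.ones(100), d=4.0, se_unit=0.5)
    assert mod2.d0 == np.inf
    assert np.allclose(mod2.s2_tilde, mod2.s02)


def test_moderation_monte_carlo_prior_recovery():
    """s2 ~ s0^2 chi2_d / d with s0^2=1, d=4: recover s0^2 in [0.9, 1.1], d0 >= 50."""
    rng = np.random.default_rng(42)
    s2 = rng.chisquare(4, 10_000) / 4
    mod = moderate_variances(np.zeros(10_000), s2, d=4.0, se_unit=1.0)
    assert 0.9 <= mod.s02 <= 1.1
    assert mod.d0 >= 50


def test_moderation_degenerate_and_small_inputs():
    with pytest.raises(ValueError):
        moderate_variances(np.zeros(20), np.zeros(20), d=4.0, se_unit=1.0)
    with pytest.raises(ValueError):
        moderate_variances(np.zeros(5), np.ones(5), d=4.0, se_unit=1.0)


def test_moderated_t_matches_limma(tmp_path, rng):
    """Dual-route check of the whole linear-model stage against limma."""
    sheet = _paired_sheet(3)
    design = build_design(sheet, "lps", "untreated")
    m = pd.DataFrame(
        rng.normal(size=(200, 6)) * rng.uniform(0.5, 2.0, size=(200, 1)),
        index=[f"p{i}" for i in range(200)],
        columns=design.samples,
    )
    fit = fit_probe_models(m, design)
    mod = moderate_variances(
        fit["coef"].to_numpy(), fit["s2"].to_numpy(), float(fit["df"].iloc[0]), fit.attrs["se_unit"]
    )
    m_path = tmp_path / "m.tsv"
    m.to_csv(m_path, sep="\t")
    x_path = tmp_path / "design.tsv"
    pd.DataFrame(design.matrix, columns=design.columns).to_csv(x_path, sep="\t", index=False)
    out_path = tmp_path / "limma.tsv"
    script = tmp_path / "run_limma.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{m_path}", row.names = 1))
        X <- as.matrix(read.delim("{x_path}", check.names = FALSE))
        fit <- eBayes(lmFit(m, X))
        out <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2],
                          d0 = fit$df.prior, s02 = fit$s2.prior)
        write.table(out, "{out_path}", sep = "\\t", quote = FALSE)
    """))
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    limma = pd.read_csv(out_path, sep="\t")
    np.testing.assert_allclose(mod.t, limma["t"], rtol=1e-6)
    np.testing.assert_allclose(mod.p, limma["p"], rtol=1e-6)
    assert mod.d0 == pytest.approx(limma["d0"].iloc[0], rel=1e-4)
    assert mod.s02 == pytest.approx(limma["s02"].iloc[0], rel=1e-4)


# ---------------------------------------------------------------------------
# BH FDR

def _bh_brute(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    for i in range(m):
        cands = [p[order[j]] * m / (j + 1) for j in range(m) if p[order[j]] >= p[i]]
        out[i] = min(1.0, min(cands))
    return out


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.03], [0.03]),
        ([0.02] * 5, [0.02] * 5),
        ([0.01, 0.04, 0.03], [0.03, 0.04, 0.04]),
    ],
)
def test_bh_known_values(p, expected):
    np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)


def test_bh_matches_exhaustive_step_up_oracle():
    grid = [0.01, 0.05, 0.5, 1.0]
    for m in range(1, 7):
        for p in itertools.product(grid, repeat=m):
            np.testing.assert_allclose(bh_fdr(list(p)), _bh_brute(list(p)), atol=1e-12)


def test_bh_properties_and_errors(rng):
    p = rng.uniform(size=200)
    q = bh_fdr(p)
    assert (q >= p - 1e-12).all() and (q <= 1).all()
    # order preserving
    assert (np.argsort(q, kind="stable")[np.argsort(np.argsort(p))] >= 0).all()
    with pytest.raises(ValueError):
        bh_fdr([0.1, np.nan])
    with pytest.raises(ValueError):
        bh_fdr([1.5])


# ---------------------------------------------------------------------------
# DMP calling

def test_call_dmps_threshold_rules():
    stats = pd.DataFrame(
        {
            "q": [0.01, 0.01, 0.2, 0.01],
            "delta_beta": [-0.25, -0.10, -0.5, 0.3],
        },
        index=["keep_hypo", "small_delta", "big_q", "keep_hyper"],
    )
    out = call_dmps(stats)
    assert set(out.index) == {"keep_hypo", "keep_hyper"}
    assert out.loc["keep_hypo", "direction"] == "hypo"
    assert out.loc["keep_hyper", "direction"] == "hyper"
    assert out.attrs["n_hypo"] == 1 and out.attrs["n_hyper"] == 1
    with pytest.raises(ValueError):
        call_dmps(stats, fdr=0.0)
    with pytest.raises(ValueError):
        call_dmps(stats, delta=1.0)


def test_dmp_recovery_on_planted_methylome(small_methylome):
    betas, sheet, truth = small_methylome
    stats = probe_statistics(betas, sheet, "lps", "untreated")
    dmps = call_dmps(stats)
    planted = set(truth.tables["dmps"]["probe"])
    called = set(dmps.index)
    assert len(called & planted) / len(planted) >= 0.8
    assert len(called - planted) / max(len(called), 1) <= 0.10
    assert (dmps.loc[dmps.index.isin(planted), "direction"] == "hypo").all()


def test_dmps_invariant_to_probe_and_sample_permutation(small_methylome, rng):
    betas, sheet, _ = small_methylome
    stats = call_dmps(probe_statistics(betas, sheet, "lps", "untreated"))
    perm_probes = betas.sample(frac=1, random_state=1)
    col_perm = rng.permutation(betas.columns)
    perm_frame = sheet.frame.set_index("sample").loc[col_perm].reset_index()
    stats2 = call_dmps(probe_statistics(perm_probes[col_perm], SampleSheet(perm_frame), "lps", "untreated"))
    assert set(stats.index) == set(stats2.index)
    pd.testing.assert_series_equal(
        stats["delta_beta"].sort_index(), stats2["delta_beta"].sort_index(), atol=1e-10
    )


# ---------------------------------------------------------------------------
# covariate-corrected betas

def test_remove_covariates_identity_without_donors(rng):
    sheet = _paired_sheet(3)
    design = build_design(sheet, "lps", "untreated", donor_col=None)
    betas = pd.DataFrame(rng.uniform(0.05, 0.95, size=(15, 6)), columns=design.samples)
    m = pd.DataFrame(beta_to_m(betas.to_numpy()), columns=design.samples)
    corrected = remove_covariate_effects(m, design)
    np.testing.assert_allclose(corrected.to_numpy(), betas.to_numpy(), atol=1e-10)


def test_remove_covariates_strips_planted_donor_offset():
    sheet = _paired_sheet(2)
    design = build_design(sheet, "lps", "untreated")
    base = np.tile(np.array([0.5, -1.0, 2.0])[:, None], (1, 4))
    m = pd.DataFrame(base, columns=design.samples)
    m[["D1_untreated", "D1_lps"]] += 1.0  # donor 2 offset of +1 M-unit
    corrected_m = beta_to_m(remove_covariate_effects(m, design).to_numpy())
    # donor difference removed exactly: both donors end up identical
    np.testing.assert_allclose(
        corrected_m[:, [0, 1]], corrected_m[:, [2, 3]], atol=1e-10
    )
    # overall probe means preserved (sum-to-zero donor coding)
    np.testing.assert_allclose(
        corrected_m.mean(axis=1), m.to_numpy().mean(axis=1), atol=1e-10
    )


def test_corrected_group_means_preserved_in_balanced_design(rng):
    sheet = _paired_sheet(4)
    design = build_design(sheet, "lps", "untreated")
    m = pd.DataFrame(rng.normal(size=(20, 8)), columns=design.samples)
    corrected_m = beta_to_m(remove_covariate_effects(m, design).to_numpy())
    cond = np.array([s.endswith("lps") for s in design.samples])
    for grp in (cond, ~cond):
        np.testing.assert_allclose(
            corrected_m[:, grp].mean(axis=1),
            m.to_numpy()[:, grp].mean(axis=1),
            atol=1e-8,
        )


# ---------------------------------------------------------------------------
# null calibration

def test_null_methylome_type_one_error_calibrated():
    from endotol.simulate import simulate_methylome

    betas, sheet, _ = simulate_methylome(n_probes=5000, n_dmp=0, n_donors=3, seed=23)
    stats = probe_statistics(betas, sheet, "lps", "untreated")
    frac = float((stats["p"] < 0.05).mean())
    se = np.sqrt(0.05 * 0.95 / len(stats))
    assert abs(frac - 0.05) <= 3 * se
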