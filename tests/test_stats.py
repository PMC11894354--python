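"""Transforms, mixed-model contrasts, ICC, Bland-Altman, device alignment."""

import math

import numpy as np
import pandas as pd
import pytest

from hrvgaps.io import ValidationError
from hrvgaps.stats import (align_devices, bland_altman, boxcox,
                           fit_missingness_contrasts,
                           fit_random_intercept_reml, icc2k, needs_transform,
                           qq_points, rmse_pairs)


# -- Box-Cox / Q-Q ----------------------------------------------------------

def test_boxcox_lognormal_lambda_near_zero(rng):
    x = np.exp(rng.normal(0, 1, 10_000))
    _, lam = boxcox(x)
    assert abs(lam) < 0.2


def test_boxcox_normal_lambda_near_one(rng):
    x = rng.normal(50, 2, 10_000)
    _, lam = boxcox(x)
    assert abs(lam - 1) < 0.5


def test_boxcox_rejects_nonpositive():
    with pytest.raises(ValidationError, match="positive"):
        boxcox([1.0, 0.0, 2.0])


def test_skewness_rule(rng):
    assert needs_transform(np.exp(rng.normal(0, 1, 5000)))
    assert not needs_transform(rng.normal(0, 1, 5000))


def test_qq_points_shapes_and_line(rng):
    pts = qq_points(rng.normal(0, 1, 2000))
    assert pts.shape == (2000, 2)
    # near the 45-degree line for a standard normal sample
    core = pts[100:-100]
    assert np.max(np.abs(core[:, 0] - core[:, 1])) < 0.3
    assert qq_points([1.0, 2.0, 3.0]).shape == (3, 2)
    with pytest.raises(ValidationError):
        qq_points([1.0, 2.0])


# -- mixed model ------------------------------------------------------------

def simulate_long(rng, n_part=8, n_win=40, effect=-0.5, sigma_b=1.0,
                  sigma_e=1.0, level="60"):
    rows = []
    for i in range(n_part):
        b = rng.normal(0, sigma_b)
        for w in range(n_win):
            rows.append((f"P{i:02d}", w, "rest", "ref", "hf",
                         5 + b + rng.normal(0, sigma_e)))
            rows.append((f"P{i:02d}", w, "rest", level, "hf",
                         5 + effect + b + rng.normal(0, sigma_e)))
    return pd.DataFrame(rows, columns=["participant_id", "window_start",
                                       "activity", "level", "metric", "value"])


def test_duplicated_level_gives_zero_estimate(rng):
    df = simulate_long(rng, n_part=4, n_win=20, effect=0.0)
    ref = df[df["level"] == "ref"].copy()
    dup = ref.copy()
    dup["level"] = "10"
    table = pd.concat([ref, dup], ignore_index=True)
    res = fit_missingness_contrasts(table, "hf", "rest", n_boot=0, seed=0,
                                    transform="none")[0]
    assert res.estimate == pytest.approx(0.0, abs=1e-8)
    assert res.p_value > 0.99


def test_effect_recovery_with_bootstrap_ci(rng):
    df = simulate_long(rng, n_part=10, n_win=60, effect=-0.5)
    res = fit_missingness_contrasts(df, "hf", "rest", n_boot=200, seed=1,
                                    transform="none")[0]
    assert res.estimate == pytest.approx(-0.5, abs=0.15)
    assert res.ci_low <= res.estimate <= res.ci_high
    assert res.ci_high - res.ci_low < 0.5
    assert res.p_value < 1e-4


def test_single_participant_rejected(rng):
    df = simulate_long(rng, n_part=1)
    with pytest.raises(ValidationError, match="participant"):
        fit_missingness_contrasts(df, "hf", "rest", n_boot=0)


def test_reference_level_required(rng):
    df = simulate_long(rng, n_part=3)
    with pytest.raises(ValidationError, match="reference"):
        fit_missingness_contrasts(df[df["level"] == "60"], "hf", "rest", n_boot=0)


def test_fast_reml_matches_statsmodels(rng):
    import statsmodels.api as sm
    df = simulate_long(rng, n_part=6, n_win=30)
    y = df["value"].to_numpy()
    X = np.column_stack([np.ones(len(df)),
                         (df["level"] == "60").to_numpy(float)])
    g = df["participant_id"].to_numpy()
    beta, sb2, se2 = fit_random_intercept_reml(X, y, g)
    fit = sm.MixedLM(y, X, groups=g).fit(reml=True)
    np.testing.assert_allclose(beta, fit.fe_params, atol=1e-5)
    assert sb2 == pytest.approx(float(np.asarray(fit.cov_re)[0, 0]), abs=1e-3)
    assert se2 == pytest.approx(float(fit.scale), abs=1e-4)


def test_satterthwaite_df_large_balanced_sample(rng):
    df = simulate_long(rng, n_part=8, n_win=50)
    res = fit_missingness_contrasts(df, "hf", "rest", n_boot=0, transform="none")[0]
    # within-participant contrast: df close to the residual count
    assert 100 < res.df <= len(df)


def test_auto_transform_applies_boxcox_to_skewed_metric(rng):
    df = simulate_long(rng, n_part=4, n_win=30, effect=0.0)
    df["value"] = np.exp(df["value"] / 2)
    res = fit_missingness_contrasts(df, "hf", "rest", n_boot=0, transform="auto")[0]
    assert res.transform.startswith("boxcox")


# -- ICC --------------------------------------------------------------------

def brute_icc2k(R):
    """ICC(2,k) from an explicitly looped two-way ANOVA table."""
    n, k = R.shape
    grand = R.mean()
    msr = sum((R[i].mean() - grand) ** 2 for i in range(n)) * k / (n - 1)
    msc = sum((R[:, j].mean() - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = sum((R[i, j] - R[i].mean() - R[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    cons = (msr - mse) / msr
    agr = (msr - mse) / (msr + (msc - mse) / n)
    return agr, cons


def test_identical_raters_perfect_icc(rng):
    a = rng.normal(0, 1, 20)
    res = icc2k(np.column_stack([a, a]))
    assert res.agreement == pytest.approx(1.0)
    assert res.consistency == pytest.approx(1.0)


def test_additive_offset_consistency_one_agreement_below(rng):
    a = rng.normal(0, 1, 30)
    res = icc2k(np.column_stack([a, a + 2.0]))
    assert res.consistency == pytest.approx(1.0)
    assert res.agreement < 1.0


def test_icc_matches_anova_oracle(rng):
    for _ in range(20):
        R = rng.normal(0, 1, (20, 2)) + rng.normal(0, 2, (20, 1))
        res = icc2k(R)
        agr, cons = brute_icc2k(R)
        assert res.agreement == pytest.approx(agr, abs=1e-9)
        assert res.consistency == pytest.approx(cons, abs=1e-9)


def test_icc_matches_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    R = rng.normal(0, 1, (40, 2)) + rng.normal(0, 2, (40, 1)) + [0.0, 1.0]
    res = icc2k(R)
    df = pd.DataFrame({"subject": np.repeat(np.arange(40), 2),
                       "rater": np.tile(["a", "b"], 40),
                       "score": R.ravel()})
    icc = pg.intraclass_corr(df, targets="subject", raters="rater",
                             ratings="score").set_index("Type")
    assert res.agreement == pytest.approx(icc.loc["ICC(A,k)", "ICC"], abs=1e-9)
    assert res.consistency == pytest.approx(icc.loc["ICC(C,k)", "ICC"], abs=1e-9)
    # pingouin rounds its CI bounds to 2 decimals
    np.testing.assert_allclose(res.agreement_ci, icc.loc["ICC(A,k)", "CI95"],
                               atol=6e-3)
    np.testing.assert_allclose(res.consistency_ci, icc.loc["ICC(C,k)", "CI95"],
                               atol=6e-3)


def test_icc_shift_invariance(rng):
    R = rng.normal(5, 2, (25, 2))
    r0 = icc2k(R)
    r1 = icc2k(R + 7.5)
    assert r1.agreement == pytest.approx(r0.agreement, abs=1e-12)
    assert r1.consistency == pytest.approx(r0.consistency, abs=1e-12)
    # constant added to one rater only: consistency unchanged
    r2 = icc2k(np.column_stack([R[:, 0], R[:, 1] + 3.0]))
    assert r2.consistency == pytest.approx(r0.consistency, abs=1e-12)


def test_icc_degenerate_flagged():
    res = icc2k(np.tile([[1.0, 1.0]], (6, 1)))
    assert not res.defined


def test_icc_minimum_pairs():
    with pytest.raises(ValidationError):
        icc2k(np.ones((4, 2)))


def test_icc_interpretation_labels():
    from hrvgaps.stats import ICCResult
    assert ICCResult.interpret(0.95) == "excellent"
    assert ICCResult.interpret(0.8) == "good"
    assert ICCResult.interpret(0.6) == "moderate"
    assert ICCResult.interpret(0.3) == "poor"


# -- Bland-Altman / RMSE / alignment ---------------------------------------

def test_bland_altman_examples(rng):
    a = rng.normal(800, 30, 50)
    res = bland_altman(a, a)
    assert res.mean_diff == 0 and res.loa_low == res.loa_high == 0
    res = bland_altman(a, a - 5)
    assert res.mean_diff == pytest.approx(5.0)
    assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-9)
    b = a + rng.normal(0, 10, 50)
    res = bland_altman(a, b)
    d = a - b
    assert res.mean_diff == pytest.approx(d.mean())
    assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
    assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))


def test_bland_altman_swap_antisymmetry(rng):
    a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
    assert bland_altman(a, b).mean_diff == pytest.approx(
        -bland_altman(b, a).mean_diff)


def test_rmse(rng):
    a = rng.normal(0, 1, 40)
    assert rmse_pairs(a, a) == 0.0
    assert rmse_pairs(a, a - 5) == pytest.approx(5.0)
    b = rng.normal(0, 1, 40)
    assert rmse_pairs(a, b) == pytest.approx(math.sqrt(np.mean((a - b) ** 2)))


def metric_df(pid, starts, values, valid=True):
    return pd.DataFrame({"participant_id": pid, "window_start_ms": starts,
                         "median_ibi": values, "time_valid": valid,
                         "freq_valid": valid})


def test_align_devices_inner_join():
    p = metric_df("P00", [0, 300_000, 600_000], [800.0, 810, 820])
    e = metric_df("P00", [300_000, 600_000, 900_000], [805.0, 815, 825])
    paired = align_devices(p, e)
    assert list(paired["window_start_ms"]) == [300_000, 600_000]


def test_align_devices_drops_invalid_windows():
    p = metric_df("P00", [0, 300_000], [800.0, 810])
    e = metric_df("P00", [0, 300_000], [805.0, 815])
    e.loc[1, "freq_valid"] = False
    paired = align_devices(p, e)
    assert list(paired["window_start_ms"]) == [0]


def test_align_devices_disjoint_errors():
    p = metric_df("P00", [0], [800.0])
    e = metric_df("P00", [300_000], [805.0])
    with pytest.raises(ValidationError):
        align_devices(p, e)
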