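"""Missingness-effect and between-device-agreement statistics.

Missingness effects
-------------------
Per HRV metric and activity class, the per-window values from the reference
dataset and each degraded dataset are stacked long and modelled with a
linear mixed model

    y_ijk = beta_0 + sum_l beta_l 1[level_ijk = l] + b_i + e_ijk,

with a participant random intercept ``b_i ~ N(0, sigma_b^2)`` and residual
``e ~ N(0, sigma_e^2)``, fit by REML (statsmodels ``MixedLM``).  Each
``beta_l`` is the mean shift a missingness level induces relative to the
complete reference data.  Two-sided p-values use Satterthwaite-approximated
denominator degrees of freedom, computed here from the closed-form REML
log-likelihood of the random-intercept model; 95 % CIs come from a
parametric bootstrap (simulate from the fitted model, refit, percentile
interval).  Metrics with skewed distributions are Box-Cox transformed
before modelling.

Between-device agreement
------------------------
Paired per-window metrics from two devices are summarised by ICC(2,k)
(two-way random effects, mean of k=2 raters) in both the consistency and
absolute-agreement forms (McGraw–Wong mean squares, F-based CIs),
Bland-Altman mean difference with 95 % limits of agreement, and RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .io import ValidationError

MISSINGNESS_LEVELS = ("ref", "10", "20", "35", "60")
SKEWNESS_RULE_THRESHOLD = 0.5


# --------------------------------------------------------------------------
# transforms and normality support

def boxcox(values) -> tuple[np.ndarray, float]:
    """Box-Cox transform with lambda chosen by maximum profile likelihood.

    ``y -> (y**lmbda - 1)/lmbda`` (``ln y`` at ``lmbda = 0``).  All values
    must be strictly positive; shift or exclude non-positive values first.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValidationError(
            "Box-Cox needs strictly positive values; shift the variable or "
            "exclude non-positive observations first")
    transformed, lmbda = spstats.boxcox(x)
    return transformed, float(lmbda)


def qq_points(values) -> np.ndarray:
    """Normal Q-Q coordinates: (theoretical quantile, ordered sample value).

    Degenerate (constant) samples are allowed; the sample quantiles are then
    a flat line, which a caller can flag visually.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("qq_points needs n >= 3")
    (osm, osr), _ = spstats.probplot(x, dist="norm", fit=True)
    return np.column_stack([osm, osr])


def needs_transform(values, threshold: float = SKEWNESS_RULE_THRESHOLD) -> bool:
    """Automated stand-in for visual Q-Q inspection: |skewness| > threshold."""
    return bool(abs(spstats.skew(np.asarray(values, dtype=float))) > threshold)


# --------------------------------------------------------------------------
# random-intercept REML internals

def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group sufficient statistics for the random-intercept model."""
    uniq, idx = np.unique(groups, return_inverse=True)
    stats = []
    for g in range(uniq.size):
        m = idx == g
        Xg, yg = X[m], y[m]
        stats.append((Xg.T @ Xg, Xg.T @ yg, float(yg @ yg),
                      Xg.sum(axis=0), float(yg.sum()), int(m.sum())))
    return stats


def _gls_pieces(stats, lam: float):
    """X'V^-1 X, X'V^-1 y, y'V^-1 y and sum log(1 + n_i lam), with V in
    units of sigma_e^2: V_i = I + lam * J."""
    p = stats[0][0].shape[0]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for XtX, Xty, yty, sx, sy, n in stats:
        c = lam / (1.0 + n * lam)
        XtVX += XtX - c * np.outer(sx, sx)
        XtVy += Xty - c * sx * sy
        ytVy += yty - c * sy * sy
        logdet += math.log1p(n * lam)
    return XtVX, XtVy, ytVy, logdet


def _profile_reml_neg2ll(stats, lam: float, n: int, p: int):
    XtVX, XtVy, ytVy, logdet = _gls_pieces(stats, lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - beta @ XtVy, 1e-300)
    sigma_e2 = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(XtVX)
    neg2 = (n - p) * math.log(sigma_e2) + logdet + logdet_xx + (n - p)
    return neg2, beta, sigma_e2


def fit_random_intercept_reml(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Fast closed-form-profile REML fit of the random-intercept model.

    Profiles the variance ratio ``lam = sigma_b^2 / sigma_e^2`` with a 1-D
    bounded search; used for bootstrap refits, where calling a general
    mixed-model fitter thousands of times would dominate the runtime.
    Returns ``(beta, sigma_b2, sigma_e2)``.
    """
    from scipy.optimize import minimize_scalar
    n, p = X.shape
    stats = _group_stats(X, y, groups)

    def obj(log_lam: float) -> float:
        return _profile_reml_neg2ll(stats, math.exp(log_lam), n, p)[0]

    res = minimize_scalar(obj, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": 1e-6})
    lam = math.exp(res.x)
    _, beta, sigma_e2 = _profile_reml_neg2ll(stats, lam, n, p)
    return beta, lam * sigma_e2, sigma_e2


def _reml_neg2ll(stats, sigma_b2: float, sigma_e2: float, n: int, p: int) -> float:
    """-2 REML log-likelihood at a variance-component point (up to const)."""
    lam = sigma_b2 / sigma_e2
    XtVX, XtVy, ytVy, logdet = _gls_pieces(stats, lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - beta @ XtVy, 1e-300)
    _, logdet_xx = np.linalg.slogdet(XtVX / sigma_e2)
    return (n * math.log(sigma_e2) + logdet + logdet_xx + rss / sigma_e2
            - p * 0.0)


def _contrast_variance(stats, sigma_b2: float, sigma_e2: float, ell: np.ndarray) -> float:
    lam = sigma_b2 / sigma_e2
    XtVX, _, _, _ = _gls_pieces(stats, lam)
    C = np.linalg.inv(XtVX / sigma_e2)
    return float(ell @ C @ ell)


def satterthwaite_df(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                     sigma_b2: float, sigma_e2: float, ell: np.ndarray) -> float:
    """Satterthwaite denominator df for the contrast ``ell' beta``.

    ``df = 2 f^2 / (g' A g)`` with ``f = ell' Cov(beta) ell``, ``g`` its
    gradient in the variance components and ``A`` their asymptotic
    covariance (inverse observed REML information), all from the
    closed-form random-intercept likelihood with numerical derivatives.
    """
    n, p = X.shape
    stats = _group_stats(X, y, groups)
    sigma_b2 = max(sigma_b2, 1e-8 * sigma_e2)
    theta = np.array([sigma_b2, sigma_e2])
    h = 1e-4 * theta

    def f(th):
        return _contrast_variance(stats, th[0], th[1], ell)

    def ll(th):
        return -0.5 * _reml_neg2ll(stats, th[0], th[1], n, p)

    grad = np.zeros(2)
    for k in range(2):
        e = np.zeros(2); e[k] = h[k]
        grad[k] = (f(theta + e) - f(theta - e)) / (2 * h[k])
    H = np.zeros((2, 2))
    for k in range(2):
        for j in range(2):
            ek = np.zeros(2); ek[k] = h[k]
            ej = np.zeros(2); ej[j] = h[j]
            H[k, j] = (ll(theta + ek + ej) - ll(theta + ek - ej)
                       - ll(theta - ek + ej) + ll(theta - ek - ej)) / (4 * h[k] * h[j])
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return float("inf")
    denom = float(grad @ A @ grad)
    fval = f(theta)
    if denom <= 0 or not math.isfinite(denom):
        return float("inf")
    return 2.0 * fval * fval / denom


# --------------------------------------------------------------------------
# missingness contrasts

@dataclass
class ContrastResult:
    """One level-vs-reference mixed-model contrast for one metric."""

    metric: str
    level: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    transform: str  # "none" or "boxcox(lambda=...)"


def fit_missingness_contrasts(table: pd.DataFrame, metric: str, activity: str,
                              n_boot: int = 1000, seed: int = 0,
                              transform: str = "auto") -> list[ContrastResult]:
    """Level-of-missingness contrasts for one metric within one activity class.

    ``table`` is long: columns ``participant_id``, ``window_start``,
    ``activity``, ``level`` (one of ``ref``/``10``/``20``/``35``/``60``),
    ``metric``, ``value``.  ``transform``: ``"auto"`` applies Box-Cox when
    |skewness| > 0.5 (an automated stand-in for visual Q-Q inspection),
    ``"boxcox"`` forces it, ``"none"`` disables it.

    The model is fit by REML via statsmodels MixedLM; bootstrap refits use
    the package's fast profile-REML solver for the same model.
    Deterministic under ``seed``.
    """
    import statsmodels.api as sm

    sub = table[(table["metric"] == metric) & (table["activity"] == activity)]
    sub = sub.dropna(subset=["value"])
    levels = [l for l in MISSINGNESS_LEVELS if l in set(sub["level"])]
    if "ref" not in levels or len(levels) < 2:
        raise ValidationError("need reference data plus >= 1 degraded level")
    if sub["participant_id"].nunique() < 2:
        raise ValidationError(
            "random intercept unidentifiable with a single participant")

    y = sub["value"].to_numpy(float)
    tr_label = "none"
    if transform == "boxcox" or (transform == "auto" and needs_transform(y)):
        y, lmbda = boxcox(y)
        tr_label = f"boxcox(lambda={lmbda:.4f})"
    elif transform not in ("auto", "none"):
        raise ValidationError("transform must be 'auto', 'boxcox' or 'none'")

    contrast_levels = [l for l in levels if l != "ref"]
    X = np.column_stack(
        [np.ones(len(sub))]
        + [(sub["level"] == l).to_numpy(float) for l in contrast_levels])
    groups = sub["participant_id"].to_numpy()

    model = sm.MixedLM(y, X, groups=groups)
    fit = model.fit(reml=True)
    beta = np.asarray(fit.fe_params, dtype=float)
    se = np.asarray(fit.bse_fe, dtype=float)
    sigma_e2 = float(fit.scale)
    sigma_b2 = float(np.asarray(fit.cov_re)[0, 0])
    # guard against optimizer collapse onto the sigma_b^2 = 0 boundary:
    # accept the in-package profile-REML solution when it has a better
    # restricted likelihood, and rebuild the SEs from it
    beta_f, sb2_f, se2_f = fit_random_intercept_reml(X, y, groups)
    if se2_f <= 0 or not math.isfinite(se2_f):
        raise ValidationError(
            f"no residual variation in {metric}/{activity}; contrasts undefined")
    stats_g = _group_stats(X, y, groups)
    n, p = X.shape
    if (sigma_e2 <= 0 or not math.isfinite(sigma_e2)
        or _reml_neg2ll(stats_g, max(sb2_f, 1e-10 * se2_f), se2_f, n, p)
            < _reml_neg2ll(stats_g, max(sigma_b2, 1e-10 * sigma_e2),
                           max(sigma_e2, 1e-300), n, p) - 1e-6):
        beta, sigma_b2, sigma_e2 = beta_f, sb2_f, se2_f
        C = np.linalg.inv(_gls_pieces(stats_g, sigma_b2 / sigma_e2)[0] / sigma_e2)
        se = np.sqrt(np.diag(C))

    # parametric bootstrap: simulate from the fitted model, refit (fast REML)
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    uniq_groups, grp_idx = np.unique(groups, return_inverse=True)
    mu = X @ beta
    boot = np.empty((n_boot, len(contrast_levels)))
    for b in range(n_boot):
        b_i = rng.normal(0.0, math.sqrt(max(sigma_b2, 0.0)), uniq_groups.size)
        y_star = mu + b_i[grp_idx] + rng.normal(0.0, math.sqrt(sigma_e2), y.size)
        beta_star, _, _ = fit_random_intercept_reml(X, y_star, groups)
        boot[b] = beta_star[1:]
    ci = np.percentile(boot, [2.5, 97.5], axis=0) if n_boot else np.full((2, len(contrast_levels)), np.nan)

    out = []
    for j, level in enumerate(contrast_levels, start=1):
        ell = np.zeros(X.shape[1]); ell[j] = 1.0
        df = satterthwaite_df(X, y, groups, sigma_b2, sigma_e2, ell)
        tstat = beta[j] / se[j]
        p = 2.0 * (spstats.t.sf(abs(tstat), df) if math.isfinite(df)
                   else spstats.norm.sf(abs(tstat)))
        out.append(ContrastResult(metric=metric, level=level,
                                  estimate=float(beta[j]), se=float(se[j]),
                                  ci_low=float(ci[0, j - 1]),
                                  ci_high=float(ci[1, j - 1]),
                                  p_value=float(p), df=float(df),
                                  transform=tr_label))
    return out


# --------------------------------------------------------------------------
# agreement

@dataclass
class ICCResult:
    """ICC(2,k): two-way random effects, mean of k raters."""

    agreement: float
    agreement_ci: tuple[float, float]
    consistency: float
    consistency_ci: tuple[float, float]
    n: int
    k: int
    defined: bool = True

    @staticmethod
    def interpret(icc: float) -> str:
        if icc > 0.9:
            return "excellent"
        if icc > 0.75:
            return "good"
        if icc >= 0.5:
            return "moderate"
        return "poor"


def _two_way_mean_squares(ratings: np.ndarray):
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = ratings - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc2k(ratings, alpha: float = 0.05) -> ICCResult:
    """ICC(2,k) agreement and consistency with F-based 95 % CIs.

    ``ratings`` is an n-subjects x k-raters matrix (rows with any missing
    rating are dropped).  Mean squares follow the two-way random-effects
    ANOVA; consistency ``(MSR - MSE)/MSR`` ignores systematic rater bias,
    agreement ``(MSR - MSE)/(MSR + (MSC - MSE)/n)`` penalises it.
    """
    R = np.asarray(ratings, dtype=float)
    R = R[~np.isnan(R).any(axis=1)]
    n, k = R.shape
    if n < 5:
        raise ValidationError("icc2k needs >= 5 complete paired observations")
    msr, msc, mse = _two_way_mean_squares(R)
    if msr <= 0 or not math.isfinite(msr):
        return ICCResult(float("nan"), (float("nan"),) * 2, float("nan"),
                         (float("nan"),) * 2, n, k, defined=False)

    icc_c = (msr - mse) / msr
    icc_a = (msr - mse) / (msr + (msc - mse) / n)

    # consistency CI (McGraw-Wong): F bounds on MSR/MSE
    f_obs = msr / mse if mse > 0 else float("inf")
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = f_obs / spstats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * spstats.f.ppf(1 - alpha / 2, df2, df1)
    ci_c = (1 - 1 / fl if fl > 0 else float("nan"),
            1 - 1 / fu if fu > 0 else float("nan"))

    # agreement CI: single-rater bounds via the Satterthwaite df, then
    # Spearman-Brown step-up to k raters
    icc_a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = (k * icc_a1) / (n * (1 - icc_a1)) if icc_a1 < 1 else float("inf")
    b = 1 + (k * icc_a1 * (n - 1)) / (n * (1 - icc_a1)) if icc_a1 < 1 else float("inf")
    if math.isfinite(a) and math.isfinite(b) and (a * msc + b * mse) > 0:
        v = ((a * msc + b * mse) ** 2 /
             ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f1 = spstats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = spstats.f.ppf(1 - alpha / 2, v, n - 1)
        l1 = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        u1 = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        ci_a = (l1 * k / (1 + (k - 1) * l1), u1 * k / (1 + (k - 1) * u1))
    else:
        ci_a = (icc_a, icc_a)
    return ICCResult(agreement=float(icc_a), agreement_ci=ci_a,
                     consistency=float(icc_c), consistency_ci=ci_c, n=n, k=k)


@dataclass
class BlandAltman:
    """Paired-difference agreement summary: mean diff and 95 % limits."""

    mean_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def bland_altman(a, b) -> BlandAltman:
    """Bland-Altman statistics for paired measurements (diffs = a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValidationError("bland_altman needs >= 2 complete pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean_diff=md, loa_low=md - 1.96 * sd,
                       loa_high=md + 1.96 * sd, means=(a + b) / 2.0, diffs=d)


def rmse_pairs(a, b) -> float:
    """Root-mean-square difference of paired measurements."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 1:
        raise ValidationError("rmse_pairs needs >= 1 pair")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def align_devices(ppg_metrics: pd.DataFrame, ecg_metrics: pd.DataFrame) -> pd.DataFrame:
    """Inner-join per-window metric tables from two devices.

    Keyed on ``(participant_id, window_start_ms)``; when validity flags are
    present only windows valid in both devices are retained.  Columns get
    ``_ppg``/``_ecg`` suffixes.
    """
    key = ["participant_id", "window_start_ms"]
    merged = ppg_metrics.merge(ecg_metrics, on=key, suffixes=("_ppg", "_ecg"))
    for flag in ("time_valid", "freq_valid"):
        c1, c2 = f"{flag}_ppg", f"{flag}_ecg"
        if c1 in merged.columns and c2 in merged.columns:
            merged = merged[merged[c1] & merged[c2]]
    if merged.empty:
        raise ValidationError("no overlapping valid windows between devices")
    return merged.reset_index(drop=True)


def agreement_summary(paired: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    """Per-metric ICC(2,k), Bland-Altman and RMSE table for paired devices.

    For the ICC the subject unit is the 5-minute window (the two device
    readings of one window are the k=2 raters).
    """
    rows = []
    for m in metrics:
        a = paired[f"{m}_ppg"].to_numpy(float)
        b = paired[f"{m}_ecg"].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        icc = icc2k(np.column_stack([a, b]))
        ba = bland_altman(a, b)
        rows.append({
            "metric": m, "n_pairs": int(a.size),
            "icc_agreement": icc.agreement,
            "icc_agreement_ci_low": icc.agreement_ci[0],
            "icc_agreement_ci_high": icc.agreement_ci[1],
            "icc_consistency": icc.consistency,
            "icc_consistency_ci_low": icc.consistency_ci[0],
            "icc_consistency_ci_high": icc.consistency_ci[1],
            "icc_label": ICCResult.interpret(icc.agreement) if icc.defined else "undefined",
            "bland_altman_mean_diff": ba.mean_diff,
            "bland_altman_loa_low": ba.loa_low,
            "bland_altman_loa_high": ba.loa_high,
            "rmse": rmse_pairs(a, b),
        })
    return pd.DataFrame(rows)
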