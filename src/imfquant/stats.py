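"""Statistical layer: effect sizes, Welch tests, mixed models, FDR control.

Slide-level fat percentages are correlated within an animal, so group
contrasts use a Gaussian linear mixed model with a single random intercept
per animal, estimated by REML (profiled over the variance ratio), with
degrees of freedom from Satterthwaite's moment-matching approximation and
Benjamini–Hochberg q-values across the contrast plan (significance at
q < 0.1).  Method-comparison summaries use Welch's t-test and pooled-SD
Cohen's d.

The REML fitter is self-contained (statsmodels' MixedLM does not expose the
variance-parameter covariance needed for Satterthwaite df) and is
cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import EffectSizeError, FitError, ImfquantError

__all__ = [
    "SummaryStats", "summary_stats", "cohens_d", "classify_effect", "welch_t",
    "bh_qvalues", "MixedModelFit", "fit_random_intercept", "satterthwaite_df",
    "satterthwaite_components", "Contrast", "default_contrast_plan",
    "run_group_comparisons",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean, SD and sample size of one group of measurements."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ImfquantError("sd must be >= 0")
        if self.n < 2:
            raise ImfquantError("need n >= 2")


def summary_stats(values) -> SummaryStats:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ImfquantError("need n >= 2 observations for summary statistics")
    return SummaryStats(float(values.mean()), float(values.std(ddof=1)), len(values))


def cohens_d(a: SummaryStats, b: SummaryStats) -> float:
    """Pooled-SD Cohen's d = (m_a - m_b) / s_p; sign follows argument order."""
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / (a.n + b.n - 2)
    diff = a.mean - b.mean
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0
        raise EffectSizeError("zero pooled SD with unequal means: d is infinite")
    return diff / np.sqrt(sp2)


def classify_effect(d: float) -> str:
    """Conventional |d| bands: <0.2 negligible, <0.5 small, <0.8 medium, else large."""
    if not np.isfinite(d):
        raise EffectSizeError("effect size must be finite")
    m = abs(d)
    if m < 0.2:
        return "negligible"
    if m < 0.5:
        return "small"
    if m < 0.8:
        return "medium"
    return "large"


def welch_t(a: SummaryStats, b: SummaryStats) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summaries: (t, df, two-sided p)."""
    if a.sd == 0.0 and b.sd == 0.0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        return float(np.inf) * np.sign(a.mean - b.mean), float(a.n + b.n - 2), 0.0
    t, p = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                    equal_var=False)
    df = satterthwaite_components(
        variances=(a.sd ** 2 / a.n, b.sd ** 2 / b.n),
        dfs=(a.n - 1, b.n - 1))
    return float(t), float(df), float(p)


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ImfquantError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ImfquantError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def satterthwaite_components(variances, dfs, coefs=None) -> float:
    """Moment-matching df for a linear combination of variance estimates.

    df = (sum a_i v_i)^2 / sum (a_i v_i)^2 / df_i — reduces to the
    Welch–Satterthwaite formula for two independent sample variances.
    """
    v = np.asarray(variances, dtype=float)
    f = np.asarray(dfs, dtype=float)
    a = np.ones_like(v) if coefs is None else np.asarray(coefs, dtype=float)
    num = (a @ v) ** 2
    den = np.sum((a * v) ** 2 / f)
    if den <= 0:
        raise FitError("degenerate variance components")
    return float(num / den)


# ---------------------------------------------------------------------------
# random-intercept mixed model (REML)


@dataclass
class MixedModelFit:
    """REML fit of y = X beta + animal intercept + noise."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_a: float
    sigma2_e: float
    loglik_reml: float
    converged: bool
    n_obs: int
    n_groups: int
    _X: np.ndarray = field(repr=False, default=None)
    _group_idx: np.ndarray = field(repr=False, default=None)

    def contrast(self, c) -> tuple[float, float]:
        """Estimate and sampling variance of c' beta."""
        c = np.asarray(c, dtype=float)
        return float(c @ self.beta), float(c @ self.cov_beta @ c)


def _reml_pieces(lam: float, y, X, group_idx, n_groups):
    n, p = X.shape
    W = np.eye(n)
    for g in range(n_groups):
        sel = group_idx == g
        W[np.ix_(sel, sel)] += lam
    try:
        L = np.linalg.cholesky(W)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise FitError("covariance not positive definite") from exc
    logdetW = 2.0 * np.log(np.diag(L)).sum()
    Wi_y = np.linalg.solve(W, y)
    Wi_X = np.linalg.solve(W, X)
    XtWiX = X.T @ Wi_X
    sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        raise FitError("X'W^-1X singular; check the design matrix")
    beta = np.linalg.solve(XtWiX, X.T @ Wi_y)
    resid_quad = float(y @ Wi_y - (X.T @ Wi_y) @ beta)
    return logdetW, logdetXtWiX, XtWiX, beta, resid_quad


def _reml_criterion(lam: float, y, X, group_idx, n_groups) -> float:
    n, p = X.shape
    logdetW, logdetXtWiX, _, _, quad = _reml_pieces(lam, y, X, group_idx, n_groups)
    quad = max(quad, 1e-300)
    return logdetW + logdetXtWiX + (n - p) * np.log(quad)


def fit_random_intercept(y, groups, X=None) -> MixedModelFit:
    """REML fit of a Gaussian one-random-intercept model.

    Parameters
    ----------
    y : observations (slide-level fat percentages).
    groups : animal label per observation.
    X : fixed-effect design matrix (defaults to an intercept column).

    The restricted likelihood is profiled down to the variance ratio
    lambda = sigma2_a / sigma2_e and optimized on a log grid with Brent's
    method (boundary lambda = 0 included), which is robust and accurate
    enough for closed-form balanced-case checks.
    """
    y = np.asarray(y, dtype=float)
    labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
    n = len(y)
    n_groups = len(labels)
    if n_groups < 2:
        raise FitError("need at least two animals")
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    p = X.shape[1]
    if n - p < 1:
        raise FitError("no residual degrees of freedom")

    if np.max(np.bincount(group_idx)) == 1:
        # one observation per animal: sigma2_a and sigma2_e are only jointly
        # identified; the model degenerates to OLS (lambda pinned at 0)
        lam = 0.0
        converged = True
    else:
        def crit_u(u):
            return _reml_criterion(np.exp(u), y, X, group_idx, n_groups)

        lo, hi = -30.0, 12.0
        with np.errstate(over="ignore"):
            res = optimize.minimize_scalar(crit_u, bounds=(lo, hi),
                                           method="bounded",
                                           options={"xatol": 1e-12})
        converged = bool(res.success)
        u_hat = float(res.x)
        crit_boundary = _reml_criterion(0.0, y, X, group_idx, n_groups)
        if crit_boundary <= res.fun + 1e-10 or u_hat <= lo + 1e-6:
            lam = 0.0
        else:
            lam = float(np.exp(u_hat))
    logdetW, logdetXtWiX, XtWiX, beta, quad = _reml_pieces(
        lam, y, X, group_idx, n_groups)
    sigma2_e = quad / (n - p)
    sigma2_a = lam * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(XtWiX)
    loglik = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2_e) + logdetW
                     + logdetXtWiX + (n - p))
    return MixedModelFit(beta=beta, cov_beta=cov_beta, sigma2_a=float(sigma2_a),
                         sigma2_e=float(sigma2_e), loglik_reml=float(loglik),
                         converged=converged, n_obs=n, n_groups=n_groups,
                         _X=X, _group_idx=group_idx)


def _model_matrices(fit: MixedModelFit):
    n = fit.n_obs
    X = fit._X
    V = fit.sigma2_e * np.eye(n)
    ZZt = np.zeros((n, n))
    for g in range(fit.n_groups):
        sel = fit._group_idx == g
        ZZt[np.ix_(sel, sel)] = 1.0
    V += fit.sigma2_a * ZZt
    Vi = np.linalg.inv(V)
    ViX = Vi @ X
    B = np.linalg.inv(X.T @ ViX)
    P = Vi - ViX @ B @ ViX.T
    return ZZt, Vi, ViX, B, P


def satterthwaite_df(fit: MixedModelFit, c) -> float:
    """Satterthwaite denominator df for the contrast c' beta.

    df = 2 Var(c'beta)^2 / Var[Var-hat(c'beta)], where the variance of the
    variance estimate comes from the inverse expected (REML) information of
    (sigma2_a, sigma2_e) by the delta method.  Reproduces the closed-form
    animal-minus-groups df exactly in balanced designs.
    """
    if not fit.converged:
        raise FitError("cannot compute df from a non-converged fit")
    c = np.asarray(c, dtype=float)
    ZZt, Vi, ViX, B, P = _model_matrices(fit)
    var_c = float(c @ B @ c)
    # gradient of Var(c'beta) w.r.t. (sigma2_a, sigma2_e)
    w = ViX @ B @ c
    if fit.sigma2_a == 0.0:
        # boundary fit: the intercept variance is pinned at zero, so the
        # model degenerates to OLS; use the residual component alone
        # (recovers df = N - p exactly)
        info_e = 0.5 * float(np.einsum("ij,ji->", P, P))
        var_var = float(w @ w) ** 2 / info_e
        if var_var <= 0:
            raise FitError("non-positive variance of the contrast variance")
        return 2.0 * var_c ** 2 / var_var
    grad = np.array([float(w @ ZZt @ w), float(w @ w)])
    # expected REML information I_jk = 0.5 tr(P Vj P Vk)
    PZ = P @ ZZt
    info = 0.5 * np.array([
        [np.einsum("ij,ji->", PZ, PZ), np.einsum("ij,ji->", PZ, P)],
        [np.einsum("ij,ji->", P, PZ), np.einsum("ij,ji->", P, P)],
    ])
    try:
        cov_theta = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular REML information matrix") from exc
    var_var = float(grad @ cov_theta @ grad)
    if var_var <= 0:
        raise FitError("non-positive variance of the contrast variance")
    return 2.0 * var_c ** 2 / var_var


def mixed_contrast_test(y, groups, is_a) -> tuple[float, float, float, float]:
    """Mixed-model two-cell contrast: (estimate a-b, t, df, p)."""
    y = np.asarray(y, dtype=float)
    is_a = np.asarray(is_a, dtype=float)
    X = np.column_stack([np.ones_like(y), is_a])
    fit = fit_random_intercept(y, groups, X)
    c = np.array([0.0, 1.0])
    est, var = fit.contrast(c)
    df = satterthwaite_df(fit, c)
    t = est / np.sqrt(var)
    p = 2.0 * sps.t.sf(abs(t), df)
    return est, t, df, p


# ---------------------------------------------------------------------------
# contrast plans over the slide table


@dataclass(frozen=True)
class Contrast:
    """Two cells of the (group, side, region) layout to compare."""

    label: str
    a: tuple[tuple[str, str], ...]
    b: tuple[tuple[str, str], ...]

    @staticmethod
    def of(label: str, a: dict, b: dict) -> "Contrast":
        return Contrast(label, tuple(sorted(a.items())), tuple(sorted(b.items())))


def default_contrast_plan() -> list[Contrast]:
    """The study's comparisons: sides within groups, electrode regions within
    sides, and matched cells across groups."""
    C = Contrast.of
    plan = [
        C("CT: nPCA vs cdPCA",
          dict(group="CT", side="nPCA"), dict(group="CT", side="cdPCA")),
    ]
    for g in ("SHAM", "DC04", "DC07"):
        plan += [
            C(f"{g}: nPCA el+ vs el++",
              dict(group=g, side="nPCA", region="el+"),
              dict(group=g, side="nPCA", region="el++")),
            C(f"{g}: cdPCA el+ vs el++",
              dict(group=g, side="cdPCA", region="el+"),
              dict(group=g, side="cdPCA", region="el++")),
            C(f"{g}: nPCA vs cdPCA (el+)",
              dict(group=g, side="nPCA", region="el+"),
              dict(group=g, side="cdPCA", region="el+")),
            C(f"{g}: nPCA vs cdPCA (el++)",
              dict(group=g, side="nPCA", region="el++"),
              dict(group=g, side="cdPCA", region="el++")),
        ]
    plan += [
        C("CT nPCA vs SHAM nPCA el++",
          dict(group="CT", side="nPCA"), dict(group="SHAM", side="nPCA", region="el++")),
        C("CT cdPCA vs SHAM cdPCA el++",
          dict(group="CT", side="cdPCA"), dict(group="SHAM", side="cdPCA", region="el++")),
        C("SHAM vs DC04 (cdPCA el++)",
          dict(group="SHAM", side="cdPCA", region="el++"),
          dict(group="DC04", side="cdPCA", region="el++")),
        C("SHAM vs DC07 (cdPCA el++)",
          dict(group="SHAM", side="cdPCA", region="el++"),
          dict(group="DC07", side="cdPCA", region="el++")),
        C("DC04 vs DC07 (nPCA el+)",
          dict(group="DC04", side="nPCA", region="el+"),
          dict(group="DC07", side="nPCA", region="el+")),
        C("DC04 vs DC07 (cdPCA el++)",
          dict(group="DC04", side="cdPCA", region="el++"),
          dict(group="DC07", side="cdPCA", region="el++")),
    ]
    return plan


def _select(df: pd.DataFrame, cell: tuple[tuple[str, str], ...]) -> pd.DataFrame:
    out = df
    for col, val in cell:
        out = out[out[col] == val]
    return out


def run_group_comparisons(slide_table: pd.DataFrame,
                          plan: list[Contrast] | None = None,
                          q_threshold: float = 0.1) -> pd.DataFrame:
    """Mixed-model p, Satterthwaite df, Cohen's d and BH q per contrast.

    ``slide_table`` needs columns animal, group, side, region, fat_percent
    (one method at a time).  Contrasts whose cells are empty, or with too
    few animals to fit, are skipped with a warning.  BH runs once across
    the whole plan.
    """
    plan = plan if plan is not None else default_contrast_plan()
    if "method" in slide_table.columns and slide_table["method"].nunique() > 1:
        raise ImfquantError("slide table mixes methods; filter to one first")
    rows = []
    for contrast in plan:
        da = _select(slide_table, contrast.a)
        db = _select(slide_table, contrast.b)
        if da.empty or db.empty:
            warnings.warn(f"contrast {contrast.label!r}: empty cell, skipped",
                          stacklevel=2)
            continue
        y = np.concatenate([da["fat_percent"].to_numpy(),
                            db["fat_percent"].to_numpy()])
        groups = np.concatenate([da["animal"].to_numpy(), db["animal"].to_numpy()])
        is_a = np.concatenate([np.ones(len(da)), np.zeros(len(db))])
        try:
            est, t, df, p = mixed_contrast_test(y, groups, is_a)
        except FitError as exc:
            warnings.warn(f"contrast {contrast.label!r}: {exc}; skipped",
                          stacklevel=2)
            continue
        try:
            d = cohens_d(summary_stats(da["fat_percent"]),
                         summary_stats(db["fat_percent"]))
            effect = classify_effect(d)
        except (EffectSizeError, ImfquantError):
            d, effect = np.nan, "undefined"
        rows.append(dict(contrast=contrast.label, estimate=est, t=t, df=df,
                         p=p, d=d, effect_class=effect,
                         n_a=len(da), n_b=len(db)))
    result = pd.DataFrame(rows)
    if not result.empty:
        result["q"] = bh_qvalues(result["p"].to_numpy())
        result["significant"] = result["q"] < q_threshold
        cols = ["contrast", "estimate", "t", "df", "p", "q", "d",
                "effect_class", "significant", "n_a", "n_b"]
        result = result[cols]
    return result
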