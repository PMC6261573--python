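"""Trial-level aggregation and variance-component statistics.

Per-crest resonance estimates come in as one row per trial.  The questions
asked of them mirror the original study design: how repeatable is a crest's
resonant frequency across trials (random-intercept linear mixed model,
adjusted repeatability), how much variance do sex, vibration orientation and
a morphological covariate explain (marginal R^2, AICc model ranking), and
how stiff are crests in bending (linear force-displacement fits).

The mixed model is a Gaussian random-intercept model fitted by
REML (or ML for information-criterion comparisons), optionally with
per-crest residual-variance multipliers (a heteroskedastic residual,
equivalent to an identity-variance-function weighting per group).  The
compound-symmetry structure of a random-intercept model admits closed-form
per-group matrix algebra, so the profiled (negative twice) log-likelihood is
cheap and is optimized directly over log-variance parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import (
    ConvergenceError,
    DesignError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)

Z_95 = 1.96  # 95% CI half-width in s.e.m. units


@dataclass
class TrialRecord:
    """One sweep trial's fitted resonance parameters plus metadata."""

    crest_id: str
    sex: str                 # "male" | "female"
    orientation: str         # "in_plane" | "out_of_plane"
    trial: int
    f_r: float
    delta_f: float
    sweep_rate: float = 1.33
    flag_area: float | None = None
    length: float | None = None
    width: float | None = None
    n_feathers: int | None = None
    pct_unaligned: float | None = None
    pct_short: float | None = None

    @property
    def Q(self) -> float:
        return self.f_r / self.delta_f


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dict(r.__dict__)
        d["Q"] = r.Q
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-crest and group summaries


def _ci_cols(vals: np.ndarray) -> tuple[float, float, float]:
    """mean, ci_lo, ci_hi with CI = mean +/- 1.96 * s.e.m.; NaN CI if n < 2."""
    mean = float(np.mean(vals))
    if len(vals) < 2:
        return mean, np.nan, np.nan
    sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
    return mean, mean - Z_95 * sem, mean + Z_95 * sem


def summarize_crests(
    df: pd.DataFrame,
    metrics: tuple[str, ...] = ("f_r", "delta_f", "Q"),
) -> dict[str, pd.DataFrame]:
    """Per-crest trial means and sex x orientation group means with 95% CIs.

    Group means are unweighted means of the per-crest means (each crest
    counts once regardless of its trial count), with CI = 1.96 x s.e.m.
    across crests.  Single-trial crests get a mean but no CI.
    """
    needed = {"crest_id", "sex", "orientation", *metrics}
    missing = needed - set(df.columns)
    if missing:
        raise InvalidParameterError(f"missing columns: {sorted(missing)}")

    per_rows = []
    for (cid, sex, orient), grp in df.groupby(
        ["crest_id", "sex", "orientation"], sort=True
    ):
        row = dict(crest_id=cid, sex=sex, orientation=orient, n_trials=len(grp))
        for m in metrics:
            mean, lo, hi = _ci_cols(grp[m].to_numpy(dtype=float))
            row[f"{m}_mean"], row[f"{m}_ci_lo"], row[f"{m}_ci_hi"] = mean, lo, hi
        per_rows.append(row)
    per_crest = pd.DataFrame(per_rows)

    grp_rows = []
    for (sex, orient), grp in per_crest.groupby(["sex", "orientation"], sort=True):
        row = dict(sex=sex, orientation=orient, n_crests=len(grp))
        for m in metrics:
            mean, lo, hi = _ci_cols(grp[f"{m}_mean"].to_numpy(dtype=float))
            row[f"{m}_mean"], row[f"{m}_ci_lo"], row[f"{m}_ci_hi"] = mean, lo, hi
        grp_rows.append(row)
    groups = pd.DataFrame(grp_rows)
    return {"per_crest": per_crest, "groups": groups}


# ---------------------------------------------------------------------------
# Random-intercept mixed model (REML/ML), optional heteroskedastic residuals


def _design_matrix(df: pd.DataFrame, fixed: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for c in fixed:
        v = df[c]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(v, prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
                names.append(dc)
        else:
            cols.append(v.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        for j in range(1, X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                collinear.append(names[j])
        raise DesignError(
            f"rank-deficient design: collinear columns {collinear}", collinear
        )
    return X, names


@dataclass
class VarianceModelFit:
    """Fitted random-intercept model for one response."""

    beta: pd.Series
    se_beta: pd.Series
    sigma2_id: float                 # among-crest variance
    sigma2_res: float                # base residual variance
    res_multipliers: pd.Series       # per-crest residual variance multipliers
    loglik: float
    reml: bool
    heteroskedastic: bool
    n_params: int                    # count of estimated parameters (ML sense)
    converged: bool
    response: str
    fixed: list[str] = field(default_factory=list)
    n_obs: int = 0
    # retained for bootstrap resimulation and marginal R^2
    X: np.ndarray | None = None
    group_labels: np.ndarray | None = None

    @property
    def sigma2_res_mean(self) -> float:
        """Mean per-crest residual variance (equals sigma2_res if homoskedastic)."""
        return float(self.sigma2_res * self.res_multipliers.mean())

    @property
    def linear_predictor(self) -> np.ndarray:
        return self.X @ self.beta.to_numpy()


def _neg2ll(
    theta: np.ndarray,
    y_groups: list[np.ndarray],
    X_groups: list[np.ndarray],
    het: bool,
    reml: bool,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Profiled -2 log-likelihood; returns (value, beta, XtViX)."""
    a = math.exp(theta[0])                      # sigma2_id
    s = math.exp(theta[1])                      # base sigma2_res
    G = len(y_groups)
    lam = np.ones(G)
    if het:
        lam[1:] = np.exp(theta[2:])             # first group's multiplier fixed at 1
    p = X_groups[0].shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    yViy = 0.0
    logdet = 0.0
    for g in range(G):
        yg, Xg = y_groups[g], X_groups[g]
        n_g = len(yg)
        s_g = s * lam[g]
        c = a / (s_g * (s_g + n_g * a))         # V^-1 = I/s_g - c * J
        ones_X = Xg.sum(axis=0)
        ones_y = yg.sum()
        XtViX += Xg.T @ Xg / s_g - c * np.outer(ones_X, ones_X)
        XtViy += Xg.T @ yg / s_g - c * ones_X * ones_y
        yViy += yg @ yg / s_g - c * ones_y**2
        logdet += n_g * math.log(s_g) + math.log1p(n_g * a / s_g)
    beta = np.linalg.solve(XtViX, XtViy)
    quad = yViy - beta @ XtViy
    N = sum(len(yg) for yg in y_groups)
    val = logdet + quad
    if reml:
        sign, ld2 = np.linalg.slogdet(XtViX)
        val += ld2 + (N - p) * math.log(2 * math.pi)
    else:
        val += N * math.log(2 * math.pi)
    return val, beta, XtViX


def fit_variance_model(
    df: pd.DataFrame,
    response: str,
    fixed: list[str] | None = None,
    group_col: str = "crest_id",
    heteroskedastic: bool = False,
    reml: bool = True,
    tol: float = 1e-6,
    min_groups: int = 5,
    polish: bool = True,
) -> VarianceModelFit:
    """REML (or ML) fit of response = fixed effects + crest intercept + residual.

    With ``heteroskedastic=True`` each crest gets its own residual-variance
    multiplier (the first crest's fixed at 1 for identifiability), profiled
    jointly with the variance components.
    """
    fixed = list(fixed or [])
    labels = df[group_col].to_numpy()
    groups = pd.unique(labels)
    if len(groups) < min_groups:
        raise InsufficientDataError(f"need >= {min_groups} groups, got {len(groups)}")
    X, names = _design_matrix(df, fixed)
    y = df[response].to_numpy(dtype=float)
    y_groups = [y[labels == g] for g in groups]
    X_groups = [X[labels == g] for g in groups]

    # method-of-moments start
    grp_means = np.array([yg.mean() for yg in y_groups])
    within = np.concatenate([yg - yg.mean() for yg in y_groups])
    s0 = max(float(np.var(within, ddof=len(groups))), 1e-8 * max(np.var(y), 1e-12))
    nbar = np.mean([len(yg) for yg in y_groups])
    a0 = max(float(np.var(grp_means, ddof=1)) - s0 / nbar, s0 * 1e-3)
    theta0 = [math.log(a0), math.log(s0)]
    if heteroskedastic:
        theta0 += [0.0] * (len(groups) - 1)
    theta0 = np.asarray(theta0)

    def objective(theta):
        try:
            return _neg2ll(theta, y_groups, X_groups, heteroskedastic, reml)[0]
        except (np.linalg.LinAlgError, OverflowError):
            return np.inf

    scale_ref = math.log(max(np.var(y), 1e-12))
    bounds = [(scale_ref - 40.0, scale_ref + 10.0)] * 2
    if heteroskedastic:
        bounds += [(-15.0, 15.0)] * (len(groups) - 1)
    res = minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                   options=dict(ftol=1e-14, gtol=tol * 1e-3, maxiter=5000))
    success = bool(res.success)
    if polish:
        # the REML surface is smooth; a short Nelder-Mead pass removes the
        # residual O(1e-6) parameter error left by the quasi-Newton line search
        res2 = minimize(objective, res.x, method="Nelder-Mead",
                        options=dict(xatol=1e-9, fatol=1e-12, maxiter=10_000))
        if res2.fun <= res.fun:
            res = res2
        success = success or bool(res2.success)
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"variance model failed to converge at {res.x}")

    val, beta, XtViX = _neg2ll(res.x, y_groups, X_groups, heteroskedastic, reml)
    a = math.exp(res.x[0])
    s = math.exp(res.x[1])
    lam = np.ones(len(groups))
    if heteroskedastic:
        lam[1:] = np.exp(res.x[2:])
    if a < 1e-8 * (a + s):  # boundary: among-group variance indistinguishable from 0
        a = 0.0
    cov_beta = np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    G = len(groups)
    n_params = X.shape[1] + 2 + (G - 1 if heteroskedastic else 0)
    return VarianceModelFit(
        beta=pd.Series(beta, index=names),
        se_beta=pd.Series(se, index=names),
        sigma2_id=float(a),
        sigma2_res=float(s),
        res_multipliers=pd.Series(lam, index=list(groups)),
        loglik=float(-0.5 * val),
        reml=reml,
        heteroskedastic=heteroskedastic,
        n_params=n_params,
        converged=success,
        response=response,
        fixed=fixed,
        n_obs=len(y),
        X=X,
        group_labels=labels,
    )


@dataclass
class Repeatability:
    value: float
    ci_low: float
    ci_high: float
    n_boot: int
    boundary: bool = False


def adjusted_repeatability(
    fit: VarianceModelFit,
    n_boot: int = 1000,
    seed: int | None = None,
) -> Repeatability:
    """Among-crest variance fraction after adjusting for the fixed effects.

    R = sigma2_id / (sigma2_id + mean per-crest residual variance), with a
    seeded parametric-bootstrap percentile CI (resimulate from the fitted
    model, refit, repeat).
    """
    if not fit.converged:
        raise ConvergenceError("repeatability requires a converged fit")
    denom = fit.sigma2_id + fit.sigma2_res_mean
    R = fit.sigma2_id / denom if denom > 0 else 0.0
    boundary = fit.sigma2_id == 0.0
    if boundary:
        warnings.warn("sigma2_id at boundary 0: repeatability CI is degenerate",
                      RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    labels = fit.group_labels
    groups = list(fit.res_multipliers.index)
    mu = fit.linear_predictor
    boot_R = []
    df_boot = pd.DataFrame({"_group": labels})
    for _ in range(n_boot):
        b = rng.normal(0.0, math.sqrt(fit.sigma2_id), size=len(groups))
        y_star = mu.copy()
        for gi, g in enumerate(groups):
            m = labels == g
            sd_g = math.sqrt(fit.sigma2_res * fit.res_multipliers[g])
            y_star[m] += b[gi] + rng.normal(0.0, sd_g, size=m.sum())
        dfb = df_boot.copy()
        dfb["_y"] = y_star
        Xdf = pd.DataFrame(fit.X[:, 1:],
                           columns=[f"_x{i}" for i in range(fit.X.shape[1] - 1)])
        dfb = pd.concat([dfb.reset_index(drop=True), Xdf], axis=1)
        try:
            bf = fit_variance_model(
                dfb, "_y", fixed=list(Xdf.columns), group_col="_group",
                heteroskedastic=fit.heteroskedastic, reml=fit.reml,
                polish=False,
            )
        except (ConvergenceError, np.linalg.LinAlgError):
            continue
        d = bf.sigma2_id + bf.sigma2_res_mean
        boot_R.append(bf.sigma2_id / d if d > 0 else 0.0)
    if boot_R:
        lo, hi = np.percentile(boot_R, [2.5, 97.5])
    else:
        lo = hi = np.nan
    return Repeatability(value=float(R), ci_low=float(lo), ci_high=float(hi),
                         n_boot=len(boot_R), boundary=boundary)


def marginal_r2(fit: VarianceModelFit) -> float:
    """Proportion of total variance explained by the fixed effects.

    var(X beta) / (var(X beta) + sigma2_id + mean residual variance); the
    linear-predictor variance is the population variance over the observed
    design rows.
    """
    if not fit.converged:
        raise ConvergenceError("marginal R^2 requires a converged fit")
    v_fix = float(np.var(fit.linear_predictor))
    return v_fix / (v_fix + fit.sigma2_id + fit.sigma2_res_mean)


def aicc_rank(fits: list[VarianceModelFit], n: int) -> pd.DataFrame:
    """Small-sample AIC ranking of ML fits on identical data.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); ascending, with delta to best.
    REML fits are rejected: their likelihoods are not comparable across
    fixed-effect structures.
    """
    if not fits:
        raise InvalidParameterError("no fits to rank")
    rows = []
    for f in fits:
        if f.reml:
            raise InvalidParameterError("aicc_rank requires ML fits (reml=False)")
        k = f.n_params
        if n <= k + 1:
            raise InvalidParameterError(
                f"AICc correction undefined: n={n} <= k+1={k + 1}"
            )
        aicc = -2.0 * f.loglik + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)
        rows.append(dict(model="+".join(f.fixed) or "(intercept)",
                         response=f.response, k=k, loglik=f.loglik, aicc=aicc))
    table = pd.DataFrame(rows).sort_values(["aicc", "k"], kind="stable")
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bending stiffness


@dataclass
class BendingFit:
    """Linear force-displacement fit over the detected linear range."""

    k: float                # bending spring constant, N/mm
    linear_range_mm: float
    r2_adj: float
    intercept: float        # N
    n_points_used: int


def _linear_r2_adj(d: np.ndarray, F: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(d, F, 1)
    resid = F - (slope * d + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n = len(d)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), float(intercept), r2_adj


def fit_bending_trial(
    displacement_mm: np.ndarray,
    force_n: np.ndarray,
    r2_floor: float = 0.98,
    min_points: int = 5,
) -> BendingFit:
    """Largest initial displacement span that is linear, and its spring constant.

    Points are taken in order of increasing displacement from the zero-force
    onset.  The window grows one point at a time and stops when the next
    point departs from the current straight-line fit by more than 4x the
    in-window residual scatter (a global R^2 floor alone cannot localize a
    softening breakpoint: a long linear run keeps R^2 high well past it).
    The final window must reach adjusted R^2 >= ``r2_floor`` (default
    calibrated so typical crest data, adj-R^2 ~ 0.98, counts as linear); the
    slope over that window is the spring constant k.
    """
    d = np.asarray(displacement_mm, dtype=float)
    F = np.asarray(force_n, dtype=float)
    if d.shape != F.shape:
        raise InvalidParameterError("displacement and force must share length")
    order = np.argsort(d, kind="stable")
    d, F = d[order], F[order]
    if len(d) < min_points:
        raise InsufficientDataError(f"need >= {min_points} points, got {len(d)}")
    scale = float(np.max(np.abs(F))) or 1.0
    m = min_points
    while m < len(d):
        slope, intercept, _ = _linear_r2_adj(d[:m], F[:m])
        resid = F[:m] - (slope * d[:m] + intercept)
        rms = float(np.sqrt(np.mean(resid**2)))
        tol_abs = max(4.0 * rms, 1e-6 * scale)
        if abs(F[m] - (slope * d[m] + intercept)) > tol_abs:
            break
        m += 1
    slope, intercept, r2_adj = _linear_r2_adj(d[:m], F[:m])
    if r2_adj < r2_floor:
        raise FitFailureError(
            f"initial range of {m} points only reaches adjusted R^2 "
            f"{r2_adj:.3f} < {r2_floor}"
        )
    if slope <= 0:
        raise FitFailureError("non-positive slope in candidate linear range")
    return BendingFit(k=slope, linear_range_mm=float(d[m - 1] - d[0]),
                      r2_adj=r2_adj, intercept=intercept, n_points_used=m)


def fit_bending(
    trials: list[tuple[np.ndarray, np.ndarray]],
    r2_floor: float = 0.98,
) -> list[BendingFit]:
    """Fit each (displacement_mm, force_n) trial; one BendingFit per trial."""
    return [fit_bending_trial(d, F, r2_floor=r2_floor) for d, F in trials]
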