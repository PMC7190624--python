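"""Model fitting: snowmelt-lag mixed models, conditional-logit step
selection, AIC comparison, and the collinearity screen.

The step-selection model is the exact (fixed-effects) conditional
logistic likelihood

    l(beta) = sum_s [ beta.x_chosen - log sum_j exp(beta.x_j) ]

maximised by Newton's method with analytic gradient and Hessian;
standard errors come from the observed information, with individual-level
cluster-robust (sandwich) errors available as the stand-in for a
stratum-in-individual random effect.  The lag models regress an
environmental value on lag day with random intercepts for individual
and, when identifiable, year nested in individual: Gaussian responses
via ML linear mixed models, binary snow via a Laplace-approximate
binomial GLMM with a random intercept per individual-year group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess1

log = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """A fitted model with enough metadata for AIC comparison."""

    name: str
    response: str
    predictors: list
    params: pd.Series
    se: pd.Series
    loglik: float
    k_params: int
    n: int
    grouping: str = "none"
    vcov: np.ndarray | None = field(default=None, repr=False)
    flags: dict = field(default_factory=dict)

    @property
    def aic(self):
        return 2.0 * self.k_params - 2.0 * self.loglik

    def z_values(self):
        return self.params / self.se

    def to_dict(self):
        return {"name": self.name, "response": self.response,
                "predictors": list(self.predictors),
                "coef": self.params.to_dict(), "se": self.se.to_dict(),
                "loglik": float(self.loglik), "k": int(self.k_params),
                "aic": float(self.aic), "n": int(self.n), "grouping": self.grouping,
                "flags": self.flags}


class SeparationError(RuntimeError):
    """A predictor perfectly discriminates chosen from alternatives."""


# ---------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------

def _stratum_structure(strata: pd.DataFrame):
    df = strata.sort_values("stratum", kind="mergesort").reset_index(drop=True)
    codes, _ = pd.factorize(df["stratum"], sort=False)
    starts = np.r_[0, 1 + np.nonzero(np.diff(codes))[0]]
    return df, codes, starts


def conditional_loglik(beta, X, y, starts):
    """Exact conditional-logit log-likelihood at ``beta`` (oracle-friendly)."""
    eta = X @ np.asarray(beta, dtype=float)
    mx = np.maximum.reduceat(eta, starts)
    counts = np.diff(np.r_[starts, eta.size])
    lse = mx + np.log(np.add.reduceat(np.exp(eta - np.repeat(mx, counts)), starts))
    return float(eta[y == 1].sum() - lse.sum())


def fit_conditional_logit(strata: pd.DataFrame, predictors: list,
                          cluster_robust: bool = False, name: str = "ssf",
                          tol: float = 1e-8, max_iter: int = 100) -> ModelFit:
    """Fit the step-selection conditional logit by Newton's method.

    ``strata`` is the long format from :func:`snowtrack.ssf.build_strata`
    (columns ``stratum``, ``case``, the predictors, and ``individual``
    when cluster-robust errors are requested).  Predictors without
    within-stratum variation are dropped with a warning (conditioning
    removes stratum constants); perfect separation raises
    :class:`SeparationError` naming the offending predictor.
    """
    df, codes, starts = _stratum_structure(strata.dropna(subset=list(predictors)))
    n_strata = starts.size
    if n_strata < 2:
        raise ValueError("need at least 2 strata")
    y = df["case"].to_numpy()
    counts = np.diff(np.r_[starts, len(df)])
    if not np.all(np.add.reduceat(y, starts) == 1):
        raise ValueError("each stratum must contain exactly one chosen endpoint")

    # drop predictors with no within-stratum variation
    keep = []
    for p in predictors:
        v = df[p].to_numpy(dtype=float)
        centered = v - np.repeat(np.add.reduceat(v, starts) / counts, counts)
        if np.max(np.abs(centered)) < 1e-12:
            warnings.warn(f"predictor {p!r} has no within-stratum variation; dropped",
                          stacklevel=2)
        else:
            keep.append(p)
    null_ll = float(-np.log(counts).sum())
    if not keep:
        return ModelFit(name, "case", [], pd.Series(dtype=float), pd.Series(dtype=float),
                        null_ll, 0, len(df), "conditional (stratum)",
                        flags={"null_model": True, "n_strata": int(n_strata)})

    X = df[keep].to_numpy(dtype=float)
    p = X.shape[1]
    beta = np.zeros(p)
    ll = conditional_loglik(beta, X, y, starts)
    for it in range(max_iter):
        eta = X @ beta
        mx = np.repeat(np.maximum.reduceat(eta, starts), counts)
        ex = np.exp(eta - mx)
        denom = np.repeat(np.add.reduceat(ex, starts), counts)
        w = ex / denom
        grad = X.T @ (y - w)
        A = X * w[:, None]
        M = np.add.reduceat(A, starts, axis=0)       # per-stratum weighted mean * 1
        info = X.T @ A - M.T @ M                     # observed information (PSD)
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"singular information matrix for predictors {keep}") from e
        # step-halving keeps the Newton update an ascent step even when
        # the information is nearly singular
        for _ in range(30):
            cand = beta + step
            ll_new = conditional_loglik(cand, X, y, starts)
            if ll_new >= ll - 1e-10:
                break
            step = step / 2.0
        beta, ll = cand, ll_new
        # a coefficient running past e^15 odds while the likelihood still
        # improves has no finite MLE
        if np.max(np.abs(beta)) > 15.0:
            worst = keep[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"divergence while fitting: predictor {worst!r} appears to separate "
                f"chosen from alternative endpoints")
    else:
        warnings.warn("conditional logit: Newton did not reach gradient tolerance",
                      stacklevel=2)

    vcov = np.linalg.inv(info)
    grouping = "conditional (stratum)"
    if cluster_robust:
        if "individual" not in df.columns:
            raise ValueError("cluster-robust errors need an 'individual' column")
        xbar = np.repeat(M, counts, axis=0)
        score_rows = (X - xbar)[y == 1]             # per-stratum score at beta-hat
        clus = pd.factorize(df.loc[y == 1, "individual"])[0]
        meat = np.zeros((p, p))
        for c in np.unique(clus):
            g = score_rows[clus == c].sum(axis=0)
            meat += np.outer(g, g)
        vcov = vcov @ meat @ vcov
        grouping = "conditional (stratum), cluster-robust by individual"
    se = np.sqrt(np.diag(vcov))
    ll = conditional_loglik(beta, X, y, starts)
    return ModelFit(name, "case", keep, pd.Series(beta, index=keep),
                    pd.Series(se, index=keep), ll, p, len(df), grouping, vcov,
                    flags={"n_strata": int(n_strata), "null_loglik": null_ll,
                           "dropped": [q for q in predictors if q not in keep]})


# ---------------------------------------------------------------------
# lag ("follow the snowmelt") mixed models
# ---------------------------------------------------------------------

def _lag_frame(lag_table: pd.DataFrame, response_variable: str) -> pd.DataFrame:
    df = lag_table[(lag_table["variable"] == response_variable)
                   & (~lag_table["value"].isna())].copy()
    if df.empty:
        raise ValueError(f"no rows for variable {response_variable!r}")
    if "year" not in df.columns:
        df["year"] = pd.to_datetime(df["date"]).dt.year
    return df


def fit_lag_model(lag_table: pd.DataFrame, response_variable: str,
                  family: str | None = None, name: str | None = None,
                  include_slope: bool = True) -> ModelFit:
    """Regress an environmental value on lag day with random intercepts.

    The fixed effect of interest is the per-day slope over the -10..+10
    day window; individuals (and years within individuals, when more
    than one year per individual is observed) get random intercepts.
    ``family`` defaults to binomial for snow and gaussian otherwise.
    ``include_slope=False`` fits the intercept-only reduced model used
    for the delta-AIC evaluation of the day effect.
    """
    if family is None:
        family = "binomial" if response_variable == "snow" else "gaussian"
    df = _lag_frame(lag_table, response_variable)
    name = name or f"lag_{response_variable}" + ("" if include_slope else "_null")
    y = df["value"].to_numpy(dtype=float)
    lag = df["lag"].to_numpy(dtype=float)
    n = len(df)
    fe_names = ["Intercept"] + (["lag"] if include_slope else [])

    if np.ptp(y) == 0.0:
        warnings.warn(f"{response_variable}: response is constant; degenerate fit",
                      stacklevel=2)
        params = pd.Series({"Intercept": float(y[0]), "lag": 0.0})
        se = pd.Series({"Intercept": 0.0, "lag": np.nan})
        return ModelFit(name, response_variable, ["lag"], params, se,
                        loglik=np.nan, k_params=2, n=n, flags={"degenerate": True})

    groups = df["individual"].astype(str)
    if groups.nunique() < 2:
        return _lag_fixed_effects(df, y, lag, family, name, response_variable, fe_names)

    multi_year = df.groupby("individual")["year"].nunique().max() > 1
    if family == "gaussian":
        data = pd.DataFrame({"value": y, "lag": lag,
                             "individual": groups.to_numpy(),
                             "year": df["year"].astype(str).to_numpy()})
        formula = "value ~ lag" if include_slope else "value ~ 1"
        if multi_year:
            model = MixedLM.from_formula(formula, groups="individual",
                                         re_formula="1",
                                         vc_formula={"year": "0 + C(year)"},
                                         data=data)
            grouping = "individual + year-in-individual (random intercepts)"
            k_var = 2
        else:
            model = MixedLM.from_formula(formula, groups="individual",
                                         re_formula="1", data=data)
            grouping = "individual (random intercept; single year per individual)"
            k_var = 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=False)
            except np.linalg.LinAlgError:
                res = model.fit(reml=False, method="cg")
        params = pd.Series(np.asarray(res.fe_params), index=fe_names)
        se = pd.Series(np.asarray(res.bse_fe), index=fe_names)
        k = len(fe_names) + k_var + 1  # fixed effects + variance components + residual
        return ModelFit(name, response_variable, fe_names[1:], params, se,
                        float(res.llf), k, n, grouping,
                        flags={"converged": bool(res.converged)})

    if family == "binomial":
        gkey = (groups + "/" + df["year"].astype(str)) if multi_year else groups
        X = np.column_stack([np.ones_like(lag)] + ([lag] if include_slope else []))
        return _fit_binomial_laplace(y, X, fe_names, gkey, name, response_variable)
    raise ValueError(f"unknown family {family!r}")


def _lag_fixed_effects(df, y, lag, family, name, response_variable, fe_names):
    import statsmodels.api as sm
    warnings.warn("fewer than 2 individuals: falling back to a fixed-effects fit",
                  stacklevel=3)
    X = np.column_stack([np.ones_like(lag)] + ([lag] if "lag" in fe_names else []))
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        k = len(fe_names) + 1
    else:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        k = len(fe_names)
    params = pd.Series(np.asarray(res.params), index=fe_names)
    se = pd.Series(np.asarray(res.bse), index=fe_names)
    return ModelFit(name, response_variable, fe_names[1:], params, se, float(res.llf),
                    k, len(df), "none (fixed-effects fallback)",
                    flags={"fallback": True})


def _fit_binomial_laplace(y, X, fe_names, group_keys, name, response_variable):
    """Random-intercept binomial GLMM via a per-group Laplace approximation.

    The marginal likelihood factorises over groups; within a group the
    scalar random intercept is profiled by Newton and the integral
    replaced by its Laplace approximation
    ``ll_g = h(b_hat) - 0.5 log(sigma2 * (-h''(b_hat)))``.
    """
    codes, _ = pd.factorize(group_keys)
    p = X.shape[1]
    group_idx = [np.nonzero(codes == g)[0] for g in range(codes.max() + 1)]

    def group_laplace(Xg, yg, beta, sigma2):
        b = 0.0
        base = Xg @ beta
        for _ in range(50):
            eta = base + b
            pr = 1.0 / (1.0 + np.exp(-eta))
            g1 = np.sum(yg - pr) - b / sigma2
            g2 = -np.sum(pr * (1 - pr)) - 1.0 / sigma2
            step = g1 / g2
            b -= step
            if abs(step) < 1e-10:
                break
        eta = base + b
        pr = 1.0 / (1.0 + np.exp(-eta))
        h = np.sum(yg * eta - np.log1p(np.exp(eta))) - b * b / (2 * sigma2)
        h2 = -np.sum(pr * (1 - pr)) - 1.0 / sigma2
        return h - 0.5 * np.log(sigma2 * (-h2))

    def negll(theta):
        beta = theta[:p]
        sigma2 = np.exp(theta[p])
        return -sum(group_laplace(X[idx], y[idx], beta, sigma2) for idx in group_idx)

    # GLM start for the fixed effects
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    theta0 = np.r_[np.asarray(glm.params), 0.0]
    opt = optimize.minimize(negll, theta0, method="L-BFGS-B")
    theta = opt.x
    ll = -float(opt.fun)
    H = approx_hess1(theta, negll)
    try:
        vcov = np.linalg.inv(H)
        se_vec = np.sqrt(np.clip(np.diag(vcov)[:p], 0, None))
    except np.linalg.LinAlgError:
        vcov, se_vec = None, np.full(p, np.nan)
    params = pd.Series(theta[:p], index=fe_names)
    se = pd.Series(se_vec, index=fe_names)
    return ModelFit(name, response_variable, fe_names[1:], params, se, ll, p + 1,
                    y.size, "individual-year (random intercept, Laplace)", vcov,
                    flags={"converged": bool(opt.success),
                           "sigma2": float(np.exp(theta[p]))})


# ---------------------------------------------------------------------
# model comparison and collinearity screen
# ---------------------------------------------------------------------

@dataclass
class ModelComparison:
    table: pd.DataFrame  # name, aic, delta_aic, weight, different

    def best(self):
        return self.table.iloc[0]["name"]


def compare_models(fits: list[ModelFit]) -> ModelComparison:
    """Rank candidate fits by AIC: delta-AIC and Akaike weights.

    All candidates must be fit to the same rows (equal n).  A candidate
    is flagged ``different`` from the best model only when its delta-AIC
    strictly exceeds 2.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits are on differing row counts: {sorted(ns)}")
    aic = np.array([f.aic for f in fits], dtype=float)
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    tab = pd.DataFrame({"name": [f.name for f in fits], "k": [f.k_params for f in fits],
                        "loglik": [f.loglik for f in fits], "aic": aic,
                        "delta_aic": delta, "weight": w,
                        "different": delta > 2.0})
    tab = tab.sort_values("delta_aic", kind="mergesort").reset_index(drop=True)
    return ModelComparison(tab)


def screen_collinearity(strata: pd.DataFrame, predictors: list,
                        threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations among predictors.

    Pairs with |r| >= threshold are flagged for exclusion from a joint
    model; zero-variance predictors yield undefined correlations and are
    flagged too.
    """
    if len(strata) < 3:
        raise ValueError("need >= 3 rows for a correlation screen")
    rows = []
    for i, a in enumerate(predictors):
        for b in predictors[i + 1:]:
            va = strata[a].to_numpy(dtype=float)
            vb = strata[b].to_numpy(dtype=float)
            if np.std(va) == 0 or np.std(vb) == 0:
                rows.append({"var_a": a, "var_b": b, "r": np.nan,
                             "flagged": True, "reason": "zero variance"})
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            rows.append({"var_a": a, "var_b": b, "r": r,
                         "flagged": abs(r) >= threshold,
                         "reason": "correlated" if abs(r) >= threshold else ""})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "flagged", "reason"])
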