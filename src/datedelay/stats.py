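"""Behavioural statistics: paired tests, repeated-measures ANOVA, Holm
correction, regression and the mixed-effects choice model.

Effect sizes follow the paired-design conventions: g_av is the mean paired
difference divided by the average of the two condition SDs, with the Hedges
small-sample correction; ANOVA effects report partial eta squared
SS_effect/(SS_effect + SS_error).  All within-subject designs here have
2-level factors, so every ANOVA effect is a 1-df contrast and is computed
as the squared paired t of the per-participant contrast scores (exact for
such designs, no sphericity correction needed).

The mixed-effects logistic choice model (choice of the larger-later option
on condition, Δreward, Δtime and their interactions, with a participant
random intercept) is estimated by maximum likelihood with Gauss-Hermite
quadrature over the random effect.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PairedTestResult",
    "AnovaResult",
    "MixedChoiceModel",
    "paired_t",
    "rm_anova",
    "holm_adjust",
    "dde_regression",
    "mixed_choice_fit",
    "paired_t_power_n",
    "pearson_matrix",
]


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    g_av: float
    mean_diff: float
    ci: tuple[float, float]
    sides: str = "two-sided"


def paired_t(x, y, sides: str = "two-sided",
             ci_level: float = 0.95) -> PairedTestResult:
    """Paired-sample t-test of x - y with the averaged-SD Hedges g.

    ``sides``: "two-sided", "less" (mean difference < 0) or "greater".
    Zero within-pair variance with a non-zero shift yields t = +/-inf.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    d = x - y
    n = d.size
    df = n - 1
    md = d.mean()
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        t = 0.0 if md == 0 else np.copysign(np.inf, md)
        warnings.warn("zero within-pair variance", UserWarning, stacklevel=2)
        p = (1.0 if md == 0 else 0.0) if sides != "two-sided" else \
            (1.0 if md == 0 else 0.0)
    else:
        t = md / (sd_d / np.sqrt(n))
        if sides == "two-sided":
            p = 2 * sps.t.sf(abs(t), df)
        elif sides == "less":
            p = sps.t.cdf(t, df)
        elif sides == "greater":
            p = sps.t.sf(t, df)
        else:
            raise ValueError("sides must be two-sided/less/greater")
    sd_av = 0.5 * (x.std(ddof=1) + y.std(ddof=1))
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    g_av = 0.0 if sd_av == 0 else correction * md / sd_av
    half = sps.t.ppf(0.5 + ci_level / 2, df) * sd_d / np.sqrt(n)
    return PairedTestResult(t=float(t), df=df, p=float(p), g_av=float(g_av),
                            mean_diff=float(md), ci=(md - half, md + half),
                            sides=sides)


@dataclass
class AnovaResult:
    """Per-effect F table for a fully within-subject 2^k design."""

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def rm_anova(data: pd.DataFrame, dv: str, within: list[str],
             subject: str = "participant") -> AnovaResult:
    """Repeated-measures ANOVA for 2-level within-subject factors.

    ``data`` is long-format; every factor in ``within`` must have exactly
    two levels.  Participants with missing cells are removed listwise (with
    a log entry).  Each effect is a 1-df within-subject contrast; F = t^2 of
    the per-participant contrast scores and partial eta squared is
    t^2/(t^2 + df_error).
    """
    df = data[[subject, dv] + list(within)].dropna()
    levels = {f: sorted(df[f].unique()) for f in within}
    for f, lv in levels.items():
        if len(lv) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels")
    cells = df.groupby([subject] + list(within))[dv].mean().unstack(within)
    n_cells = int(np.prod([2] * len(within)))
    complete = cells.dropna()
    if len(complete) < len(cells):
        logger.info("rm_anova: removed %d participant(s) with missing cells",
                    len(cells) - len(complete))
    if len(complete) < 3:
        raise ValueError("need >= 3 participants with complete cells")
    # code each cell +/-1 per factor
    combos = list(itertools.product(*[levels[f] for f in within]))
    codes = {f: {levels[f][0]: -1.0, levels[f][1]: 1.0} for f in within}
    rows = []
    for r in range(1, len(within) + 1):
        for effect in itertools.combinations(within, r):
            w = []
            for combo in combos:
                c = 1.0
                for f, lev in zip(within, combo):
                    if f in effect:
                        c *= codes[f][lev]
                w.append(c)
            col_index = (complete.columns if len(within) > 1
                         else list(complete.columns))
            weights = pd.Series(w, index=pd.MultiIndex.from_tuples(combos,
                                names=within) if len(within) > 1
                                else [c[0] for c in combos])
            scores = (complete * weights.reindex(complete.columns)).sum(axis=1) / n_cells
            n = len(scores)
            m, sd = scores.mean(), scores.std(ddof=1)
            if sd == 0:
                t = 0.0 if m == 0 else np.copysign(np.inf, m)
            else:
                t = m / (sd / np.sqrt(n))
            F = t ** 2
            df_den = n - 1
            p = sps.f.sf(F, 1, df_den) if np.isfinite(F) else 0.0
            rows.append({"effect": ":".join(effect), "F": F, "df_num": 1,
                         "df_den": df_den, "p": p,
                         "partial_eta_sq": F / (F + df_den)
                         if np.isfinite(F) else 1.0})
    return AnovaResult(pd.DataFrame(rows).set_index("effect"))


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def dde_regression(dde, delta_payne, delta_focus) -> dict:
    """OLS of the date/delay effect on strategy-index difference measures.

    Predictors and outcome are the per-participant condition differences
    (date - delay).  Reports standardised betas, their t/p values, R^2 and
    the model F-test p.
    """
    import statsmodels.api as sm

    y = np.asarray(dde, dtype=float)
    X = np.column_stack([np.asarray(delta_payne, float),
                         np.asarray(delta_focus, float)])
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[keep], X[keep]

    def z(v):
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    Xz = np.column_stack([z(X[:, 0]), z(X[:, 1])])
    yz = z(y)
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    return {"beta": dict(zip(["delta_payne", "delta_focus"],
                             model.params[1:])),
            "t": dict(zip(["delta_payne", "delta_focus"], model.tvalues[1:])),
            "p": dict(zip(["delta_payne", "delta_focus"], model.pvalues[1:])),
            "r_squared": float(model.rsquared),
            "model_p": float(model.f_pvalue),
            "n": int(y.size)}


# ---------------------------------------------------------------------------
# mixed-effects logistic choice model

@dataclass
class MixedChoiceModel:
    """Random-intercept logistic model of LLR choice."""

    coef: pd.DataFrame            # index term; columns estimate, se, z, p
    sigma_u: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        eta = X @ self.coef["estimate"].to_numpy()
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


_TERMS = ("intercept", "condition", "d_reward", "d_time",
          "condition:d_reward", "condition:d_time", "d_reward:d_time",
          "condition:d_reward:d_time")


def _design(trials: pd.DataFrame, absolute: bool, terms=_TERMS):
    cond = np.where(trials["condition"].to_numpy() == "date", 1.0, -1.0)
    dr = trials["llr_amount"].to_numpy(float) - trials["sir_amount"].to_numpy(float)
    dt = trials["delay_days"].to_numpy(float)  # SIR delay is 0
    if absolute:
        dr, dt = np.abs(dr), np.abs(dt)
    dr = (dr - dr.mean()) / dr.std(ddof=1)
    dt = (dt - dt.mean()) / dt.std(ddof=1)
    cols = {"intercept": np.ones_like(cond), "condition": cond,
            "d_reward": dr, "d_time": dt, "condition:d_reward": cond * dr,
            "condition:d_time": cond * dt, "d_reward:d_time": dr * dt,
            "condition:d_reward:d_time": cond * dr * dt}
    return np.column_stack([cols[t] for t in terms])


def _gh_negll_grad(p, X, y, group_idx, n_groups, nodes, weights,
                   penalty: float = 0.0):
    """Negative marginal log-likelihood and its gradient.

    The random intercept is integrated out per participant with
    Gauss-Hermite quadrature; the gradient follows from differentiating
    under the (finite) quadrature sum, with node responsibilities
    p_gq = softmax_q(log w_q + per-group log-likelihood at node q).
    """
    k = X.shape[1]
    beta, log_sigma = p[:k], p[k]
    # clip keeps line-search excursions finite; the optimum is far inside
    sigma = np.exp(np.clip(log_sigma, -10.0, 5.0))
    eta = X @ beta                                  # (N,)
    u = np.sqrt(2.0) * sigma * nodes                # (Q,)
    z = np.clip(eta[None, :] + u[:, None], -700, 700)
    ll_obs = np.where(y[None, :] == 1.0, -np.logaddexp(0, -z),
                      -np.logaddexp(0, z))          # (Q, N)
    per_group = np.zeros((len(nodes), n_groups))
    np.add.at(per_group.T, group_idx, ll_obs.T)
    A = np.log(weights)[:, None] + per_group        # (Q, G)
    mx = A.max(axis=0)
    expA = np.exp(A - mx)
    denom = expA.sum(axis=0)
    loglik = float((mx + np.log(denom)).sum()) - n_groups * 0.5 * np.log(np.pi)
    resp = expA / denom                              # (Q, G)
    mu = 1.0 / (1.0 + np.exp(-z))
    resid = y[None, :] - mu                          # (Q, N)
    w_obs = (resp[:, group_idx] * resid).sum(axis=0)  # (N,)
    grad_beta = X.T @ w_obs
    R = np.zeros((len(nodes), n_groups))
    np.add.at(R.T, group_idx, resid.T)
    grad_ls = float((resp * R * u[:, None]).sum())
    grad = np.concatenate([grad_beta, [grad_ls]])
    negll = -loglik
    ngrad = -grad
    if penalty > 0:
        negll += penalty * float(beta @ beta)
        ngrad[:k] += 2 * penalty * beta
    return negll, ngrad


def mixed_choice_fit(trials: pd.DataFrame, absolute_differences: bool = True,
                     n_quad: int = 15, penalty: float = 0.0,
                     maxiter: int = 500, terms=_TERMS) -> MixedChoiceModel:
    """Fit the random-intercept logistic choice model by ML.

    Required columns: participant, condition (delay/date), sir_amount,
    llr_amount, delay_days, choice_llr.  Condition is effect-coded
    (-1 = delay, +1 = date); Δreward/Δtime are the (by default absolute)
    attribute differences, z-scored across trials.  Wald tests use the
    numerical observed-information matrix.  Apparent separation (runaway
    coefficients) triggers a weakly penalised refit with a warning.
    """
    tr = trials.dropna(subset=["choice_llr"])
    groups, group_idx = np.unique(tr["participant"].to_numpy(),
                                  return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need >= 2 participants")
    X = _design(tr, absolute_differences, terms)
    y = tr["choice_llr"].to_numpy(dtype=float)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    n_groups = len(groups)
    k = X.shape[1]

    def negll_grad(p):
        return _gh_negll_grad(p, X, y, group_idx, n_groups, nodes, weights,
                              penalty)

    def negll(p):
        return negll_grad(p)[0]

    # two deterministic starts (moderate and near-zero random-effect SD):
    # the likelihood is flat in log sigma near the sigma = 0 boundary, so a
    # single start can stall there
    res = None
    for ls0 in (np.log(0.5), np.log(0.02)):
        p0 = np.zeros(k + 1)
        p0[k] = ls0
        cand = optimize.minimize(negll_grad, p0, method="BFGS", jac=True,
                                 options={"maxiter": maxiter, "gtol": 1e-8})
        if res is None or cand.fun < res.fun:
            res = cand
    if penalty == 0 and np.abs(res.x[:k]).max() > 15.0:
        warnings.warn("apparent separation; refitting with a weak L2 penalty",
                      UserWarning, stacklevel=2)
        return mixed_choice_fit(trials, absolute_differences, n_quad,
                                penalty=1e-3, maxiter=maxiter, terms=terms)
    hess = _numerical_hessian(lambda p: negll_grad(p)[1], res.x)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.maximum(np.diag(cov)[:k], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    est = res.x[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = est / se
    pval = 2 * sps.norm.sf(np.abs(zval))
    coef = pd.DataFrame({"estimate": est, "se": se, "z": zval, "p": pval},
                        index=list(terms))
    return MixedChoiceModel(coef=coef,
                            sigma_u=float(np.exp(np.clip(res.x[k], -10, 5))),
                            loglik=float(-res.fun), converged=bool(res.success),
                            n_obs=len(y), n_groups=n_groups)


def _numerical_hessian(grad, x, eps: float = 1e-5) -> np.ndarray:
    """Central differences of an analytic gradient, symmetrised."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = eps
        H[:, i] = (grad(x + e) - grad(x - e)) / (2 * eps)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# power analysis

def paired_t_power_n(d: float, alpha: float = 0.05,
                     sides: str = "one-sided", power: float = 0.80,
                     n_max: int = 100000) -> int:
    """Smallest N with noncentral-t power >= target for a paired t-test."""
    if d <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("need d > 0, alpha and power in (0, 1)")
    tails = 1 if sides in ("one-sided", "one-tailed") else 2
    for n in range(3, n_max + 1):
        df = n - 1
        crit = sps.t.ppf(1 - alpha / tails, df)
        nc = d * np.sqrt(n)
        achieved = sps.nct.sf(crit, df, nc)
        if tails == 2:
            achieved += sps.nct.cdf(-crit, df, nc)
        if achieved >= power:
            return n
    raise ValueError("no N below n_max reaches the target power")


def pearson_matrix(measures: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with n and p per pair.

    Returns a long-format table (var1, var2, n, r, p) over the numeric
    columns of ``measures``.
    """
    cols = measures.select_dtypes(include=[np.number]).columns
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            pair = measures[[a, b]].dropna()
            n = len(pair)
            if a == b:
                r, p = 1.0, 0.0
            elif n < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(pair[a], pair[b])
            rows.append({"var1": a, "var2": b, "n": n, "r": r, "p": p})
    return pd.DataFrame(rows)
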