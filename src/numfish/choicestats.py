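"""Choice-data statistics: exact binomial inference, Cohen's g, and a
random-intercept binomial GLMM with Laplace-approximated ML.

The analysis chain for a two-alternative choice experiment:

1. fit a binomial GLMM (logit link) of the per-trial choice on the design
   factors with a random intercept per fish, maximising the Laplace-
   approximated marginal likelihood;
2. simplify by backward elimination, dropping interactions then factors
   whenever removal improves AIC/BIC;
3. when no factor survives, summarise the pooled choices with an exact
   binomial test, a Clopper-Pearson 95% CI, and Cohen's g = p_hat - 0.5;
4. compare factor levels post hoc with Tukey-adjusted pairwise contrasts
   on the log-odds scale.

The random-intercept variance is parameterised on the log scale; when the
optimum is at the boundary (variance -> 0) the model collapses to a plain
logistic GLM and the reported estimates match it exactly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "CHOICE_TABLE_COLUMNS",
    "validate_choice_table",
    "ProportionSummary",
    "GLMMFit",
    "logit",
    "inv_logit",
    "exact_binomial",
    "classify_g",
    "fit_binomial_glmm",
    "backward_select",
    "tukey_contrasts",
    "t_from_summary",
    "congruency_analysis",
]

#: required columns of a long-format choice table
CHOICE_TABLE_COLUMNS = (
    "fish_id",
    "experiment",
    "phase",
    "session",
    "trial",
    "geometry_control",
    "spatial_control",
    "congruency_level",
    "comparison",
    "chose_target",
    "responded",
)


def validate_choice_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a choice table's schema and invariants; return the valid rows.

    ``chose_target`` must be 0/1 wherever ``responded`` is 1 and is ignored
    (may be NaN) elsewhere.
    """
    missing = [c for c in CHOICE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choice table missing columns: {missing}")
    responded = df["responded"].astype(int)
    if not responded.isin((0, 1)).all():
        raise ValueError("responded must be binary")
    answered = df.loc[responded == 1, "chose_target"]
    if not answered.isin((0, 1)).all():
        raise ValueError("chose_target must be 0/1 on responded trials")
    return df


# ---------------------------------------------------------------------------
# link functions and exact binomial inference
# ---------------------------------------------------------------------------

def logit(p: float) -> float:
    """Log-odds of a proportion (0 < p < 1)."""
    if not 0 < p < 1:
        raise ValueError("logit requires 0 < p < 1")
    return math.log(p / (1 - p))


def inv_logit(x: float) -> float:
    """Proportion corresponding to a log-odds value: e^x / (1 + e^x)."""
    return float(special.expit(x))


#: Cohen's g interpretation bands: <0.05 negligible, 0.1-0.15 small,
#: 0.2-0.25 medium, >0.25 large; values in the two gaps are assigned to
#: the nearer band boundary.
_G_EDGES = (0.075, 0.175, 0.25)
_G_BANDS = ("negligible", "small", "medium", "large")


def classify_g(g: float) -> str:
    """Interpretation band of a Cohen's g effect size (|g| <= 0.5)."""
    a = abs(g)
    if a > 0.5 + 1e-12:
        raise ValueError("|g| cannot exceed 0.5 for a proportion")
    for edge, band in zip(_G_EDGES, _G_BANDS):
        if a < edge or (band == "medium" and a <= edge):
            return band
    return _G_BANDS[-1]


@dataclass(frozen=True)
class ProportionSummary:
    """Exact binomial summary of k successes in n trials."""

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    p_value: float  # two-sided exact vs p0
    cohens_g: float  # p_hat - 0.5
    g_band: str


def exact_binomial(k: int, n: int, p0: float = 0.5) -> ProportionSummary:
    """Two-sided exact binomial test with Clopper-Pearson 95% CI and Cohen's g.

    The two-sided p-value uses the minimum-likelihood convention (all
    outcomes no more probable than the observed one), and g is banded on
    the unrounded value.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    test = stats.binomtest(k, n, p0)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    p_hat = k / n
    g = p_hat - 0.5
    return ProportionSummary(
        k=k,
        n=n,
        p_hat=p_hat,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(test.pvalue),
        cohens_g=g,
        g_band=classify_g(g),
    )


def t_from_summary(
    m1: float, sem1: float, n1: int, m2: float, sem2: float, n2: int,
    *, welch: bool = False,
) -> tuple[float, float, float]:
    """Independent-samples t-test reconstructed from means, SEMs and ns.

    Group variances are recovered as s^2 = n * SEM^2.  The default is the
    pooled-variance test with df = n1 + n2 - 2; ``welch=True`` uses the
    Welch statistic and Satterthwaite df instead.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    v1, v2 = n1 * sem1**2, n2 * sem2**2
    if welch:
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


# ---------------------------------------------------------------------------
# design matrices for categorical factors
# ---------------------------------------------------------------------------

def _factor_levels(df: pd.DataFrame, factor: str) -> list:
    return sorted(df[factor].dropna().unique().tolist())


def build_design(
    df: pd.DataFrame, terms: list[tuple[str, ...]]
) -> tuple[np.ndarray, list[str], dict]:
    """Treatment-coded design matrix with intercept for categorical terms.

    ``terms`` is a list of factor tuples; single-factor terms produce the
    usual dummy columns (first level as reference), multi-factor terms the
    products of their dummies.  Returns (X, column names, level map).
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    levels: dict[str, list] = {}

    def dummies(factor: str) -> tuple[list[np.ndarray], list[str]]:
        lv = levels.setdefault(factor, _factor_levels(df, factor))
        vecs, labels = [], []
        for level in lv[1:]:
            vecs.append((df[factor] == level).to_numpy(dtype=float))
            labels.append(f"{factor}[{level}]")
        return vecs, labels

    for term in terms:
        vec_sets, label_sets = zip(*(dummies(f) for f in term))
        for combo_vecs, combo_labels in zip(
            itertools.product(*vec_sets), itertools.product(*label_sets)
        ):
            col = np.ones(n)
            for v in combo_vecs:
                col = col * v
            cols.append(col)
            names.append(":".join(combo_labels))
    X = np.column_stack(cols)
    return X, names, levels


# ---------------------------------------------------------------------------
# random-intercept binomial GLMM (Laplace / adaptive Gauss-Hermite)
# ---------------------------------------------------------------------------

@dataclass
class GLMMFit:
    """Fitted random-intercept binomial GLMM (logit link)."""

    fixed_names: list[str]
    fixed_effects: np.ndarray  # log-odds estimates
    fixed_se: np.ndarray
    cov_fixed: np.ndarray
    random_intercept_variance: float  # log-odds^2
    log_likelihood: float
    aic: float
    bic: float
    converged: bool
    n_obs: int  # Bernoulli trials
    n_groups: int
    terms: list[tuple[str, ...]] = field(default_factory=list)
    factor_levels: dict = field(default_factory=dict)
    method: str = "laplace"

    @property
    def n_params(self) -> int:
        return len(self.fixed_effects) + 1  # + random-intercept variance

    def coef_table(self) -> pd.DataFrame:
        z = self.fixed_effects / self.fixed_se
        return pd.DataFrame(
            {
                "estimate": self.fixed_effects,
                "se": self.fixed_se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=self.fixed_names,
        )


def _aggregate(
    df: pd.DataFrame, X: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Collapse Bernoulli rows to binomial counts per (group, covariate row)."""
    out = []
    frame = pd.DataFrame(X)
    frame["__g"] = groups
    frame["__y"] = y
    key_cols = [c for c in frame.columns if c not in ("__y",)]
    agg = frame.groupby(key_cols, sort=False)["__y"].agg(["sum", "count"]).reset_index()
    for g, sub in agg.groupby("__g", sort=False):
        Xg = sub[[c for c in sub.columns if c not in ("__g", "sum", "count")]].to_numpy(
            dtype=float
        )
        out.append((Xg, sub["sum"].to_numpy(float), sub["count"].to_numpy(float)))
    return out


def _group_loglik_parts(Xg, kg, ng, beta, b):
    eta = Xg @ beta + b
    # stable log(1 + e^eta)
    l1p = np.logaddexp(0.0, eta)
    ll = float(np.sum(kg * eta - ng * l1p))
    p = special.expit(eta)
    grad = float(np.sum(kg - ng * p))
    w = float(np.sum(ng * p * (1 - p)))
    return ll, grad, w


def _find_mode(Xg, kg, ng, beta, sigma2, b0=0.0):
    """Newton mode of the per-group log joint density in b."""
    b = b0
    for _ in range(100):
        _, grad, w = _group_loglik_parts(Xg, kg, ng, beta, b)
        g = grad - b / sigma2
        h = w + 1.0 / sigma2
        step = g / h
        b += step
        if abs(step) < 1e-10:
            break
    return b


def _binom_const(kg, ng):
    # The data are per-trial Bernoulli outcomes; rows are aggregated to
    # binomial counts only for speed.  The combinatorial constants of the
    # aggregated form depend on the model's covariate patterns and would
    # break cross-model AIC comparability, so the Bernoulli likelihood
    # (constant 0) is used throughout.
    return 0.0


def _marginal_loglik(
    grouped, beta, sigma2, method: str = "laplace", agq_nodes: int = 9
) -> float:
    """Laplace or adaptive Gauss-Hermite marginal log-likelihood."""
    total = 0.0
    if method == "agq":
        nodes, weights = np.polynomial.hermite_e.hermegauss(agq_nodes)
        # probabilists' Hermite: integral w.r.t. standard normal density
    for Xg, kg, ng in grouped:
        const = _binom_const(kg, ng)
        if sigma2 <= 0:
            ll, _, _ = _group_loglik_parts(Xg, kg, ng, beta, 0.0)
            total += ll + const
            continue
        bhat = _find_mode(Xg, kg, ng, beta, sigma2)
        ll_hat, _, w = _group_loglik_parts(Xg, kg, ng, beta, bhat)
        h = w + 1.0 / sigma2  # negative curvature of log joint
        if method == "laplace":
            total += (
                const + ll_hat - bhat**2 / (2 * sigma2)
                - 0.5 * math.log(sigma2 * h)
            )
        elif method == "agq":
            s = 1.0 / math.sqrt(h)
            bq = bhat + s * nodes
            vals = np.empty(agq_nodes)
            for q, b in enumerate(bq):
                llq, _, _ = _group_loglik_parts(Xg, kg, ng, beta, b)
                vals[q] = (
                    llq
                    - b**2 / (2 * sigma2)
                    + 0.5 * nodes[q] ** 2  # cancel the e^{-x^2/2} of hermegauss
                )
            # weights include sqrt(2*pi); normal density has 1/sqrt(2*pi*sigma2)
            total += (
                const
                + special.logsumexp(vals, b=weights)
                + math.log(s)
                - 0.5 * math.log(2 * math.pi * sigma2)
            )
        else:
            raise ValueError(f"unknown integration method {method!r}")
    return total


_THETA_FLOOR = -30.0  # log-variance at which the model is declared degenerate


def fit_binomial_glmm(
    table: pd.DataFrame,
    fixed: list[tuple[str, ...]] | list[str],
    random_intercept: str = "fish_id",
    response: str = "chose_target",
    *,
    method: str = "laplace",
    agq_nodes: int = 9,
    force_zero_variance: bool = False,
) -> GLMMFit:
    """Fit a binomial GLMM with a single random intercept by ML.

    ``fixed`` lists the categorical model terms (strings or tuples; tuples
    are interactions); the intercept is always included.  Only responded
    trials enter the likelihood.  The marginal likelihood integrates the
    random intercept out by the Laplace approximation (default) or adaptive
    Gauss-Hermite quadrature with ``agq_nodes`` nodes (``method='agq'``,
    used as the internal accuracy cross-check).

    A variance estimate driven to the boundary is reported as 0 and the
    fixed effects then equal the plain logistic GLM fit.
    """
    terms = [t if isinstance(t, tuple) else (t,) for t in fixed]
    df = table
    if "responded" in df.columns:
        df = df[df["responded"].astype(int) == 1]
    y = df[response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary")
    groups = df[random_intercept].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    X, names, levels = build_design(df, terms)
    grouped = _aggregate(df, X, y, groups)
    n_obs = len(y)
    p = X.shape[1]

    # starting values: plain logistic GLM
    beta0 = _glm_start(X, y)

    if force_zero_variance:
        boundary = True
        beta_hat = beta0
        sigma2_hat = 0.0
    else:
        def negll(params: np.ndarray) -> float:
            beta, theta = params[:p], params[p]
            sigma2 = math.exp(theta)
            return -_marginal_loglik(grouped, beta, sigma2, method, agq_nodes)

        x0 = np.concatenate([beta0, [math.log(0.1)]])
        bounds = [(None, None)] * p + [(_THETA_FLOOR, 5.0)]
        res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
        # restart from the boundary if the variance wants to vanish
        if res.x[p] < math.log(1e-6):
            x_bound = res.x.copy()
            x_bound[p] = _THETA_FLOOR
            res2 = optimize.minimize(
                negll, x_bound, method="L-BFGS-B", bounds=bounds
            )
            if res2.fun <= res.fun:
                res = res2

        beta_hat = res.x[:p]
        sigma2_hat = math.exp(res.x[p])
        boundary = res.x[p] <= _THETA_FLOOR + 1e-6 or sigma2_hat < 1e-10

    if boundary:
        # collapse to the plain logistic GLM: exact ML at sigma^2 = 0
        import statsmodels.api as sm

        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        beta_hat = np.asarray(glm.params, dtype=float)
        cov = np.asarray(glm.cov_params(), dtype=float)
        sigma2_hat = 0.0
        loglik = _marginal_loglik(grouped, beta_hat, 0.0)
        converged = bool(glm.converged)
    else:
        loglik = -res.fun
        cov = _fixed_cov(
            lambda b: -_marginal_loglik(grouped, b, sigma2_hat, method, agq_nodes),
            beta_hat,
        )
        converged = bool(res.success)

    se = np.sqrt(np.diag(cov))
    k_params = p + 1
    aic = -2 * loglik + 2 * k_params
    bic = -2 * loglik + math.log(n_obs) * k_params
    if not converged:
        warnings.warn("GLMM fit did not converge cleanly", RuntimeWarning)
    return GLMMFit(
        fixed_names=names,
        fixed_effects=beta_hat,
        fixed_se=se,
        cov_fixed=cov,
        random_intercept_variance=sigma2_hat,
        log_likelihood=loglik,
        aic=aic,
        bic=bic,
        converged=converged,
        n_obs=n_obs,
        n_groups=len(grouped),
        terms=terms,
        factor_levels=levels,
        method=method,
    )


def _glm_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    try:
        return np.asarray(
            sm.GLM(y, X, family=sm.families.Binomial()).fit().params, dtype=float
        )
    except Exception:
        return np.zeros(X.shape[1])


def _fixed_cov(negll_beta, beta_hat: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Observed-information covariance via central finite differences."""
    p = len(beta_hat)
    H = np.zeros((p, p))
    f0 = negll_beta(beta_hat)
    steps = eps * np.maximum(1.0, np.abs(beta_hat))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            if i == j:
                fpp = negll_beta(beta_hat + ei)
                fmm = negll_beta(beta_hat - ei)
                H[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
            else:
                fpp = negll_beta(beta_hat + ei + ej)
                fpm = negll_beta(beta_hat + ei - ej)
                fmp = negll_beta(beta_hat - ei + ej)
                fmm = negll_beta(beta_hat - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (
                    4 * steps[i] * steps[j]
                )
    return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# backward elimination and post hoc contrasts
# ---------------------------------------------------------------------------

def _removable(terms: list[tuple[str, ...]]) -> list[tuple[str, ...]]:
    """Terms not marginal to any retained higher-order term."""
    out = []
    for t in terms:
        if not any(set(t) < set(u) for u in terms if u != t):
            out.append(t)
    return out


def backward_select(
    table: pd.DataFrame,
    full_terms: list[tuple[str, ...]] | list[str],
    criterion: str = "AIC",
    random_intercept: str = "fish_id",
    response: str = "chose_target",
) -> tuple[GLMMFit, list[dict]]:
    """Backward-eliminate GLMM terms by information criterion.

    Starting from the full model, repeatedly drop the single removable term
    (interactions before their main effects) whose removal lowers the
    criterion the most; stop when no removal improves it.  Returns the final
    fit and the elimination trace.
    """
    crit = criterion.upper()
    if crit not in ("AIC", "BIC"):
        raise ValueError("criterion must be AIC or BIC")
    terms = [t if isinstance(t, tuple) else (t,) for t in full_terms]

    def score(fit: GLMMFit) -> float:
        return fit.aic if crit == "AIC" else fit.bic

    current = fit_binomial_glmm(table, terms, random_intercept, response)
    trace = [{"terms": list(terms), "criterion": score(current), "removed": None}]
    while terms:
        best_fit, best_term = None, None
        for t in _removable(terms):
            candidate = [u for u in terms if u != t]
            fit = fit_binomial_glmm(table, candidate, random_intercept, response)
            if best_fit is None or score(fit) < score(best_fit):
                best_fit, best_term = fit, t
        if best_fit is not None and score(best_fit) < score(current):
            terms = [u for u in terms if u != best_term]
            current = best_fit
            trace.append(
                {"terms": list(terms), "criterion": score(current),
                 "removed": best_term}
            )
        else:
            break
    return current, trace


def tukey_contrasts(fit: GLMMFit, factor: str) -> pd.DataFrame:
    """All pairwise level contrasts of a factor, Tukey-adjusted.

    Contrasts are on the log-odds scale with standard errors from the fixed-
    effect covariance; familywise adjustment uses the studentized-range
    distribution with the fit's residual degrees of freedom.
    """
    if factor not in fit.factor_levels:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    levels = fit.factor_levels[factor]
    k = len(levels)
    if k < 2:
        raise ValueError("factor needs >= 2 levels")
    df_resid = max(fit.n_obs - len(fit.fixed_effects), 2)

    def coef_vec(level) -> np.ndarray:
        v = np.zeros(len(fit.fixed_names))
        name = f"{factor}[{level}]"
        if name in fit.fixed_names:
            v[fit.fixed_names.index(name)] = 1.0
        return v

    rows = []
    for la, lb in itertools.combinations(levels, 2):
        c = coef_vec(lb) - coef_vec(la)
        est = float(c @ fit.fixed_effects)
        se = float(np.sqrt(c @ fit.cov_fixed @ c))
        t = est / se if se > 0 else 0.0
        p_unadj = 2 * float(stats.t.sf(abs(t), df_resid))
        q = abs(t) * math.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append(
            {
                "contrast": f"{lb} - {la}",
                "estimate": est,
                "se": se,
                "t": t,
                "p_unadjusted": p_unadj,
                "p_adjusted": min(1.0, p_adj),
            }
        )
    return pd.DataFrame(rows)


def level_estimates(fit: GLMMFit, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """Per-level log-odds estimates with Wald CIs, also on the probability scale."""
    if factor not in fit.factor_levels:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for level in fit.factor_levels[factor]:
        c = np.zeros(len(fit.fixed_names))
        c[fit.fixed_names.index("(Intercept)")] = 1.0
        name = f"{factor}[{level}]"
        if name in fit.fixed_names:
            c[fit.fixed_names.index(name)] = 1.0
        est = float(c @ fit.fixed_effects)
        se = float(np.sqrt(c @ fit.cov_fixed @ c))
        rows.append(
            {
                "level": level,
                "log_odds": est,
                "se": se,
                "ci_low": est - z * se,
                "ci_high": est + z * se,
                "prob": inv_logit(est),
                "prob_ci_low": inv_logit(est - z * se),
                "prob_ci_high": inv_logit(est + z * se),
            }
        )
    return pd.DataFrame(rows)


def congruency_analysis(
    table: pd.DataFrame, random_intercept: str = "fish_id"
) -> dict:
    """GLMM of choice on congruency level plus Tukey pairwise contrasts.

    Proceeds over the levels present in the data (with a warning if some of
    the three levels are absent) and returns the fit, the adjusted pairwise
    contrasts, and per-level estimates with 95% CIs.
    """
    df = table[table["responded"].astype(int) == 1].copy()
    present = sorted(df["congruency_level"].unique().tolist())
    if len(present) < 3:
        warnings.warn(
            f"only congruency levels {present} present; analysis proceeds over them",
            UserWarning,
        )
    df["congruency_level"] = df["congruency_level"].astype(str)
    fit = fit_binomial_glmm(df, ["congruency_level"], random_intercept)
    contrasts = tukey_contrasts(fit, "congruency_level")
    levels = level_estimates(fit, "congruency_level")
    return {"fit": fit, "contrasts": contrasts, "level_estimates": levels}
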