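"""GLM inference chain for habitat-island diversity.

The chain mirrors standard practice for count responses on habitat
islands:

1. screen predictors for normality (Shapiro–Wilk, α = 0.05) and log10(x +
   0.01)-transform the rejected ones;
2. z-standardize all predictors (quadratic terms are built afterwards as
   the square of the z-score);
3. single-predictor GLMs with linear and quadratic terms decide which
   quadratics enter the full model;
4. the full model is reduced by exhaustive AICc search over all term
   subsets that respect marginality (x² never without x) — the classic
   "dredge" —
5. followed by backward pruning of non-significant terms (Wald p ≥ 0.05)
   and of collinear terms (VIF > 5), refitting at every step;
6. explained variance is the deviance pseudo-R² = (null − residual) /
   null deviance.

Counts use a negative-binomial family with log link (theta estimated by
maximum likelihood, re-estimated for every candidate model); proportions
use a binomial family with logit link on (successes, trials).  A Poisson
family is kept for overdispersion checks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = [
    "screen_transform",
    "standardize",
    "GLMFit",
    "fit_glm",
    "nb_loglik",
    "overdispersion_check",
    "single_predictor_scan",
    "dredge_aicc",
    "vif",
    "pseudo_r2",
    "finalize_model",
    "aicc_from",
]

ALPHA_SIG = 0.05
VIF_THRESHOLD = 5.0
_LOG_SHIFT = 0.01


# --------------------------------------------------------------------------
# predictor screening and standardization

def screen_transform(
    pt: pd.DataFrame,
    alpha: float = ALPHA_SIG,
    shift: float = _LOG_SHIFT,
    on_domain_error: str = "raise",
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Shapiro–Wilk normality screen per column; non-normal columns are
    replaced by log10(column + shift).

    Returns (table, flags) where flags[name] is True when the column was
    transformed.  Constant columns make the test undefined and raise.
    Values ≤ −shift put the log out of domain: with the default
    ``on_domain_error='raise'`` this is an error; ``'keep'`` leaves such a
    column untransformed with a warning (sensible for predictors that are
    already on a log scale, like the target effect).
    """
    out = pt.copy()
    flags: dict[str, bool] = {}
    for name in pt.columns:
        x = pt[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"predictor {name!r} is constant; normality test undefined")
        p = stats.shapiro(x).pvalue
        if p < alpha:
            if np.any(x + shift <= 0):
                if on_domain_error == "keep":
                    warnings.warn(
                        f"predictor {name!r} is non-normal but has values <= {-shift}; "
                        "leaving it untransformed"
                    )
                    flags[name] = False
                    continue
                raise ValueError(
                    f"predictor {name!r} has values <= {-shift}; log10(x + {shift}) undefined"
                )
            out[name] = np.log10(x + shift)
            flags[name] = True
        else:
            flags[name] = False
    return out, flags


def standardize(pt: pd.DataFrame) -> pd.DataFrame:
    """z-scores per column (sample SD, ddof = 1); zero variance raises."""
    out = pt.copy()
    for name in pt.columns:
        x = pt[name].to_numpy(dtype=float)
        sd = np.std(x, ddof=1)
        if sd == 0:
            raise ValueError(f"predictor {name!r} has zero variance")
        out[name] = (x - np.mean(x)) / sd
    return out


# --------------------------------------------------------------------------
# design matrices

def is_quadratic(term: str) -> bool:
    return term.endswith("^2")

def base_of(term: str) -> str:
    return term[:-2] if is_quadratic(term) else term


def build_design(pt: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Design matrix (without intercept) for a list of terms; a term
    ``name^2`` is the square of the (already standardized) column."""
    cols = {}
    for t in terms:
        base = base_of(t)
        if base not in pt.columns:
            raise KeyError(f"unknown predictor {base!r}")
        cols[t] = pt[base].to_numpy(dtype=float) ** 2 if is_quadratic(t) else pt[base].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=pt.index)


def respects_marginality(terms: list[str] | tuple[str, ...]) -> bool:
    terms = list(terms)
    return all(base_of(t) in terms for t in terms if is_quadratic(t))


# --------------------------------------------------------------------------
# fitting

@dataclass
class GLMFit:
    """One fitted GLM: coefficients, deviances, information criteria."""

    family: str                       # 'nb' | 'poisson' | 'binomial'
    terms: list[str]
    params: pd.Series                 # includes 'const'
    bse: pd.Series
    pvalues: pd.Series
    null_deviance: float
    residual_deviance: float
    theta: float | None               # NB dispersion (None otherwise)
    loglik: float
    k: int                            # parameters counted by AIC (incl. theta)
    n: int
    converged: bool
    design: pd.DataFrame = field(repr=False)
    endog: np.ndarray = field(repr=False)
    pearson_chi2: float = 0.0

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def aicc(self) -> float:
        return aicc_from(self.loglik, self.k, self.n)

    @property
    def pseudo_r2(self) -> float:
        return pseudo_r2(self)


def aicc_from(loglik: float, k: int, n: int) -> float:
    """Small-sample AIC: AIC + 2k(k+1)/(n − k − 1)."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Negative-binomial (NB2) log-likelihood with mean mu, size theta."""
    r = theta
    mu = np.maximum(mu, 1e-300)
    return float(
        np.sum(
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _ml_alpha(y: np.ndarray, mu: np.ndarray, lo: float = -15.0, hi: float = 10.0) -> float:
    """ML estimate of the NB alpha (= 1/theta) for fixed means."""
    def neg(log_alpha: float) -> float:
        return -nb_loglik(y, mu, 1.0 / np.exp(log_alpha))
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    return float(np.exp(res.x))


def fit_glm(
    endog,
    design: pd.DataFrame,
    family: str = "nb",
    trials=None,
    terms: list[str] | None = None,
    max_theta_iter: int = 50,
) -> GLMFit:
    """Fit one GLM by IRLS.

    Parameters
    ----------
    endog : counts (nb/poisson) or successes (binomial, with ``trials``).
    design : DataFrame of term columns (no intercept; may be empty for an
        intercept-only model).
    family : 'nb' (log link, theta by ML), 'poisson' (log link) or
        'binomial' (logit link on successes/trials).
    """
    y = np.asarray(endog, dtype=float)
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add") \
        if design.shape[1] else np.ones((len(y), 1))
    names = ["const"] + list(design.columns)
    terms = list(design.columns) if terms is None else terms
    n = len(y)
    converged = True

    if family == "binomial":
        if trials is None:
            raise ValueError("binomial fits need trial counts")
        tr = np.asarray(trials, dtype=float)
        resp = np.column_stack([y, tr - y])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(resp, X, family=sm.families.Binomial()).fit()
        theta = None
        ll = float(res.llf)
        k = X.shape[1]
        null_dev = float(res.null_deviance)
        resid_dev = float(res.deviance)
        converged = bool(res.converged)
    elif family == "poisson":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        theta = None
        ll = float(res.llf)
        k = X.shape[1]
        null_dev = float(res.null_deviance)
        resid_dev = float(res.deviance)
        converged = bool(res.converged)
    elif family == "nb":
        res, theta, converged = _fit_nb(y, X, max_theta_iter)
        ll = nb_loglik(y, res.fittedvalues, theta)
        k = X.shape[1] + 1  # theta is estimated too
        null_dev = float(res.null_deviance)
        resid_dev = float(res.deviance)
    else:
        raise ValueError(f"unknown family {family!r}")

    params = pd.Series(res.params, index=names)
    return GLMFit(
        family=family,
        terms=terms,
        params=params,
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        null_deviance=null_dev,
        residual_deviance=resid_dev,
        theta=theta,
        loglik=ll,
        k=k,
        n=n,
        converged=converged,
        design=design,
        endog=y,
        pearson_chi2=float(res.pearson_chi2),
    )


def _fit_nb(y: np.ndarray, X: np.ndarray, max_iter: int):
    """Alternate IRLS for beta with ML profiling of the NB dispersion,
    in the spirit of the classic glm.nb algorithm."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu = np.maximum(pois.fittedvalues, 1e-10)
    # method-of-moments start for alpha
    mom = float(np.sum((y - mu) ** 2 - mu) / max(np.sum(mu**2), 1e-12))
    alpha = float(np.clip(mom, 1e-6, 50.0))
    res = pois
    converged = False
    last_ll = -np.inf
    for _ in range(max_iter):
        alpha = _ml_alpha(y, mu, lo=np.log(1e-8), hi=np.log(1e4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit(
                start_params=res.params if res is not None else None
            )
        mu = np.maximum(res.fittedvalues, 1e-10)
        ll = nb_loglik(y, mu, 1.0 / alpha)
        if abs(ll - last_ll) < 1e-6:
            converged = True
            break
        last_ll = ll
    return res, 1.0 / alpha, converged and bool(res.converged)


# --------------------------------------------------------------------------
# diagnostics

def overdispersion_check(fit: GLMFit, threshold: float = 1.5) -> tuple[float, bool]:
    """Pearson χ²/df of a Poisson fit; a ratio above ``threshold`` flags
    overdispersion (the pipeline then prefers the NB family)."""
    df = fit.n - len(fit.params)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    ratio = fit.pearson_chi2 / df
    return float(ratio), bool(ratio > threshold)


def pseudo_r2(fit: GLMFit) -> float:
    """Deviance-explained: (null − residual) / null deviance."""
    if fit.null_deviance == 0:
        raise ValueError("null deviance is zero; pseudo-R² undefined")
    return float((fit.null_deviance - fit.residual_deviance) / fit.null_deviance)


def vif(design: pd.DataFrame | GLMFit) -> pd.Series:
    """Variance inflation factors of the design columns (intercept
    excluded): VIF_j = 1/(1 − R²_j) regressing column j on the others.

    Perfect collinearity reports inf."""
    X = design.design if isinstance(design, GLMFit) else design
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two non-intercept terms")
    out = {}
    M = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        others = np.delete(M, j, axis=1)
        res = sm.OLS(M[:, j], sm.add_constant(others)).fit()
        r2 = min(res.rsquared, 1.0)
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# --------------------------------------------------------------------------
# model search

def single_predictor_scan(
    endog,
    pt: pd.DataFrame,
    family: str = "nb",
    trials=None,
    alpha: float = ALPHA_SIG,
) -> pd.DataFrame:
    """Linear and quadratic single-predictor models for every column.

    Returns one row per (predictor, form) with coefficients, Wald
    p-values, pseudo-R² and AICc; ``quadratic_significant`` marks
    predictors whose squared term earns a place in the full model.  Fit
    failures are recorded and the scan continues.
    """
    rows = []
    for name in pt.columns:
        for form in ("linear", "quadratic"):
            terms = [name] if form == "linear" else [name, f"{name}^2"]
            try:
                fit = fit_glm(endog, build_design(pt, terms), family, trials=trials)
                key = terms[-1]
                rows.append(
                    {
                        "predictor": name,
                        "form": form,
                        "coef_linear": fit.params[name],
                        "p_linear": fit.pvalues[name],
                        "coef_quadratic": fit.params.get(key) if form == "quadratic" else np.nan,
                        "p_quadratic": fit.pvalues.get(key) if form == "quadratic" else np.nan,
                        "pseudo_r2": fit.pseudo_r2,
                        "aicc": fit.aicc,
                        "converged": fit.converged,
                        "error": "",
                    }
                )
            except Exception as exc:  # keep scanning other predictors
                rows.append(
                    {"predictor": name, "form": form, "coef_linear": np.nan,
                     "p_linear": np.nan, "coef_quadratic": np.nan, "p_quadratic": np.nan,
                     "pseudo_r2": np.nan, "aicc": np.nan, "converged": False,
                     "error": str(exc)}
                )
    scan = pd.DataFrame(rows)
    quad = scan[scan["form"] == "quadratic"].set_index("predictor")["p_quadratic"]
    scan["quadratic_significant"] = scan["predictor"].map(quad < alpha)
    return scan


def candidate_terms_from_scan(scan: pd.DataFrame, alpha: float = ALPHA_SIG) -> list[str]:
    """Full-model term list: every predictor linearly, plus the squared
    term of each predictor whose quadratic was significant in the scan."""
    preds = list(dict.fromkeys(scan["predictor"]))
    quad = scan[scan["form"] == "quadratic"].set_index("predictor")["p_quadratic"]
    terms = list(preds)
    for p in preds:
        if p in quad.index and quad[p] < alpha:
            terms.append(f"{p}^2")
    return terms


def dredge_aicc(
    endog,
    pt: pd.DataFrame,
    terms: list[str],
    family: str = "nb",
    trials=None,
) -> tuple[pd.DataFrame, GLMFit]:
    """Exhaustive all-subsets search ranked by AICc.

    Every subset of ``terms`` respecting marginality (a squared term only
    with its linear term) is fitted, including the intercept-only model.
    Non-converged subsets are kept in the table but ranked after all
    converged ones.  Returns (selection table, best fit).
    """
    if len(terms) > 12:
        raise ValueError("refusing an exhaustive search over more than 12 terms")
    subsets = [
        combo
        for r in range(len(terms) + 1)
        for combo in itertools.combinations(terms, r)
        if respects_marginality(combo)
    ]
    rows = []
    fits: dict[tuple[str, ...], GLMFit] = {}
    for combo in subsets:
        label = " + ".join(combo) if combo else "(intercept)"
        try:
            fit = fit_glm(endog, build_design(pt, list(combo)), family, trials=trials)
            fits[combo] = fit
            rows.append(
                {"terms": label, "n_terms": len(combo), "loglik": fit.loglik,
                 "k": fit.k, "aicc": fit.aicc, "pseudo_r2": fit.pseudo_r2,
                 "converged": fit.converged}
            )
        except Exception:
            rows.append(
                {"terms": label, "n_terms": len(combo), "loglik": np.nan, "k": np.nan,
                 "aicc": np.nan, "pseudo_r2": np.nan, "converged": False}
            )
    table = pd.DataFrame(rows)
    order = table["aicc"].where(table["converged"], np.inf)
    table = table.assign(_order=order).sort_values(
        ["_order", "n_terms", "terms"]
    ).drop(columns="_order").reset_index(drop=True)
    finite = table.loc[table["converged"], "aicc"]
    if finite.empty:
        raise RuntimeError("no candidate model converged")
    table["delta_aicc"] = table["aicc"] - finite.min()
    best_label = table.iloc[0]["terms"]
    best_combo = tuple(t for t in terms if t in best_label.split(" + "))
    return table, fits[best_combo]


def finalize_model(
    fit: GLMFit,
    endog,
    pt: pd.DataFrame,
    family: str = "nb",
    trials=None,
    alpha: float = ALPHA_SIG,
    vif_threshold: float = VIF_THRESHOLD,
    log=None,
) -> GLMFit:
    """Backward pruning of the dredge-best model.

    First the least significant droppable term with Wald p ≥ alpha is
    removed (never a linear term whose square is still present) and the
    model refitted, until all terms are significant.  Then, while any VIF
    exceeds ``vif_threshold``, the collinear term whose removal gives the
    lowest AICc is dropped.  Intercept-only is a legal endpoint.
    """
    def say(msg: str) -> None:
        if log is not None:
            log(msg)

    terms = list(fit.terms)

    def refit(ts: list[str]) -> GLMFit:
        return fit_glm(endog, build_design(pt, ts), family, trials=trials, terms=ts)

    current = fit
    while True:
        droppable = [t for t in current.terms if f"{t}^2" not in current.terms]
        cand = [(current.pvalues[t], t) for t in droppable if current.pvalues[t] >= alpha]
        if not cand:
            break
        worst = max(cand)[1]
        say(f"dropping {worst} (p = {max(cand)[0]:.3f} >= {alpha})")
        terms = [t for t in current.terms if t != worst]
        current = refit(terms)

    while len(current.terms) >= 2:
        v = vif(current.design)
        if (v <= vif_threshold).all():
            break
        collinear = list(v[v > vif_threshold].index)
        best_aicc, best_terms = np.inf, None
        for t in collinear:
            trial = [u for u in current.terms if u != t and base_of(u) != t]
            f = refit(trial)
            if f.aicc < best_aicc:
                best_aicc, best_terms = f.aicc, trial
        say(f"VIF pruning to: {best_terms} (AICc = {best_aicc:.2f})")
        current = refit(best_terms)
        # removal may leave newly non-significant terms
        current = finalize_model(current, endog, pt, family, trials, alpha, vif_threshold, log=None) \
            if any(current.pvalues[t] >= alpha for t in current.terms) else current
    return current
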