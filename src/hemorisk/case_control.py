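"""Per-SD standardized logistic models with progressive adjustment.

Exposure markers are analysed on the natural-log scale and standardized so
that effect estimates are odds ratios per 1 SD higher log level.  Odds ratios
are estimated by unconditional logistic regression (appropriate under
frequency matching, with the matching factors in every model) and adjusted
progressively: first for the matching factors (age, sex, recruitment period),
then for non-lipid risk factors, then for lipids, optionally for C-reactive
protein.  The module also provides interaction likelihood-ratio tests for
subgroup analyses and adjusted percentage differences of markers across
covariates among controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


# --------------------------------------------------------------------------
# adjustment tiers
# --------------------------------------------------------------------------

@dataclass
class AdjustmentTier:
    """Named, ordered covariate set; tiers form a nested ladder."""
    name: str
    covariates: list[str] = field(default_factory=list)


def default_tiers(include_crp: bool = False) -> list[AdjustmentTier]:
    """The standard progressive-adjustment ladder.

    minimal: matching factors only (age, sex, period of recruitment);
    plus_nonlipid: + smoking, BMI, history of diabetes, systolic BP;
    plus_lipid: + total cholesterol and log triglycerides;
    plus_crp (optional): + log C-reactive protein.
    """
    minimal = ["age", "sex", "period"]
    nonlipid = minimal + ["smoking", "bmi", "diabetes", "sbp"]
    lipid = nonlipid + ["tchol", "log_tg"]
    tiers = [
        AdjustmentTier("minimal", minimal),
        AdjustmentTier("plus_nonlipid", nonlipid),
        AdjustmentTier("plus_lipid", lipid),
    ]
    if include_crp:
        tiers.append(AdjustmentTier("plus_crp", lipid + ["log_crp"]))
    return tiers


def build_design(df: pd.DataFrame, covariates: list[str],
                 intercept: bool = True) -> tuple[np.ndarray, list[str]]:
    """Design matrix for a covariate list.

    ``sex`` becomes a male indicator and ``period`` becomes stage indicator
    variables (first stage reference); other covariates enter as numeric.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(df)))
        names.append("const")
    for c in covariates:
        if c == "sex":
            cols.append((df["sex"] == "male").to_numpy(dtype=float))
            names.append("sex_male")
        elif c == "period":
            levels = np.sort(df["period"].unique())
            for lev in levels[1:]:
                cols.append((df["period"] == lev).to_numpy(dtype=float))
                names.append(f"period_{lev}")
        elif c not in df.columns:
            raise KeyError(f"covariate column {c!r} missing from data")
        else:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

def standardize_log_exposure(values, sd_source) -> tuple[np.ndarray, float]:
    """Z-score a log-scale exposure against a reference sample.

    Returns ``(values - mean(sd_source)) / SD(sd_source)`` together with the
    SD used, so that one standardized unit is exactly ``sd_used`` log units
    (e.g. sd_used = 0.5 log units corresponds to an e^0.5 ≈ 1.6-fold
    difference on the original scale).
    """
    values = np.asarray(values, dtype=float)
    ref = np.asarray(sd_source, dtype=float)
    sd = float(np.std(ref, ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError("sd_source has zero variance")
    return (values - float(np.mean(ref))) / sd, sd


# --------------------------------------------------------------------------
# logistic regression by IRLS
# --------------------------------------------------------------------------

class SeparationError(RuntimeError):
    """Raised when maximum-likelihood coefficients diverge."""


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n_obs: int
    converged: bool
    n_iter: int
    names: list[str] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _binom_loglik(y, eta):
    # numerically stable: -log(1+exp(-eta)) for y=1, -log(1+exp(eta)) for y=0
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_irls(design: np.ndarray, outcome, *, names=None,
                      max_iter: int = 50, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares (Newton-Raphson with step halving).

    Converges when the largest coefficient change is below ``tol``.  The
    covariance matrix is the inverse observed information at the optimum.
    Raises on rank-deficient designs and on (quasi-)complete separation,
    where the likelihood has no finite maximizer.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design/outcome shape mismatch")
    if y.min() == y.max():
        raise ValueError("outcome is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {np.linalg.matrix_rank(X)} "
            f"< {X.shape[1]} columns)")

    beta = np.zeros(X.shape[1])
    ll = _binom_loglik(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular; fitted probabilities have "
                "collapsed to 0/1 (separation)") from exc
        # step-halving guarantees a non-decreasing log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _binom_loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        delta = float(np.max(np.abs(cand - beta)))
        beta, ll = cand, ll_new
        if delta < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 30.0:
        raise SeparationError(
            "coefficients diverging (|beta| > 30); data are separated")
    if not converged:
        raise SeparationError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last max step {delta:.3g}); possible separation")
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (mu * (1 - mu))[:, None])
    cov = np.linalg.inv(info)
    return LogisticFit(coef=beta, cov=cov, loglik=ll, n_obs=len(y),
                       converged=converged, n_iter=it,
                       names=list(names) if names is not None else [])


# --------------------------------------------------------------------------
# per-SD odds ratios with progressive adjustment
# --------------------------------------------------------------------------

@dataclass
class OddsRatioResult:
    marker: str
    tier: str
    or_per_sd: float
    ci_low: float
    ci_high: float
    sd_used: float
    n_cases: int = 0
    n_controls: int = 0


def _complete_cases(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    cols = [c for c in dict.fromkeys(columns) if c in data.columns]
    return data.dropna(subset=cols)


def or_per_sd_progressive(
    data: pd.DataFrame,
    marker: str,
    tiers: list[AdjustmentTier],
    sd_source: str = "pooled",
) -> list[OddsRatioResult]:
    """Odds ratio per 1 SD higher log marker at each adjustment tier.

    Rows are restricted to complete cases for the *largest* tier so that n is
    constant across the ladder.  ``sd_source`` selects the standardization
    sample: the pooled case+control sample (default) or ``"controls"``.
    """
    widest = max(tiers, key=lambda t: len(t.covariates))
    data = _complete_cases(data, [marker] + widest.covariates)
    ref = data[marker] if sd_source == "pooled" else data.loc[data["is_case"] == 0, marker]
    z, sd_used = standardize_log_exposure(data[marker], ref)
    y = data["is_case"].to_numpy(dtype=float)

    out = []
    for tier in tiers:
        Xc, names = build_design(data, tier.covariates)
        X = np.column_stack([Xc, z])
        fit = fit_logistic_irls(X, y, names=names + [marker])
        b = fit.coef[-1]
        se = fit.se()[-1]
        out.append(OddsRatioResult(
            marker=marker, tier=tier.name,
            or_per_sd=float(np.exp(b)),
            ci_low=float(np.exp(b - 1.96 * se)),
            ci_high=float(np.exp(b + 1.96 * se)),
            sd_used=sd_used,
            n_cases=int(y.sum()), n_controls=int((1 - y).sum())))
    return out


# --------------------------------------------------------------------------
# subgroup interaction tests
# --------------------------------------------------------------------------

def tertile_groups(values, controls) -> np.ndarray:
    """Code a continuous modifier into thirds by control tertile cutoffs."""
    cuts = np.percentile(np.asarray(controls, dtype=float), [100 / 3, 200 / 3])
    return np.searchsorted(cuts, np.asarray(values, dtype=float), side="left")


def interaction_lrt(
    data: pd.DataFrame,
    marker: str,
    modifier: str,
    base_tier: AdjustmentTier,
    sd_source: str = "pooled",
) -> dict:
    """Likelihood-ratio test of effect modification.

    Compares logistic models with and without standardized-marker x modifier
    interaction terms; the modifier enters as a categorical variable (code
    continuous modifiers with :func:`tertile_groups` first).
    """
    data = _complete_cases(data, [marker, modifier] + base_tier.covariates)
    mod = data[modifier]
    levels = np.sort(mod.unique())
    if len(levels) < 2:
        raise ValueError(f"modifier {modifier!r} is constant")
    ref = data[marker] if sd_source == "pooled" else data.loc[data["is_case"] == 0, marker]
    z, _ = standardize_log_exposure(data[marker], ref)
    y = data["is_case"].to_numpy(dtype=float)

    base_covs = [c for c in base_tier.covariates if c != modifier]
    Xc, names = build_design(data, base_covs)
    mod_dummies = np.column_stack([(mod == lev).to_numpy(dtype=float)
                                   for lev in levels[1:]])
    reduced = np.column_stack([Xc, mod_dummies, z])
    full = np.column_stack([reduced, mod_dummies * z[:, None]])
    fit_r = fit_logistic_irls(reduced, y)
    fit_f = fit_logistic_irls(full, y)
    lrt = max(0.0, 2.0 * (fit_f.loglik - fit_r.loglik))
    df = mod_dummies.shape[1]
    return {"lrt_statistic": lrt, "df": df,
            "p_value": float(stats.chi2.sf(lrt, df))}


# --------------------------------------------------------------------------
# cross-sectional percentage differences among controls
# --------------------------------------------------------------------------

def percentage_difference(
    controls: pd.DataFrame,
    marker: str,
    covariate: str,
    adjust: list[str] = ("age", "sex", "period"),
) -> dict:
    """Adjusted percentage difference in a marker per covariate contrast.

    Linear regression of the log marker on the covariate plus adjusters,
    among controls.  For a continuous covariate the difference is per 1 SD
    higher covariate, ``100 * (exp(b * SD) - 1)``; for a binary covariate it
    is versus the reference category, ``100 * (exp(b) - 1)``.
    """
    adjust = [a for a in adjust]
    if covariate in adjust:
        raise ValueError(f"covariate {covariate!r} also appears in adjust")
    controls = _complete_cases(controls, [marker, covariate] + adjust)
    Xa, names = build_design(controls, adjust)
    xcov, cname = build_design(controls, [covariate], intercept=False)
    if xcov.shape[1] != 1:
        raise ValueError("covariate must map to a single design column")
    x = xcov[:, 0]
    uniq = np.unique(x)
    binary = set(uniq) <= {0.0, 1.0}
    scale = 1.0 if binary else float(np.std(x, ddof=1))

    X = np.column_stack([Xa, x])
    res = sm.OLS(controls[marker].to_numpy(dtype=float), X).fit()
    b, se = res.params[-1], res.bse[-1]
    lo, hi = b - 1.96 * se, b + 1.96 * se
    return {
        "pct": 100.0 * (np.exp(b * scale) - 1.0),
        "ci_low": 100.0 * (np.exp(lo * scale) - 1.0),
        "ci_high": 100.0 * (np.exp(hi * scale) - 1.0),
        "per": "1 SD" if not binary else "category",
        "n": int(res.nobs),
    }
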