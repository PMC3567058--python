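"""Grouped (fifths) odds ratios with floated variances.

Dose-response shape is assessed by grouping subjects into fifths of the
marker distribution in controls and estimating log-ORs for each fifth against
the bottom fifth.  Conventional contrasts leave the reference group without a
confidence interval and make the displayed intervals correlated; floating
absolute risk assigns every group g its own "floated variance" f_g such that

    Var(log OR_j vs log OR_k)  ~  f_j + f_k    for every pair (j, k).

The floated variances are found by minimizing the Kullback-Leibler divergence
between the true contrast distribution N(0, V) -- V the estimated (K-1)x(K-1)
covariance of the non-reference contrasts -- and the independence
approximation N(0, F) with F = diag(f_1..f_{K-1}) + f_0 * J.  The attained
divergence and the range of approximated/true contrast-SE ratios are reported
so the adequacy of the approximation is visible, in the spirit of the
divergence-based refinement of floating absolute risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .case_control import AdjustmentTier, build_design, fit_logistic_irls


# --------------------------------------------------------------------------
# fifths defined in controls
# --------------------------------------------------------------------------

@dataclass
class QuantileGrouping:
    cutpoints: np.ndarray              # 4 interior cutpoints, log units
    group: np.ndarray                  # per-subject fifth in 1..5
    geometric_means: np.ndarray        # original-scale geometric mean per fifth


def control_quintile_cutpoints(
    values, is_control, n_groups: int = 5
) -> QuantileGrouping:
    """Assign all subjects to fifths using control-based cutpoints.

    Cutpoints sit at the 20/40/60/80 empirical percentiles of the control
    distribution, with percentiles defined by linear interpolation of the
    empirical CDF; ties on a cutpoint go to the lower fifth.  Geometric means
    are computed per fifth on the original (unlogged) scale from all subjects.
    """
    values = np.asarray(values, dtype=float)
    is_control = np.asarray(is_control, dtype=bool)
    ctrl = values[is_control]
    if len(np.unique(ctrl)) < n_groups:
        raise ValueError(
            f"need at least {n_groups} distinct control values, "
            f"got {len(np.unique(ctrl))}")
    qs = 100.0 * np.arange(1, n_groups) / n_groups
    cutpoints = np.percentile(ctrl, qs, method="linear")
    group = 1 + np.searchsorted(cutpoints, values, side="left")
    counts = np.bincount(group[is_control], minlength=n_groups + 1)[1:]
    if counts.max() - counts.min() > 1 and len(np.unique(ctrl)) < len(ctrl):
        warnings.warn("tied control values make fifths unbalanced "
                      f"(control counts {counts.tolist()})")
    gm = np.array([np.exp(values[group == g].mean()) if np.any(group == g)
                   else np.nan for g in range(1, n_groups + 1)])
    return QuantileGrouping(cutpoints=cutpoints, group=group, geometric_means=gm)


def fit_quantile_group_model(
    data: pd.DataFrame,
    grouping: QuantileGrouping,
    tier: AdjustmentTier,
) -> dict:
    """Adjusted log-ORs of fifths 2..K against the bottom fifth.

    Logistic regression on K-1 fifth indicators plus the tier covariates;
    returns the indicator coefficient block and its covariance.
    """
    y = data["is_case"].to_numpy(dtype=float)
    g = np.asarray(grouping.group)
    K = int(g.max())
    for k in range(1, K + 1):
        sel = g == k
        if not (np.any(y[sel] == 1) and np.any(y[sel] == 0)):
            raise ValueError(f"fifth {k} lacks cases or controls")
    dummies = np.column_stack([(g == k).astype(float) for k in range(2, K + 1)])
    Xc, names = build_design(data, tier.covariates)
    X = np.column_stack([Xc, dummies])
    fit = fit_logistic_irls(X, y, names=names + [f"fifth_{k}" for k in range(2, K + 1)])
    p = Xc.shape[1]
    return {
        "contrasts": fit.coef[p:],
        "cov": fit.cov[p:, p:],
        "n_cases": np.array([int(y[g == k].sum()) for k in range(1, K + 1)]),
        "n_controls": np.array([int((1 - y)[g == k].sum()) for k in range(1, K + 1)]),
        "fit": fit,
    }


# --------------------------------------------------------------------------
# floated variances via KL minimization
# --------------------------------------------------------------------------

@dataclass
class FloatedVariances:
    f: np.ndarray                  # K floated variances, reference first
    kl_divergence: float           # nats, attained at the optimum
    se_ratio_range: tuple[float, float]

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)


def _kl_to_independence(log_f: np.ndarray, V: np.ndarray) -> float:
    """KL( N(0,V) || N(0,F) ) with F = diag(f_1..) + f_0 J, f = exp(log_f)."""
    f = np.exp(log_f)
    m = V.shape[0]
    F = np.diag(f[1:]) + f[0]
    sign, logdet_F = np.linalg.slogdet(F)
    if sign <= 0:
        return np.inf
    _, logdet_V = np.linalg.slogdet(V)
    Finv = np.linalg.inv(F)
    return 0.5 * (np.trace(Finv @ V) - m + logdet_F - logdet_V)


def _kl_grad(log_f: np.ndarray, V: np.ndarray) -> np.ndarray:
    f = np.exp(log_f)
    F = np.diag(f[1:]) + f[0]
    Finv = np.linalg.inv(F)
    dF = 0.5 * (Finv - Finv @ V @ Finv)      # dKL/dF
    g = np.empty_like(f)
    g[0] = dF.sum()
    g[1:] = np.diag(dF)
    return g * f                              # chain rule through exp


def heuristic_init(V: np.ndarray) -> np.ndarray:
    """Moment-style starting values: f_0 from the mean off-diagonal
    covariance (the value that would decorrelate a compound-symmetric V),
    the rest from the residual diagonal."""
    m = V.shape[0]
    if m > 1:
        off = V[~np.eye(m, dtype=bool)]
        f0 = float(np.mean(off))
    else:
        f0 = 0.5 * float(V[0, 0])
    f0 = max(f0, 1e-4 * float(np.max(np.diag(V))))
    rest = np.maximum(np.diag(V) - f0, 1e-4 * float(np.max(np.diag(V))))
    return np.concatenate([[f0], rest])


def float_variances(contrast_cov: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 500) -> FloatedVariances:
    """Fit K floated variances to a (K-1)x(K-1) contrast covariance.

    Minimizes the KL divergence between N(0, V) and the floating-risk
    approximation by quasi-Newton descent on log f (positivity for free),
    started from a moment heuristic.  K = 2 is rejected: only f_0 + f_1 is
    identified from a single contrast variance.
    """
    V = np.asarray(contrast_cov, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("contrast covariance must be square")
    if V.shape[0] < 2:
        raise ValueError("K = 2 floated variances are not identified "
                         "(only f_0 + f_1 enters the likelihood)")
    if not np.allclose(V, V.T, rtol=1e-8, atol=1e-12):
        raise ValueError("contrast covariance must be symmetric")
    if np.linalg.eigvalsh(V).min() <= 0:
        raise ValueError("contrast covariance must be positive-definite")

    x0 = np.log(heuristic_init(V))
    res = optimize.minimize(
        _kl_to_independence, x0, args=(V,), jac=_kl_grad, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12})
    if not np.isfinite(res.fun):
        raise RuntimeError("floated-variance optimization failed to converge")
    f = np.exp(res.x)
    return FloatedVariances(
        f=f, kl_divergence=float(res.fun),
        se_ratio_range=se_ratio_range(f, V))


def se_ratio_range(f: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    """Min/max over all group pairs of approximated / true contrast SE."""
    f = np.asarray(f, dtype=float)
    m = V.shape[0]
    ratios = []
    for j in range(m):            # pairs with the reference group
        ratios.append(np.sqrt((f[0] + f[j + 1]) / V[j, j]))
    for j in range(m):
        for k in range(j + 1, m):
            true = V[j, j] + V[k, k] - 2 * V[j, k]
            ratios.append(np.sqrt((f[j + 1] + f[k + 1]) / true))
    return (float(np.min(ratios)), float(np.max(ratios)))


def floated_group_intervals(contrasts: np.ndarray,
                            floated: FloatedVariances) -> pd.DataFrame:
    """Per-fifth log-OR and floated 95% CI, reference fifth included.

    The reference estimate is 0 (OR 1.0) with the finite interval
    ``±1.96 sqrt(f_0)``; group g gets ``estimate ± 1.96 sqrt(f_g)``.
    """
    est = np.concatenate([[0.0], np.asarray(contrasts, dtype=float)])
    se = np.sqrt(floated.f)
    return pd.DataFrame({
        "group": np.arange(1, len(est) + 1),
        "log_or": est,
        "or": np.exp(est),
        "ci_low": np.exp(est - 1.96 * se),
        "ci_high": np.exp(est + 1.96 * se),
        "floated_variance": floated.f,
    })


def quintile_or_table(
    data: pd.DataFrame,
    marker: str,
    tier: AdjustmentTier,
) -> pd.DataFrame:
    """End-to-end fifths analysis for one marker: grouping, adjusted model,
    floated variances, and the per-fifth OR table with geometric means."""
    data = data.dropna(subset=[marker] + [c for c in tier.covariates if c in data.columns])
    grouping = control_quintile_cutpoints(
        data[marker].to_numpy(), data["is_case"].to_numpy() == 0)
    model = fit_quantile_group_model(data, grouping, tier)
    floated = float_variances(model["cov"])
    tab = floated_group_intervals(model["contrasts"], floated)
    tab.insert(0, "marker", marker)
    tab["geometric_mean"] = grouping.geometric_means
    tab["n_cases"] = model["n_cases"]
    tab["n_controls"] = model["n_controls"]
    return tab
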