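"""Regression dilution ratios, usual levels, and corrected odds ratios.

A single baseline biomarker measurement is an error-prone snapshot of the
long-term average ("usual") level, so per-SD odds ratios estimated from
baseline values are attenuated toward the null.  With a repeat measurement
taken years later in a subsample, the regression dilution ratio (RDR) --
the slope from regressing the repeat on the baseline, adjusted for
confounders such as age and sex -- estimates the attenuation factor under
the classical error model.  Participant-level predictions from that
calibration regression ("usual levels") replace the baseline values in the
outcome model to yield ORs corrected for within-person variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .case_control import (AdjustmentTier, OddsRatioResult, build_design,
                           fit_logistic_irls, standardize_log_exposure)


@dataclass
class RdrEstimate:
    rdr: float
    se: float
    ci_low: float
    ci_high: float
    n_pairs: int
    adjust: list[str]
    model: object = None       # fitted calibration regression (statsmodels)
    columns: list[str] = None  # design column order used for prediction


def serial_pairs(data: pd.DataFrame, marker: str) -> pd.DataFrame:
    """Rows of ``data`` with a non-missing repeat for ``marker``, renamed to
    the generic (baseline, repeat) calibration layout."""
    base, rep = f"{marker}_log_base", f"{marker}_log_rep"
    pairs = data.dropna(subset=[base, rep]).copy()
    pairs["baseline"] = pairs[base]
    pairs["repeat"] = pairs[rep]
    return pairs


def estimate_rdr(pairs: pd.DataFrame,
                 adjust: list[str] = ("age", "sex")) -> RdrEstimate:
    """Regression dilution ratio from serial pairs.

    Linear regression of the repeat measurement on the baseline measurement
    plus adjusters; the RDR is the baseline coefficient, with a Wald 95% CI.
    When several repeats per person exist, average them before calling.
    """
    adjust = list(adjust)
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 serial pairs, got {len(pairs)}")
    b = pairs["baseline"].to_numpy(dtype=float)
    if np.std(b) == 0:
        raise ValueError("baseline values have zero variance")
    Xa, names = build_design(pairs, adjust)
    X = np.column_stack([Xa, b])
    res = sm.OLS(pairs["repeat"].to_numpy(dtype=float), X).fit()
    rdr, se = float(res.params[-1]), float(res.bse[-1])
    return RdrEstimate(
        rdr=rdr, se=se, ci_low=rdr - 1.96 * se, ci_high=rdr + 1.96 * se,
        n_pairs=len(pairs), adjust=adjust, model=res,
        columns=names + ["baseline"])


def predict_usual_levels(baseline, rdr_model: RdrEstimate,
                         covariates: pd.DataFrame | None = None) -> np.ndarray:
    """Predicted usual levels for every participant.

    Applies the calibration regression's fitted-value formula to all
    participants (not only the repeat subsample): predictions shrink each
    baseline toward its conditional mean with slope equal to the RDR.
    """
    baseline = np.asarray(baseline, dtype=float)
    adjust = rdr_model.adjust
    if adjust:
        if covariates is None:
            raise ValueError(f"calibration model adjusts for {adjust}; pass covariates")
        missing = [c for c in adjust if c not in covariates.columns and c != "period"]
        if missing:
            raise ValueError(f"covariates missing for prediction: {missing}")
        Xa, names = build_design(covariates, adjust)
    else:
        Xa = np.ones((len(baseline), 1))
        names = ["const"]
    if names != rdr_model.columns[:-1]:
        raise ValueError(
            f"prediction design {names} does not match calibration design "
            f"{rdr_model.columns[:-1]}")
    X = np.column_stack([Xa, baseline])
    return X @ rdr_model.model.params


def corrected_or_per_sd(
    data: pd.DataFrame,
    marker: str,
    tier: AdjustmentTier,
    calib_adjust: list[str] = ("age", "sex"),
    ci_method: str = "bootstrap",
    n_boot: int = 500,
    seed: int = 0,
    sd_source: str = "pooled",
    calib_pairs: pd.DataFrame | None = None,
) -> OddsRatioResult:
    """Per-SD odds ratio corrected for within-person variability.

    Two stages: (1) calibration -- regress repeat on baseline (+``calib_adjust``)
    in the repeat subsample; (2) outcome -- refit the per-SD logistic model
    with predicted usual levels in place of baseline.  Usual levels are
    standardized by the *baseline* SD, keeping "per 1 SD" on the familiar
    baseline scale.  ``ci_method="naive"`` reuses the outcome-model Wald CI
    (ignoring calibration uncertainty); ``"bootstrap"`` resamples
    participants and re-runs both stages, returning percentile CIs.  By
    default calibration uses the repeat pairs inside ``data``; pass
    ``calib_pairs`` to calibrate on a larger serial-measurement table (e.g.
    the full cohort's repeat subsample).
    """
    base_col = f"{marker}_log_base"
    need = [base_col] + [c for c in tier.covariates if c in data.columns]
    data = data.dropna(subset=need).reset_index(drop=True)
    if calib_pairs is None:
        calib_pairs = serial_pairs(data, marker)

    def one_pass(df: pd.DataFrame, pairs: pd.DataFrame) -> tuple[float, float, float]:
        rdr_fit = estimate_rdr(pairs, adjust=calib_adjust)
        usual = predict_usual_levels(df[base_col], rdr_fit, covariates=df)
        ref = (df[base_col] if sd_source == "pooled"
               else df.loc[df["is_case"] == 0, base_col])
        sd_used = float(np.std(np.asarray(ref, dtype=float), ddof=1))
        z = (usual - float(np.mean(np.asarray(ref, dtype=float)))) / sd_used
        Xc, names = build_design(df, tier.covariates)
        fit = fit_logistic_irls(np.column_stack([Xc, z]),
                                df["is_case"].to_numpy(dtype=float))
        return float(fit.coef[-1]), float(fit.se()[-1]), sd_used

    b, se, sd_used = one_pass(data, calib_pairs)
    n_cases = int(data["is_case"].sum())
    n_controls = int(len(data) - n_cases)

    if ci_method == "naive":
        lo, hi = b - 1.96 * se, b + 1.96 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        attempts = 0
        while len(reps) < n_boot and attempts < 3 * n_boot:
            attempts += 1
            df_b = data.sample(n=len(data), replace=True,
                               random_state=rng.integers(0, 2**31 - 1))
            pairs_b = calib_pairs.sample(n=len(calib_pairs), replace=True,
                                         random_state=rng.integers(0, 2**31 - 1))
            try:
                reps.append(one_pass(df_b.reset_index(drop=True),
                                     pairs_b.reset_index(drop=True))[0])
            except (ValueError, RuntimeError):
                continue   # degenerate resample (e.g. too few repeat pairs)
        if len(reps) < n_boot // 2:
            raise RuntimeError("bootstrap failed on most resamples")
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return OddsRatioResult(
        marker=marker, tier=tier.name, or_per_sd=float(np.exp(b)),
        ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
        sd_used=sd_used, n_cases=n_cases, n_controls=n_controls)


def rdr_time_trend(estimates: pd.DataFrame) -> dict:
    """Trend of within-person self-correlation/RDR with time between
    measurements.

    Inverse-variance-weighted linear regression of the estimate on the gap
    (years); expects columns ``estimate``, ``se``, ``gap_years``.  Returns
    the slope per year with SE and a two-sided normal-theory p-value.
    """
    est = np.asarray(estimates["estimate"], dtype=float)
    se = np.asarray(estimates["se"], dtype=float)
    gap = np.asarray(estimates["gap_years"], dtype=float)
    if len(est) < 3:
        raise ValueError("need at least 3 estimates")
    if np.ptp(gap) == 0:
        raise ValueError("all gaps equal; trend not identified")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    X = np.column_stack([np.ones_like(gap), gap])
    res = sm.WLS(est, X, weights=1.0 / se**2).fit()
    slope, slope_se = float(res.params[1]), float(res.bse[1])
    z = slope / slope_se
    return {"slope": slope, "se": slope_se,
            "p": float(2 * stats.norm.sf(abs(z)))}
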