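"""Synthetic prospective cohort with a nested case-control sample.

This module emulates the data structure of a large population-based cohort in
which three hemostatic markers -- t-PA antigen, D-dimer and von Willebrand
factor (VWF) -- were measured at baseline, CHD events accrued over long
follow-up, and a frequency-matched nested case-control sample was drawn.

Ground truth is fully known: each participant has a latent "usual" (long-term
average) log-marker level, and the stored baseline and repeat measurements are
the usual level plus independent classical measurement error.  The error
variance is calibrated so that regressing a repeat measurement on baseline
recovers a chosen regression dilution ratio (RDR):

    sigma2_error = sigma2_usual * (1 - RDR) / RDR

equivalently sigma2_usual = RDR * sigma2_baseline, so the per-marker
``marker_log_sds`` are the *observed baseline* SDs, matching how such studies
report them.  Disease risk follows a logistic model in the standardized usual
levels and covariates, which makes attenuation and dilution-correction
behaviour analytically predictable.
"""

from __future__ import annotations

import dataclasses
import io
import json
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

MARKERS = ("tpa", "ddimer", "vwf")

#: fixed participant CSV header; repeats may be empty (missing)
CSV_COLUMNS = [
    "id", "age", "sex", "period", "smoking", "diabetes", "bmi", "sbp",
    "tchol", "log_tg", "tpa_log_base", "ddimer_log_base", "vwf_log_base",
    "tpa_log_rep", "ddimer_log_rep", "vwf_log_rep", "is_case",
]

#: internal ground-truth columns kept in memory but never written to CSV
USUAL_COLUMNS = ["tpa_log_usual", "ddimer_log_usual", "vwf_log_usual"]


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named random substream: independent, reproducible child of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# --------------------------------------------------------------------------
# cohort specification
# --------------------------------------------------------------------------

def _default_covariate_params() -> dict:
    # control-group summaries of a middle-aged European cohort
    return {
        "smoking_prev": 0.48,
        "diabetes_prev": 0.02,
        "bmi_mean": 25.4, "bmi_sd": 3.7,
        "sbp_mean": 141.9, "sbp_sd": 20.1,
        "tchol_mean": 6.4, "tchol_sd": 1.1,
        "log_tg_mean": 0.0, "log_tg_sd": 0.4,
    }


def _default_covariate_log_ors() -> dict:
    # log-odds of CHD per 1 SD of continuous covariates / per category of
    # binary ones; moderate conventional-risk-factor effects
    return {
        "age": 0.5, "male": 0.6, "smoking": 0.5, "diabetes": 0.6,
        "bmi": 0.10, "sbp": 0.25, "tchol": 0.30, "log_tg": 0.10,
    }


def _default_marker_loadings() -> dict:
    # log-marker shift (t-PA, D-dimer, VWF) per 1 SD of each covariate.
    # Signs follow the observed cross-sectional pattern: t-PA antigen rises
    # with adiposity/lipids/blood pressure while D-dimer falls, and VWF is
    # largely independent of conventional risk factors.  Magnitudes are about
    # half the marginal associations so that, with mutually independent
    # covariates, the jointly explained variance stays below the usual-level
    # variance implied by the target RDRs.
    return {
        "age": (0.04, 0.11, 0.045),
        "male": (0.105, -0.165, 0.015),
        "smoking": (0.02, 0.035, 0.025),
        "diabetes": (-0.015, -0.05, 0.03),
        "bmi": (0.09, -0.085, 0.005),
        "sbp": (0.05, -0.03, 0.005),
        "tchol": (0.035, -0.025, 0.0),
        "log_tg": (0.095, -0.075, 0.01),
    }


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults describe the emulated study: ~19,000 middle-aged participants
    recruited in five stages, log-marker baseline SDs (0.5, 1.0, 0.4) for
    t-PA antigen, D-dimer and VWF, an inverse t-PA/D-dimer correlation,
    RDR targets (0.47, 0.30, 0.55) over an 11.6-year repeat gap, and roughly
    a 10% cumulative CHD risk.
    """

    n_participants: int = 18912
    n_periods: int = 5
    age_range: tuple[float, float] = (33.0, 86.0)
    male_fraction: float = 0.48
    covariate_params: dict = field(default_factory=_default_covariate_params)
    marker_log_means: tuple[float, float, float] = (2.5, 4.8, 4.6)
    marker_log_sds: tuple[float, float, float] = (0.5, 1.0, 0.4)
    marker_corr: tuple = ((1.0, -0.35, 0.20), (-0.35, 1.0, 0.25), (0.20, 0.25, 1.0))
    covariate_marker_loadings: dict = field(default_factory=_default_marker_loadings)
    target_rdrs: tuple[float, float, float] = (0.47, 0.30, 0.55)
    repeat_gap_years: float = 11.6
    repeat_subsample_n: int = 371
    rdr_decay_per_year: float = 0.0
    true_log_or_per_sd: tuple[float, float, float] = (
        float(np.log(1.15)), float(np.log(1.11)), float(np.log(1.10)))
    covariate_log_ors: dict = field(default_factory=_default_covariate_log_ors)
    baseline_risk: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 100:
            raise ValueError("n_participants must be >= 100")
        corr = np.asarray(self.marker_corr, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ValueError("marker_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("marker_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("marker_corr is not positive-definite")
        sds = np.asarray(self.marker_log_sds, dtype=float)
        if np.any(sds <= 0):
            raise ValueError("marker_log_sds must be positive")
        rdrs = np.asarray(self.target_rdrs, dtype=float)
        if np.any(rdrs <= 0) or np.any(rdrs > 1):
            raise ValueError("target_rdrs must lie in (0, 1]")
        if not 0 < self.male_fraction < 1:
            raise ValueError("male_fraction must be in (0, 1)")
        if not 0 < self.baseline_risk < 1:
            raise ValueError("baseline_risk must be in (0, 1)")

    # ---- lossless round-trip serialization ----

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_marker_loadings"] = {
            k: list(v) for k, v in d["covariate_marker_loadings"].items()}
        d["marker_corr"] = [list(r) for r in d["marker_corr"]]
        for k in ("age_range", "marker_log_means", "marker_log_sds",
                  "target_rdrs", "true_log_or_per_sd"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for k in ("age_range", "marker_log_means", "marker_log_sds",
                  "target_rdrs", "true_log_or_per_sd"):
            if k in d:
                d[k] = tuple(float(x) for x in d[k])
        if "marker_corr" in d:
            d["marker_corr"] = tuple(tuple(float(x) for x in r) for r in d["marker_corr"])
        if "covariate_marker_loadings" in d:
            d["covariate_marker_loadings"] = {
                k: tuple(float(x) for x in v)
                for k, v in d["covariate_marker_loadings"].items()}
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "CohortSpec":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(io.StringIO(source))
        return cls.from_dict(data)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _covariate_design(spec: CohortSpec, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Standardized covariate matrix (population-parameter standardization)."""
    p = spec.covariate_params
    lo, hi = spec.age_range
    age_sd = (hi - lo) / np.sqrt(12.0)
    cols = {
        "age": (df["age"] - (lo + hi) / 2.0) / age_sd,
        "male": ((df["sex"] == "male").astype(float) - spec.male_fraction)
                / np.sqrt(spec.male_fraction * (1 - spec.male_fraction)),
        "smoking": (df["smoking"] - p["smoking_prev"])
                   / np.sqrt(p["smoking_prev"] * (1 - p["smoking_prev"])),
        "diabetes": (df["diabetes"] - p["diabetes_prev"])
                    / np.sqrt(p["diabetes_prev"] * (1 - p["diabetes_prev"])),
        "bmi": (df["bmi"] - p["bmi_mean"]) / p["bmi_sd"],
        "sbp": (df["sbp"] - p["sbp_mean"]) / p["sbp_sd"],
        "tchol": (df["tchol"] - p["tchol_mean"]) / p["tchol_sd"],
        "log_tg": (df["log_tg"] - p["log_tg_mean"]) / p["log_tg_sd"],
    }
    names = list(cols)
    return np.column_stack([np.asarray(cols[c], dtype=float) for c in names]), names


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one synthetic cohort as a participant table.

    Returns a DataFrame with the fixed participant columns plus the latent
    ``*_log_usual`` ground-truth columns.  Reproducible: the same spec (and
    seed) yields an identical table.
    """
    spec.validate()
    n = spec.n_participants
    p = spec.covariate_params

    rng_cov = _stream(spec.seed, "covariates")
    df = pd.DataFrame({"id": np.arange(n, dtype=np.int64)})
    df["age"] = rng_cov.uniform(*spec.age_range, size=n)
    df["sex"] = np.where(rng_cov.random(n) < spec.male_fraction, "male", "female")
    df["period"] = rng_cov.integers(0, spec.n_periods, size=n)
    df["smoking"] = (rng_cov.random(n) < p["smoking_prev"]).astype(int)
    df["diabetes"] = (rng_cov.random(n) < p["diabetes_prev"]).astype(int)
    df["bmi"] = rng_cov.normal(p["bmi_mean"], p["bmi_sd"], size=n)
    df["sbp"] = rng_cov.normal(p["sbp_mean"], p["sbp_sd"], size=n)
    df["tchol"] = rng_cov.normal(p["tchol_mean"], p["tchol_sd"], size=n)
    df["log_tg"] = rng_cov.normal(p["log_tg_mean"], p["log_tg_sd"], size=n)

    # latent usual log-levels: covariate loadings + correlated residual
    Z, znames = _covariate_design(spec, df)
    B = np.array([spec.covariate_marker_loadings.get(c, (0.0, 0.0, 0.0))
                  for c in znames], dtype=float)          # (p, 3)
    sd_base = np.asarray(spec.marker_log_sds, dtype=float)
    rdr = np.asarray(spec.target_rdrs, dtype=float)
    sd_usual = np.sqrt(rdr) * sd_base
    corr = np.asarray(spec.marker_corr, dtype=float)
    cov_usual = corr * np.outer(sd_usual, sd_usual)
    cov_resid = cov_usual - B.T @ B
    ev = np.linalg.eigvalsh(cov_resid)
    if ev.min() <= 0:
        raise ValueError(
            "covariate_marker_loadings explain more (co)variance than the "
            "usual-level covariance implied by marker_log_sds, marker_corr "
            f"and target_rdrs allows (min residual eigenvalue {ev.min():.4g})")

    rng_mark = _stream(spec.seed, "markers")
    L = np.linalg.cholesky(cov_resid)
    usual = (np.asarray(spec.marker_log_means, dtype=float)
             + Z @ B + rng_mark.standard_normal((n, 3)) @ L.T)

    # classical measurement error calibrated to the target RDRs
    sd_err = np.sqrt(np.maximum(cov_usual.diagonal() * (1 - rdr) / rdr, 0.0))
    rng_err = _stream(spec.seed, "measurement_error")
    baseline = usual + rng_err.standard_normal((n, 3)) * sd_err

    # repeat measurements in a random subsample; optional drift of the usual
    # level lowers the baseline-repeat self-correlation with gap length
    rng_rep = _stream(spec.seed, "repeats")
    rep_ids = rng_rep.choice(n, size=min(spec.repeat_subsample_n, n), replace=False)
    lam = max(0.0, 1.0 - spec.rdr_decay_per_year * spec.repeat_gap_years)
    mu = np.asarray(spec.marker_log_means, dtype=float)
    if lam < 1.0:
        usual_rep = mu + lam * (usual[rep_ids] - mu - Z[rep_ids] @ B) + Z[rep_ids] @ B
        drift_cov = (1.0 - lam ** 2) * cov_resid
        usual_rep = usual_rep + rng_rep.standard_normal(
            (len(rep_ids), 3)) @ np.linalg.cholesky(drift_cov).T
    else:
        usual_rep = usual[rep_ids]
    repeat = np.full((n, 3), np.nan)
    repeat[rep_ids] = usual_rep + rng_rep.standard_normal((len(rep_ids), 3)) * sd_err

    # logistic event model in standardized usual levels + covariates
    beta_m = np.asarray(spec.true_log_or_per_sd, dtype=float)
    z_usual = (usual - mu) / sd_base          # per baseline-SD convention
    beta_cov = np.array([spec.covariate_log_ors.get(c, 0.0) for c in znames])
    lp = (np.log(spec.baseline_risk / (1 - spec.baseline_risk))
          + z_usual @ beta_m + Z @ beta_cov)
    rng_case = _stream(spec.seed, "events")
    df["is_case"] = (rng_case.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)

    for j, m in enumerate(MARKERS):
        df[f"{m}_log_base"] = baseline[:, j]
        df[f"{m}_log_rep"] = repeat[:, j]
        df[f"{m}_log_usual"] = usual[:, j]
    return df[CSV_COLUMNS + USUAL_COLUMNS]


# --------------------------------------------------------------------------
# nested case-control sampling
# --------------------------------------------------------------------------

@dataclass
class CaseControlSet:
    """Ids of cases and frequency-matched controls from one cohort."""
    case_ids: np.ndarray
    control_ids: np.ndarray
    matching_factors: list[str]
    ratio: float

    def subset(self, cohort: pd.DataFrame) -> pd.DataFrame:
        ids = np.concatenate([self.case_ids, self.control_ids])
        return cohort.set_index("id").loc[ids].reset_index()


def _matching_key(cohort: pd.DataFrame, matching: list[str]) -> pd.Series:
    parts = []
    for f in matching:
        if f == "age_band":
            parts.append((np.floor(cohort["age"] / 5.0) * 5).astype(int).astype(str))
        elif f in cohort.columns:
            parts.append(cohort[f].astype(str))
        else:
            raise KeyError(f"matching factor {f!r} not in cohort")
    key = parts[0]
    for pt in parts[1:]:
        key = key + "|" + pt
    return key


def sample_nested_case_control(
    cohort: pd.DataFrame,
    ratio: float,
    matching: list[str] = ("sex", "age_band", "period"),
    seed: int = 0,
) -> CaseControlSet:
    """Draw all cases plus frequency-matched controls.

    Within each joint stratum of the matching factors, ``round(ratio * cases)``
    controls are sampled without replacement from the stratum's non-cases.
    Strata with too few eligible controls contribute all of them (a warning
    is emitted), mirroring practical frequency matching.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    matching = list(matching)
    key = _matching_key(cohort, matching)
    is_case = cohort["is_case"].to_numpy().astype(bool)
    rng = _stream(seed, "ncc_sampling")

    case_ids = cohort.loc[is_case, "id"].to_numpy()
    control_ids = []
    for stratum, idx in cohort.groupby(key, sort=True).groups.items():
        sub_case = is_case[cohort.index.get_indexer(idx)]
        n_cases = int(sub_case.sum())
        if n_cases == 0:
            continue
        pool = cohort.loc[idx][~sub_case]["id"].to_numpy()
        want = int(round(ratio * n_cases))
        if want > len(pool):
            warnings.warn(
                f"stratum {stratum!r}: wanted {want} controls, only "
                f"{len(pool)} non-cases available; taking all")
            want = len(pool)
        control_ids.append(rng.choice(pool, size=want, replace=False))
    controls = np.sort(np.concatenate(control_ids)) if control_ids else np.array([], dtype=np.int64)
    return CaseControlSet(
        case_ids=np.sort(case_ids), control_ids=controls,
        matching_factors=matching, ratio=float(ratio))


# --------------------------------------------------------------------------
# CSV / spec I/O
# --------------------------------------------------------------------------

def write_participants_csv(df: pd.DataFrame, path) -> None:
    """Write the fixed-header participant CSV (missing repeats → empty)."""
    df[CSV_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_participants_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"participant CSV missing columns: {missing}")
    return df[CSV_COLUMNS]


def casecontrol_to_json(cc: CaseControlSet) -> str:
    return json.dumps({
        "case_ids": cc.case_ids.tolist(),
        "control_ids": cc.control_ids.tolist(),
        "matching_factors": cc.matching_factors,
        "ratio": cc.ratio,
    })
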