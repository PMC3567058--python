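"""Config-driven orchestration of the full analysis skeleton.

Runs the nested case-control analysis (per-SD ORs across adjustment tiers,
fifths with floated variances, cross-sectional percentage differences,
subgroup interaction tests, RDR estimation and dilution-corrected ORs) and
the per-SD harmonized meta-analysis, on synthetic or user-supplied CSVs.
Every run writes plain CSV tables plus a JSON manifest (seed, config hash,
package versions, emitted files with row counts) from which the outputs are
exactly re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .case_control import (default_tiers, interaction_lrt, or_per_sd_progressive,
                           percentage_difference, tertile_groups)
from .floated_risk import quintile_or_table
from .meta import (HarmonizedEffect, egger_test, generate_study_estimates,
                   harmonize_to_per_sd, meta_regress, pool_random_effects,
                   read_estimates_csv, subgroup_compare, write_estimates_csv)
from .regression_dilution import corrected_or_per_sd, estimate_rdr, serial_pairs
from .synthetic_cohort import (MARKERS, CohortSpec, generate_cohort,
                               read_participants_csv, sample_nested_case_control,
                               write_participants_csv)

log = logging.getLogger("hemorisk")

MARKER_BASE = {m: f"{m}_log_base" for m in MARKERS}

#: Table-1-style covariate list for cross-sectional percentage differences
PCT_DIFF_COVARIATES = ["age", "sex", "smoking", "diabetes", "bmi", "sbp",
                       "tchol", "log_tg"]

#: default effect-modifier list for subgroup interaction tests
INTERACTION_MODIFIERS = ["sex", "smoking", "diabetes", "bmi", "tchol"]


@dataclass
class RunConfig:
    """Everything one run needs; fully determines the outputs given the seed."""
    mode: str = "all"                       # simulate|casecontrol|rdr|meta|all
    out_dir: str = "hemorisk_out"
    seed: int = 0
    participants_csv: str | None = None     # None -> simulate
    estimates_csv: str | None = None        # None -> simulate
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    control_ratio: float = 1.88
    matching: list[str] = field(default_factory=lambda: ["sex", "age_band", "period"])
    sd_source: str = "pooled"               # or "controls"
    ci_method: str = "bootstrap"            # corrected-OR CIs: bootstrap|naive
    n_boot: int = 500
    # meta simulation parameters: per-marker true per-SD log RR
    meta_k: int = 18
    meta_true_log_rr: dict = field(default_factory=lambda: {
        "tpa": float(np.log(1.13)), "ddimer": float(np.log(1.23)),
        "vwf": float(np.log(1.16))})
    meta_tau2: float = 0.01
    meta_bias: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)      # location does not affect the results
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(out_dir / "run.log", mode="a")
    fh.setFormatter(fmt)
    log.addHandler(fh)
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    log.addHandler(sh)


class _Manifest:
    def __init__(self, config: RunConfig):
        self.config = config
        self.files: dict[str, dict] = {}
        self.t0 = time.time()

    def emit(self, name: str, df: pd.DataFrame, out_dir: Path) -> Path:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        self.files[name] = {"path": path.name, "rows": int(len(df))}
        log.info("wrote %s (%d rows)", path.name, len(df))
        return path

    def write(self, out_dir: Path) -> Path:
        # merge with an existing manifest from the same configuration so
        # multi-stage runs list every emitted file
        path = out_dir / "manifest.json"
        files = dict(self.files)
        if path.exists():
            try:
                prev = json.loads(path.read_text())
                if prev.get("config_hash") == self.config.config_hash():
                    files = {**prev.get("files", {}), **files}
            except (json.JSONDecodeError, OSError):
                pass
        payload = {
            "seed": self.config.seed,
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "versions": {
                "hemorisk": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "files": files,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        log.info("manifest written (%.2fs elapsed)", time.time() - self.t0)
        return path


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _load_or_simulate_participants(config: RunConfig, out_dir: Path,
                                   manifest: _Manifest) -> pd.DataFrame:
    if config.participants_csv is not None:
        df = read_participants_csv(config.participants_csv)
        log.info("loaded %d participants from %s", len(df), config.participants_csv)
        return df
    spec = CohortSpec.from_dict({**config.cohort, "seed": config.seed})
    cohort = generate_cohort(spec)
    log.info("simulated cohort: n=%d, cases=%d", len(cohort),
             int(cohort["is_case"].sum()))
    cc = sample_nested_case_control(cohort, config.control_ratio,
                                    config.matching, seed=config.seed)
    sample = cc.subset(cohort)
    log.info("nested case-control sample: %d cases, %d controls",
             len(cc.case_ids), len(cc.control_ids))
    write_participants_csv(sample, out_dir / "participants.csv")
    manifest.files["participants"] = {"path": "participants.csv",
                                      "rows": int(len(sample))}
    return sample.drop(columns=[c for c in sample.columns
                                if c.endswith("_log_usual")], errors="ignore")


def run_casecontrol_analysis(config: RunConfig) -> dict:
    """Full case-control stage; returns the manifest payload."""
    out_dir = Path(config.out_dir)
    setup_logging(out_dir)
    manifest = _Manifest(config)
    data = _load_or_simulate_participants(config, out_dir, manifest)

    n0 = len(data)
    tiers = default_tiers()
    widest = tiers[-1].covariates
    data = data.dropna(subset=list(MARKER_BASE.values())
                       + [c for c in widest if c in data.columns])
    log.info("complete-case restriction: %d -> %d participants", n0, len(data))
    controls = data[data["is_case"] == 0]

    # Table-1-style adjusted percentage differences among controls
    rows = []
    for cov in PCT_DIFF_COVARIATES:
        for m in MARKERS:
            adj = [a for a in ("age", "sex", "period") if a != cov]
            r = percentage_difference(controls, MARKER_BASE[m], cov, adjust=adj)
            rows.append({"covariate": cov, "marker": m, **r})
    manifest.emit("percentage_differences", pd.DataFrame(rows), out_dir)

    # Table-2-style per-SD ORs across the adjustment ladder
    rows = []
    for m in MARKERS:
        for r in or_per_sd_progressive(data, MARKER_BASE[m], tiers,
                                       sd_source=config.sd_source):
            rows.append({"marker": m, "tier": r.tier, "or": r.or_per_sd,
                         "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "sd_used": r.sd_used, "n_cases": r.n_cases,
                         "n_controls": r.n_controls})
    or_table = pd.DataFrame(rows)
    manifest.emit("or_per_sd", or_table, out_dir)

    # Fig-2-style fifths with floated variances
    fifths = pd.concat([quintile_or_table(data, MARKER_BASE[m], tiers[-1])
                        .assign(marker=m) for m in MARKERS])
    manifest.emit("quintile_or", fifths, out_dir)

    # subgroup interaction LRTs (continuous modifiers tertile-coded)
    rows = []
    for m in MARKERS:
        for mod in INTERACTION_MODIFIERS:
            d = data.copy()
            if d[mod].nunique() > 3:
                d[mod + "_t"] = tertile_groups(
                    d[mod], d.loc[d["is_case"] == 0, mod])
                mod_col = mod + "_t"
            else:
                mod_col = mod
            r = interaction_lrt(d, MARKER_BASE[m], mod_col, tiers[-1],
                                sd_source=config.sd_source)
            rows.append({"marker": m, "modifier": mod, **r})
    manifest.emit("interaction_tests", pd.DataFrame(rows), out_dir)

    # RDR estimates and corrected ORs
    rows, crows = [], []
    for m in MARKERS:
        pairs = serial_pairs(data, m)
        if len(pairs) < 10:
            log.warning("marker %s: only %d serial pairs; skipping RDR", m, len(pairs))
            continue
        rd = estimate_rdr(pairs)
        rows.append({"variable": m, "rdr": rd.rdr, "se": rd.se,
                     "ci_low": rd.ci_low, "ci_high": rd.ci_high,
                     "n_pairs": rd.n_pairs, "mean_gap_years": np.nan})
        cr = corrected_or_per_sd(data, m, tiers[-1],
                                 ci_method=config.ci_method,
                                 n_boot=config.n_boot, seed=config.seed,
                                 sd_source=config.sd_source)
        crows.append({"marker": m, "tier": cr.tier, "or": cr.or_per_sd,
                      "ci_low": cr.ci_low, "ci_high": cr.ci_high,
                      "ci_method": config.ci_method})
    manifest.emit("rdr", pd.DataFrame(rows), out_dir)
    manifest.emit("corrected_or", pd.DataFrame(crows), out_dir)

    manifest.write(out_dir)
    log.info("case-control stage complete")
    return {"files": manifest.files, "out_dir": str(out_dir)}


def run_meta_analysis(config: RunConfig) -> dict:
    """Meta-analysis stage; returns the manifest payload."""
    out_dir = Path(config.out_dir)
    setup_logging(out_dir)
    manifest = _Manifest(config)

    if config.estimates_csv is not None:
        estimates = read_estimates_csv(config.estimates_csv)
        log.info("loaded %d published estimates from %s",
                 len(estimates), config.estimates_csv)
    else:
        estimates = []
        for j, (m, truth) in enumerate(sorted(config.meta_true_log_rr.items())):
            estimates += generate_study_estimates(
                k=config.meta_k, true_log_rr_per_sd=truth,
                tau2=config.meta_tau2, bias=config.meta_bias,
                marker=m, seed=config.seed * 1000 + j)
        write_estimates_csv(estimates, out_dir / "estimates.csv")
        manifest.files["estimates"] = {"path": "estimates.csv",
                                       "rows": len(estimates)}

    forest, funnel, subgroups, metareg, egger_rows = [], [], [], [], []
    for m in sorted({e.marker for e in estimates}):
        ests = [e for e in estimates if e.marker == m]
        if len(ests) < 2:
            log.warning("marker %s has %d study; skipping", m, len(ests))
            continue
        effects = [harmonize_to_per_sd(e) for e in ests]
        pooled = pool_random_effects(effects)
        log.info("marker %s: pooled RR per SD = %.3f (%.3f, %.3f), k=%d, "
                 "I2=%.0f%%", m, pooled.pooled_rr, pooled.ci_low,
                 pooled.ci_high, pooled.k, pooled.i2)
        for e, h in zip(ests, effects):
            forest.append({
                "marker": m, "study": e.study, "n_cases": e.n_cases,
                "adjustment_degree": e.adjustment_degree,
                "rr_per_sd": float(np.exp(h.log_rr_per_sd)),
                "ci_low": float(np.exp(h.log_rr_per_sd - 1.96 * h.se)),
                "ci_high": float(np.exp(h.log_rr_per_sd + 1.96 * h.se)),
                "weight_pct": np.nan})
        forest.append({"marker": m, "study": "POOLED",
                       "n_cases": sum(e.n_cases for e in ests),
                       "adjustment_degree": np.nan,
                       "rr_per_sd": pooled.pooled_rr, "ci_low": pooled.ci_low,
                       "ci_high": pooled.ci_high, "weight_pct": 100.0})
        # funnel data with fixed-effect pseudo-CI bounds
        fe = np.array([h.log_rr_per_sd for h in effects])
        w = 1.0 / np.array([h.se for h in effects]) ** 2
        center = float(np.sum(w * fe) / np.sum(w))
        for h in effects:
            funnel.append({"marker": m, "study": h.study,
                           "log_rr_per_sd": h.log_rr_per_sd, "se": h.se,
                           "pseudo_low": center - 1.96 * h.se,
                           "pseudo_high": center + 1.96 * h.se})
        # pre-specified subgroup: >= 500 cases vs smaller studies
        big = np.array([e.n_cases >= 500 for e in ests])
        if big.sum() >= 2 and (~big).sum() >= 2:
            sg = subgroup_compare(effects, big)
            subgroups.append({
                "marker": m, "grouping": "n_cases>=500",
                "rr_large": sg["group_a"].pooled_rr,
                "k_large": sg["group_a"].k,
                "rr_small": sg["group_b"].pooled_rr,
                "k_small": sg["group_b"].k, "p_between": sg["p"]})
        # meta-regression on study-level characteristics
        for covname, vals in (
                ("adjustment_degree", [e.adjustment_degree for e in ests]),
                ("followup_y", [e.followup_y for e in ests]),
                ("storage_c", [e.storage_c for e in ests]),
                ("baseline_year", [e.baseline_year for e in ests])):
            vals = np.asarray(vals, dtype=float)
            if np.ptp(vals[np.isfinite(vals)]) == 0 or not np.isfinite(vals).all():
                continue
            mr = meta_regress(effects, vals)
            metareg.append({"marker": m, "covariate": covname, **mr})
        eg = egger_test(effects)
        egger_rows.append({"marker": m, "intercept": eg.intercept,
                           "se": eg.se, "t": eg.t, "df": eg.df, "p": eg.p,
                           "tau2": pooled.tau2, "Q": pooled.Q,
                           "i2": pooled.i2,
                           "p_heterogeneity": pooled.p_heterogeneity,
                           "pooled_rr_per_sd": pooled.pooled_rr,
                           "pooled_ci_low": pooled.ci_low,
                           "pooled_ci_high": pooled.ci_high})

    manifest.emit("forest", pd.DataFrame(forest), out_dir)
    manifest.emit("funnel", pd.DataFrame(funnel), out_dir)
    manifest.emit("subgroup", pd.DataFrame(subgroups), out_dir)
    manifest.emit("meta_regression", pd.DataFrame(metareg), out_dir)
    manifest.emit("pooled_summary", pd.DataFrame(egger_rows), out_dir)
    manifest.write(out_dir)
    log.info("meta-analysis stage complete")
    return {"files": manifest.files, "out_dir": str(out_dir)}


def run_all(config: RunConfig) -> dict:
    cc = run_casecontrol_analysis(config)
    meta = run_meta_analysis(config)
    return {"casecontrol": cc, "meta": meta}
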