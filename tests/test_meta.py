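"""Scale harmonization, DerSimonian-Laird pooling, meta-regression, Egger."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from hemorisk import (HarmonizedEffect, PublishedEstimate, egger_test,
                      generate_study_estimates, harmonize_to_per_sd,
                      meta_regress, pool_random_effects, quantile_spacing,
                      se_from_ci, subgroup_compare)


def dl_oracle(y, se):
    """Independent brute-force DerSimonian-Laird implementation."""
    y, se = np.asarray(y, float), np.asarray(se, float)
    w = se**-2
    ybar = (w * y).sum() / w.sum()
    Q = float((w * (y - ybar) ** 2).sum())
    df = len(y) - 1
    tau2 = max(0.0, (Q - df) / (w.sum() - (w**2).sum() / w.sum()))
    ws = 1.0 / (se**2 + tau2)
    return {"pooled": (ws * y).sum() / ws.sum(), "se": ws.sum() ** -0.5,
            "tau2": tau2, "Q": Q,
            "i2": max(0.0, 100 * (Q - df) / Q) if Q > 0 else 0.0}


def effects_from(y, se, marker="m"):
    return [HarmonizedEffect(study=f"s{i}", marker=marker,
                             log_rr_per_sd=float(a), se=float(b))
            for i, (a, b) in enumerate(zip(y, se))]


# ---------------------------------------------------------------------
# quantile spacing and CI inversion
# ---------------------------------------------------------------------

def truncated_normal_spacing(q):
    """Numeric-integration oracle: E[Z | top q] - E[Z | bottom q]."""
    z = stats.norm.ppf(1 - q)
    top, _ = integrate.quad(lambda x: x * stats.norm.pdf(x), z, 12)
    return 2 * top / q


@pytest.mark.parametrize("q,expected", [
    (1 / 2, 1.5958), (1 / 3, 2.1813), (1 / 4, 2.5427), (1 / 5, 2.7997)])
def test_quantile_spacing_against_integration_oracle(q, expected):
    d = quantile_spacing(q)
    assert d == pytest.approx(truncated_normal_spacing(q), abs=1e-6)
    assert d == pytest.approx(expected, abs=1e-3)


def test_spacing_increases_as_fraction_shrinks():
    qs = np.linspace(0.5, 0.02, 30)
    ds = [quantile_spacing(q) for q in qs]
    assert np.all(np.diff(ds) > 0)
    with pytest.raises(ValueError):
        quantile_spacing(0.6)


def test_se_from_ci_inversion():
    # exp(b +/- 1.96 s) round-trips s exactly
    b, s = 0.22, 0.031
    se = se_from_ci(np.exp(b), np.exp(b - 1.96 * s), np.exp(b + 1.96 * s))
    assert se == pytest.approx(s, rel=1e-12)
    # published-style input: 1.25 (1.18, 1.33)
    assert se_from_ci(1.25, 1.18, 1.33) == pytest.approx(
        (np.log(1.33) - np.log(1.18)) / 3.92, rel=1e-12)
    with pytest.warns(UserWarning, match="degenerate"):
        se_from_ci(1.2, 1.2, 1.2)


# ---------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------

def _pub(form, rr, lo, hi, q=None, sd=None):
    return PublishedEstimate(study="s", marker="m", form=form, rr=rr,
                             ci_low=lo, ci_high=hi, n_cases=100, q=q, sd=sd)


def test_per_sd_passes_through():
    h = harmonize_to_per_sd(_pub("per_sd", 1.3, 1.1, 1.55))
    assert h.log_rr_per_sd == pytest.approx(np.log(1.3))


def test_extreme_fifths_conversion():
    # RR 2.0 top vs bottom fifth -> per-SD RR exp(ln2 / 2.7997) = 1.281
    h = harmonize_to_per_sd(_pub("extreme_quantiles", 2.0, 1.5, 2.7, q=0.2))
    assert np.exp(h.log_rr_per_sd) == pytest.approx(
        np.exp(np.log(2.0) / quantile_spacing(0.2)), rel=1e-12)
    assert np.exp(h.log_rr_per_sd) == pytest.approx(1.281, abs=1e-3)


def test_per_unit_scaling():
    # RR 1.1 per unit with SD 2 -> per-SD RR 1.21
    h = harmonize_to_per_sd(_pub("per_unit", 1.1, 1.05, 1.16), dist_info={"sd": 2.0})
    assert np.exp(h.log_rr_per_sd) == pytest.approx(1.1**2, rel=1e-12)
    with pytest.raises(ValueError, match="SD"):
        harmonize_to_per_sd(_pub("per_unit", 1.1, 1.05, 1.16))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(logrr=st.floats(-1.0, 1.0), s=st.floats(0.01, 0.5),
       q=st.sampled_from([1 / 3, 1 / 4, 1 / 5]))
def test_extreme_quantile_roundtrip_is_exact(logrr, s, q):
    d = quantile_spacing(q)
    native = _pub("extreme_quantiles",
                  float(np.exp(logrr * d)),
                  float(np.exp(logrr * d - 1.96 * s * d)),
                  float(np.exp(logrr * d + 1.96 * s * d)), q=q)
    h = harmonize_to_per_sd(native)
    assert h.log_rr_per_sd * d == pytest.approx(logrr * d, abs=1e-12)
    assert h.se == pytest.approx(s, rel=1e-9)


# ---------------------------------------------------------------------
# DerSimonian-Laird pooling
# ---------------------------------------------------------------------

def test_identical_effects_pool_to_common_value():
    p = pool_random_effects(effects_from([0.2, 0.2, 0.2], [0.1, 0.1, 0.1]))
    assert p.pooled_log_rr == pytest.approx(0.2)
    assert p.Q == pytest.approx(0.0, abs=1e-12)
    assert p.tau2 == 0.0 and p.i2 == 0.0


def test_hand_computed_two_study_example():
    p = pool_random_effects(effects_from([0.0, 2.0], [1.0, 1.0]))
    assert p.Q == pytest.approx(2.0)
    assert p.tau2 == pytest.approx(1.0)
    assert p.pooled_log_rr == pytest.approx(1.0)
    assert p.se == pytest.approx(1.0)
    assert p.i2 == pytest.approx(50.0)


def test_pooling_matches_brute_force_on_random_sets():
    rng = np.random.default_rng(12)
    for _ in range(10):
        k = rng.integers(3, 15)
        y = rng.normal(0.2, 0.3, k)
        se = rng.uniform(0.05, 0.4, k)
        p = pool_random_effects(effects_from(y, se))
        o = dl_oracle(y, se)
        assert p.pooled_log_rr == pytest.approx(o["pooled"], rel=1e-12)
        assert p.se == pytest.approx(o["se"], rel=1e-12)
        assert p.tau2 == pytest.approx(o["tau2"], rel=1e-12)
        assert p.i2 == pytest.approx(o["i2"], rel=1e-12)
        # pooled estimate stays inside the convex hull of the inputs
        assert y.min() <= p.pooled_log_rr <= y.max()


def test_tau2_zero_reduces_to_fixed_effect():
    y, se = [0.1, 0.12, 0.11], [0.1, 0.1, 0.1]
    p = pool_random_effects(effects_from(y, se))
    assert p.tau2 == 0.0
    w = 1 / np.array(se) ** 2
    fixed = np.sum(w * y) / np.sum(w)
    assert p.pooled_log_rr == pytest.approx(fixed, rel=1e-12)


def test_i2_invariant_under_common_rescaling():
    rng = np.random.default_rng(13)
    y = rng.normal(0, 0.3, 8)
    se = rng.uniform(0.05, 0.3, 8)
    p1 = pool_random_effects(effects_from(y, se))
    p2 = pool_random_effects(effects_from(3.7 * y, 3.7 * se))
    assert p1.i2 == pytest.approx(p2.i2, rel=1e-9)
    assert p1.Q == pytest.approx(p2.Q, rel=1e-9)


# ---------------------------------------------------------------------
# meta-regression
# ---------------------------------------------------------------------

def test_noiseless_linear_effects_recovered_exactly():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = 0.05 + 0.03 * x
    r = meta_regress(effects_from(y, [0.1] * 4), x)
    assert r["slope"] == pytest.approx(0.03, abs=1e-10)


def test_binary_covariate_equals_subgroup_difference_when_tau2_zero():
    y = np.array([0.10, 0.12, 0.30, 0.28])
    se = np.array([0.1, 0.2, 0.1, 0.2])
    x = np.array([0.0, 0.0, 1.0, 1.0])
    r = meta_regress(effects_from(y, se), x)
    if r["tau2"] == 0.0:
        w = se**-2
        diff = (np.sum((w * y)[x == 1]) / np.sum(w[x == 1])
                - np.sum((w * y)[x == 0]) / np.sum(w[x == 0]))
        assert r["slope"] == pytest.approx(diff, rel=1e-9)


def test_constant_covariate_rejected():
    with pytest.raises(ValueError, match="constant"):
        meta_regress(effects_from([0.1, 0.2, 0.3], [0.1] * 3), [1.0, 1.0, 1.0])


# ---------------------------------------------------------------------
# Egger's test
# ---------------------------------------------------------------------

def test_egger_constant_effect_zero_intercept():
    rng = np.random.default_rng(14)
    se = rng.uniform(0.05, 0.4, 12)
    eg = egger_test(effects_from(np.full(12, 0.3), se))
    assert eg.intercept == pytest.approx(0.0, abs=1e-10)
    assert eg.df == 10


def test_egger_linear_in_se_recovers_intercept():
    rng = np.random.default_rng(15)
    se = rng.uniform(0.05, 0.4, 10)
    y = 0.2 + 1.5 * se
    eg = egger_test(effects_from(y, se))
    assert eg.intercept == pytest.approx(1.5, abs=1e-9)


def test_egger_detects_small_study_inflation():
    rng = np.random.default_rng(16)
    rejections = 0
    for rep in range(100):
        ests = generate_study_estimates(
            k=15, true_log_rr_per_sd=0.1, tau2=0.0, bias=2.0,
            forms=("per_sd",), seed=10_000 + rep)
        effects = [harmonize_to_per_sd(e) for e in ests]
        rejections += egger_test(effects).p < 0.05
    assert rejections / 100 > 0.3       # well above the nominal 5%


def test_egger_needs_three_studies():
    with pytest.raises(ValueError):
        egger_test(effects_from([0.1, 0.2], [0.1, 0.1]))


# ---------------------------------------------------------------------
# subgroup comparison
# ---------------------------------------------------------------------

def test_identical_groups_give_p_one():
    eff = effects_from([0.1, 0.2, 0.1, 0.2], [0.1, 0.1, 0.1, 0.1])
    r = subgroup_compare(eff, [True, True, False, False])
    assert r["z"] == pytest.approx(0.0, abs=1e-12)
    assert r["p"] == pytest.approx(1.0)


def test_distinct_group_effects_detected():
    rng = np.random.default_rng(17)
    y = np.r_[rng.normal(0.0, 0.05, 6), rng.normal(0.3, 0.05, 6)]
    eff = effects_from(y, np.full(12, 0.05))
    r = subgroup_compare(eff, np.r_[np.ones(6), np.zeros(6)].astype(bool))
    assert r["p"] < 0.01


def test_union_pool_between_group_estimates_when_homogeneous():
    eff = effects_from([0.10, 0.10, 0.20, 0.20], [0.1, 0.1, 0.1, 0.1])
    r = subgroup_compare(eff, [True, True, False, False])
    both = pool_random_effects(eff)
    lo = min(r["group_a"].pooled_log_rr, r["group_b"].pooled_log_rr)
    hi = max(r["group_a"].pooled_log_rr, r["group_b"].pooled_log_rr)
    assert lo <= both.pooled_log_rr <= hi


# ---------------------------------------------------------------------
# study-estimate simulator
# ---------------------------------------------------------------------

def test_generator_roundtrip_through_harmonization():
    ests = generate_study_estimates(k=12, true_log_rr_per_sd=0.2, tau2=0.02,
                                    seed=5)
    assert {e.form for e in ests} == {"per_sd", "extreme_quantiles",
                                      "per_unit", "per_log_unit"}
    effects = [harmonize_to_per_sd(e) for e in ests]
    # round-trip: harmonized SEs land back in the generating per-SD range
    for h in effects:
        assert 0.04 < h.se < 0.31


def test_pooled_estimate_covers_truth():
    rng = np.random.default_rng(18)
    covered = 0
    truth = 0.2
    n_rep = 100
    for rep in range(n_rep):
        ests = generate_study_estimates(k=30, true_log_rr_per_sd=truth,
                                        tau2=0.0, se_range=(0.05, 0.05),
                                        forms=("per_sd",), seed=20_000 + rep)
        p = pool_random_effects([harmonize_to_per_sd(e) for e in ests])
        covered += (p.pooled_log_rr - 1.96 * p.se <= truth
                    <= p.pooled_log_rr + 1.96 * p.se)
    assert 0.88 <= covered / n_rep <= 1.0


def test_tau2_estimation_order_of_magnitude():
    tau2_hats = []
    for rep in range(40):
        ests = generate_study_estimates(k=50, true_log_rr_per_sd=0.2,
                                        tau2=0.04, forms=("per_sd",),
                                        se_range=(0.05, 0.15),
                                        seed=30_000 + rep)
        tau2_hats.append(pool_random_effects(
            [harmonize_to_per_sd(e) for e in ests]).tau2)
    assert abs(np.mean(tau2_hats) - 0.04) / 0.04 < 0.5


def test_csv_round_trip(tmp_path):
    from hemorisk import read_estimates_csv, write_estimates_csv
    ests = generate_study_estimates(k=8, true_log_rr_per_sd=0.15, seed=9)
    path = tmp_path / "estimates.csv"
    write_estimates_csv(ests, path)
    back = read_estimates_csv(path)
    for a, b in zip(ests, back):
        assert a.study == b.study and a.form == b.form
        assert a.rr == pytest.approx(b.rr, rel=1e-9)
        h1, h2 = harmonize_to_per_sd(a), harmonize_to_per_sd(b)
        assert h1.log_rr_per_sd == pytest.approx(h2.log_rr_per_sd, rel=1e-9)
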