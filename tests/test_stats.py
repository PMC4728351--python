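"""Variability, repeatability and trial-order statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faststart.simulate import PopulationDesign, simulate_population
from faststart.stats import (
    cv,
    fit_trial_order_model,
    flag_weak_fish,
    icc_oneway,
    repeatability_best2,
    summarize_study,
    within_among_cv,
)


def table_from(rows):
    df = pd.DataFrame(rows)
    for c in ("tl_cm", "initial_orientation_deg", "initial_distance_cm"):
        if c not in df.columns:
            df[c] = np.nan
    if "flag" not in df.columns:
        df["flag"] = ""
    return df


def rows_for(values_by_fish, measure="u_max_cm_s"):
    rows = []
    for fid, vals in values_by_fish.items():
        for t, v in enumerate(vals, start=1):
            rows.append({"fish_id": fid, "trial": t, "measure": measure, "value": v})
    return table_from(rows)


# ---------------------------------------------------------------------------
# CV


def test_cv_hand_arithmetic():
    assert cv([1.0, 2.0, 3.0]) == pytest.approx(0.5, rel=1e-12)
    assert cv([7.0, 7.0, 7.0]) == 0.0


def test_cv_matches_longhand_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.lognormal(1.0, 0.4, rng.integers(2, 30))
        n = len(x)
        m = sum(x) / n
        sd = (sum((xi - m) ** 2 for xi in x) / (n - 1)) ** 0.5
        assert cv(x) == pytest.approx(sd / m, rel=1e-12)


def test_cv_rejects_bad_input():
    with pytest.raises(ValueError, match="at least 2"):
        cv([1.0])
    with pytest.raises(ValueError, match="positive mean"):
        cv([-1.0, -2.0])


@settings(derandomize=True, deadline=None, max_examples=40)
@given(st.integers(0, 2**32 - 1), st.floats(0.01, 1e4))
def test_cv_scale_invariance(seed, scale):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(0.0, 0.5, 10)
    assert cv(scale * x) == pytest.approx(cv(x), rel=1e-9)


# ---------------------------------------------------------------------------
# within/among CV


def test_within_among_two_fish_hand_case():
    """Fish at {10,10,10} and {20,20,20}: within CVs 0, among CV 0.4714."""
    tab = rows_for({"a": [10, 10, 10], "b": [20, 20, 20]})
    r = within_among_cv(tab, "u_max_cm_s")
    assert list(r.per_fish_cv.values()) == [0.0, 0.0]
    assert r.mean_within_cv == 0.0
    assert r.among_cv == pytest.approx(np.std([10, 20], ddof=1) / 15, rel=1e-12)
    assert r.among_cv == pytest.approx(0.4714, abs=1e-4)


def test_zero_within_variance_puts_among_outside_ci():
    d = PopulationDesign(n_fish=10, n_trials=5, among_cv=0.3, within_cv=0.0, seed=8)
    tab = simulate_population(d)
    r = within_among_cv(tab, "u_max_cm_s")
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in r.per_fish_cv.values())
    assert r.among_cv > 0
    assert r.among_outside_ci


def test_within_among_bootstrap_ci_close_to_t():
    d = PopulationDesign(n_fish=30, n_trials=5, among_cv=0.3, within_cv=0.2, seed=9)
    tab = simulate_population(d)
    rt = within_among_cv(tab, "u_max_cm_s", ci_method="t")
    rb = within_among_cv(tab, "u_max_cm_s", ci_method="bootstrap", n_boot=2000, seed=1)
    assert rb.mean_within_cv == rt.mean_within_cv
    assert rb.within_cv_ci95[0] == pytest.approx(rt.within_cv_ci95[0], abs=0.02)
    assert rb.within_cv_ci95[1] == pytest.approx(rt.within_cv_ci95[1], abs=0.02)


def test_within_among_rejects_insufficient_replication():
    tab = rows_for({"a": [1.0], "b": [2.0]})
    with pytest.raises(ValueError, match="2 trials"):
        within_among_cv(tab, "u_max_cm_s")


# ---------------------------------------------------------------------------
# repeatability


def test_repeatability_perfect_limit():
    """Zero within-individual variance: best = second best, r = 1, ICC = 1."""
    d = PopulationDesign(n_fish=8, n_trials=5, among_cv=0.3, within_cv=0.0, seed=3)
    tab = simulate_population(d)
    r = repeatability_best2(tab, "u_max_cm_s")
    assert r.pearson_r == 1.0
    assert r.icc == 1.0
    for best, second in r.pairs.values():
        assert best == second


def test_repeatability_correlation_mechanics():
    tab = rows_for({"a": [1, 1], "b": [2, 2], "c": [3, 3]})
    r = repeatability_best2(tab, "u_max_cm_s")
    assert r.pearson_r == pytest.approx(1.0)
    tab2 = rows_for({"a": [1, 1], "b": [2, 2], "c": [3, 1]})
    r2 = repeatability_best2(tab2, "u_max_cm_s")
    assert r2.pearson_r < 1.0


def test_repeatability_matches_definition_oracle():
    d = PopulationDesign(n_fish=12, n_trials=5, among_cv=0.3, within_cv=0.2, seed=4)
    tab = simulate_population(d)
    r = repeatability_best2(tab, "d_esc_cm")
    x = np.array([p[0] for p in r.pairs.values()])
    y = np.array([p[1] for p in r.pairs.values()])
    xm, ym = x - x.mean(), y - y.mean()
    r_hand = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
    assert r.pearson_r == pytest.approx(r_hand, rel=1e-12)


def test_repeatability_direction_min():
    tab = rows_for({"a": [5, 1, 3], "b": [6, 2, 4], "c": [7, 3, 5]}, "latency_ms")
    r = repeatability_best2(tab, "latency_ms", direction="min")
    assert r.pairs["a"] == (1.0, 3.0)
    rmax = repeatability_best2(tab, "latency_ms", direction="max")
    assert rmax.pairs["a"] == (5.0, 3.0)


def test_repeatability_excludes_short_fish_and_needs_three():
    tab = rows_for({"a": [1, 2], "b": [2, 3], "c": [3.0]})
    with pytest.raises(ValueError, match=">= 3 fish"):
        repeatability_best2(tab, "u_max_cm_s")


# ---------------------------------------------------------------------------
# ICC


def test_icc_limits():
    tab = rows_for({"a": [10, 10], "b": [20, 20], "c": [30, 30]})
    assert icc_oneway(tab, "u_max_cm_s").icc == 1.0
    flat = rows_for({"a": [10, 20], "b": [12, 18], "c": [14, 16]})
    res = icc_oneway(flat, "u_max_cm_s")
    assert res.icc <= 0.0
    assert "no_among_individual_signal" in res.flags


def test_icc_converges_to_variance_ratio():
    """Among sigma^2 = within sigma^2 = 1 gives ICC -> 0.5 for large n."""
    rng = np.random.default_rng(6)
    rows = {}
    for i in range(400):
        mu = rng.normal(10, 1.0)
        rows[f"F{i}"] = mu + rng.normal(0, 1.0, 6)
    res = icc_oneway(rows_for(rows), "u_max_cm_s")
    assert res.icc == pytest.approx(0.5, abs=0.05)


def test_icc_matches_pingouin():
    """Independent oracle: pingouin's ICC(1,1) and its CI."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    rows = {}
    for i in range(8):
        rows[f"F{i}"] = rng.normal(100, 15) + rng.normal(0, 5, 5)
    tab = rows_for(rows)
    mine = icc_oneway(tab, "u_max_cm_s")
    sub = tab.assign(trial=tab["trial"])
    out = pg.intraclass_corr(data=sub, targets="fish_id", raters="trial",
                             ratings="value")
    ref = out[out["Type"] == "ICC(1,1)"].iloc[0]
    assert mine.icc == pytest.approx(float(ref["ICC"]), rel=1e-9)
    lo, hi = ref["CI95"]
    assert mine.ci95[0] == pytest.approx(lo, abs=0.01)
    assert mine.ci95[1] == pytest.approx(hi, abs=0.01)


# ---------------------------------------------------------------------------
# trial-order mixed model


def test_lmm_pure_random_intercept_signal():
    """Distinct constant per fish: trial F ~ 0, R2m ~ 0, R2c ~ 1."""
    tab = rows_for({f"f{i}": [100.0 + 10 * i] * 5 for i in range(6)})
    r = fit_trial_order_model(tab, "u_max_cm_s")
    assert r.f_trial == pytest.approx(0.0, abs=1e-6)
    assert r.r2_marginal == pytest.approx(0.0, abs=1e-6)
    assert r.r2_conditional == pytest.approx(1.0, abs=1e-6)


def test_lmm_degenerate_constant_response():
    tab = rows_for({f"f{i}": [5.0] * 4 for i in range(5)})
    r = fit_trial_order_model(tab, "u_max_cm_s")
    assert "degenerate_constant_response" in r.flags
    assert r.sigma2_fixed == r.sigma2_id == r.sigma2_resid == 0.0


def test_lmm_balanced_equals_rm_anova():
    """On balanced data without covariates the trial Wald F equals the
    two-way (fish x trial) repeated-measures ANOVA F to 1e-6."""
    d = PopulationDesign(n_fish=10, n_trials=5, among_cv=0.3, within_cv=0.2, seed=7)
    tab = simulate_population(d)
    r = fit_trial_order_model(tab, "u_max_cm_s", covariates=())
    piv = tab[tab["measure"] == "u_max_cm_s"].pivot(
        index="fish_id", columns="trial", values="value").to_numpy()
    n, k = piv.shape
    grand = piv.mean()
    ss_trial = n * np.sum((piv.mean(0) - grand) ** 2)
    ss_res = np.sum((piv - piv.mean(1)[:, None] - piv.mean(0)[None, :] + grand) ** 2)
    f_anova = (ss_trial / (k - 1)) / (ss_res / ((n - 1) * (k - 1)))
    assert r.f_trial == pytest.approx(f_anova, rel=1e-6)
    assert r.df_den == (n - 1) * (k - 1)


def test_lmm_log_transform_for_latency():
    d = PopulationDesign(n_fish=8, n_trials=5, seed=10)
    tab = simulate_population(d)
    r = fit_trial_order_model(tab, "latency_ms")
    assert r.transform == "log"
    r2 = fit_trial_order_model(tab, "u_max_cm_s")
    assert r2.transform == "identity"
    # non-positive latency rows are dropped with a note, not fatal
    tab.loc[tab.index[tab["measure"] == "latency_ms"][0], "value"] = -1.0
    r3 = fit_trial_order_model(tab, "latency_ms")
    assert r3.n_dropped_nonpositive == 1


def test_lmm_r2_ordering_and_ddf_methods():
    d = PopulationDesign(n_fish=12, n_trials=5, among_cv=0.3, within_cv=0.2, seed=11)
    tab = simulate_population(d)
    r = fit_trial_order_model(tab, "a_max_cm_s2")
    assert 0.0 <= r.r2_marginal <= r.r2_conditional <= 1.0
    assert r.sigma2_id >= 0 and r.sigma2_resid >= 0
    rr = fit_trial_order_model(tab, "a_max_cm_s2", ddf_method="residual")
    assert rr.f_trial == pytest.approx(r.f_trial, rel=1e-9)
    assert rr.df_den != r.df_den


# ---------------------------------------------------------------------------
# study-level driver


def weak_fish_table(seed=12):
    d = PopulationDesign(n_fish=14, n_trials=5, seed=seed)
    tab = simulate_population(d)
    # make two fish consistently slow responders (median latency > 200 ms)
    weak = ["F01", "F02"]
    m = (tab["measure"] == "latency_ms") & tab["fish_id"].isin(weak)
    tab.loc[m, "value"] = tab.loc[m, "value"] + 400.0
    return tab, weak


def test_exclusion_rule_kinematics_only():
    """Flagged fish leave the kinematic analyses but stay in latency."""
    tab, weak = weak_fish_table()
    assert set(flag_weak_fish(tab)) == set(weak)
    rep = summarize_study(tab)
    assert set(rep.excluded_fish) == set(weak)
    assert rep.variation["latency_ms"].n_fish == 14
    assert rep.variation["u_max_cm_s"].n_fish == 12
    assert rep.trial_order["u_max_cm_s"].n_fish == 12
    assert all(w not in rep.repeatability["d_esc_cm"].pairs for w in weak)
    assert all(w in rep.repeatability["latency_ms"].pairs for w in weak)


def test_summarize_study_structure():
    d = PopulationDesign(n_fish=14, n_trials=5, seed=13)
    rep = summarize_study(simulate_population(d))
    assert len(rep.variation) == 5
    assert len(rep.repeatability) == 5
    assert len(rep.trial_order) == 5
    assert rep.errors == {}
    as_json = rep.to_dict()
    assert as_json["schema_version"] == 1
    assert set(as_json["variation"]) == set(rep.variation)


def test_summarize_study_empty_table():
    rep = summarize_study(pd.DataFrame())
    assert rep.variation == {} and rep.errors  # structured "no data" report
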