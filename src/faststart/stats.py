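"""Variability, repeatability and trial-order statistics for escape trials.

Works on a long-format trial table (fish_id, trial, measure, value,
covariates, flag) and implements the three analyses of the reference
design:

* within- vs among-individual coefficients of variation: the CV of each
  fish across its trials (mean + 95% CI = average variation within
  individuals) against the CV of the per-fish means (variation among
  individuals);
* repeatability of maximum performance: each fish's best and second-best
  values correlated across fish (Pearson), plus the one-way
  random-effects intraclass correlation ICC(1,1);
* habituation/fatigue: a random-intercept linear mixed model of trial
  order (categorical) with size/distance/angle covariates, with marginal
  and conditional R^2 from the variance components
  (R2m = s2_f / (s2_f + s2_id + s2_e), R2c adds the random intercept).

Fish with consistently weak, long-latency responses (putative
non-Mauthner responders) can be excluded from the kinematic analyses
while retained for latency, mirroring the reference study's handling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "cv",
    "within_among_cv",
    "repeatability_best2",
    "icc_oneway",
    "fit_trial_order_model",
    "flag_weak_fish",
    "summarize_study",
    "VariationReport",
    "RepeatabilityReport",
    "ICCResult",
    "TrialOrderModelResult",
    "StudyReport",
    "KINEMATIC_MEASURES",
    "DEFAULT_COVARIATES",
]

KINEMATIC_MEASURES = ("d_esc_cm", "u_max_cm_s", "a_max_cm_s2", "turning_rate_deg_ms")
ALL_MEASURES = ("latency_ms",) + KINEMATIC_MEASURES
DEFAULT_COVARIATES = ("tl_cm", "initial_distance_cm", "initial_orientation_deg")


def cv(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over the mean."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError(f"CV needs at least 2 values, got {len(x)}")
    m = float(np.mean(x))
    if m <= 0:
        raise ValueError(f"CV requires a positive mean, got {m}")
    return float(np.std(x, ddof=1)) / m


def _pivot(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    sub = table[(table["measure"] == measure) & table["value"].notna()]
    if sub.empty:
        raise ValueError(f"no values for measure {measure!r}")
    return sub


@dataclass
class VariationReport:
    measure: str
    per_fish_cv: dict[str, float]
    mean_within_cv: float
    within_cv_ci95: tuple[float, float]
    among_cv: float
    among_outside_ci: bool
    n_fish: int
    ci_method: str = "t"

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "per_fish_cv": self.per_fish_cv,
            "mean_within_cv": self.mean_within_cv,
            "within_cv_ci95": list(self.within_cv_ci95),
            "among_cv": self.among_cv,
            "among_outside_ci": self.among_outside_ci,
            "n_fish": self.n_fish,
            "ci_method": self.ci_method,
        }


def within_among_cv(
    table: pd.DataFrame,
    measure: str,
    ci_method: str = "t",
    n_boot: int = 10_000,
    seed: int = 0,
) -> VariationReport:
    """Within- vs among-individual CV for one measure.

    Within: CV of each fish over its trials, averaged, with a 95% CI
    (t-interval across fish by default; bias-corrected percentile
    bootstrap with ``ci_method="bootstrap"``).  Among: CV of the per-fish
    means.  ``among_outside_ci`` reproduces the overlap comparison: does
    the among-individual CV fall outside the CI of the mean within-CV?
    """
    sub = _pivot(table, measure)
    groups = sub.groupby("fish_id")["value"]
    counts = groups.count()
    ok = counts[counts >= 2].index
    if len(ok) < 2:
        raise ValueError(
            f"need >= 2 fish with >= 2 trials for {measure!r}; "
            f"trial counts: {counts.to_dict()}"
        )
    per_fish = {fid: cv(groups.get_group(fid)) for fid in ok}
    cvs = np.array(list(per_fish.values()))
    n = len(cvs)
    mean_cv = float(np.mean(cvs))
    if ci_method == "t":
        half = sps.t.ppf(0.975, n - 1) * np.std(cvs, ddof=1) / math.sqrt(n)
        ci = (mean_cv - float(half), mean_cv + float(half))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.mean(rng.choice(cvs, size=(n_boot, n), replace=True), axis=1)
        # bias-corrected percentile interval
        z0 = sps.norm.ppf(np.clip(np.mean(boots < mean_cv), 1e-9, 1 - 1e-9))
        alphas = sps.norm.cdf(2 * z0 + sps.norm.ppf([0.025, 0.975]))
        lo, hi = np.quantile(boots, alphas)
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    fish_means = groups.mean().loc[ok]
    among = cv(fish_means)
    outside = among < ci[0] or among > ci[1]
    return VariationReport(measure, per_fish, mean_cv, ci, among, bool(outside), n, ci_method)


@dataclass
class RepeatabilityReport:
    measure: str
    direction: str
    pairs: dict[str, tuple[float, float]]  # fish -> (best, second best)
    pearson_r: float
    pearson_p: float
    icc: float
    icc_ci95: tuple[float, float]
    n_fish: int
    excluded: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "direction": self.direction,
            "pairs": {k: list(v) for k, v in self.pairs.items()},
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "icc": self.icc,
            "icc_ci95": list(self.icc_ci95),
            "n_fish": self.n_fish,
            "excluded": self.excluded,
            "flags": self.flags,
        }


def repeatability_best2(
    table: pd.DataFrame, measure: str, direction: str = "max"
) -> RepeatabilityReport:
    """Best vs second-best performance across fish (Pearson r) + ICC.

    ``direction="max"`` takes each fish's two highest values (the
    convention for speed/acceleration/distance and the reference figure's
    "highest and second highest"); ``"min"`` takes the two lowest, the
    biological reading of "best" for latency.  Ties keep trial order
    (earlier trial first).
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    sub = _pivot(table, measure).sort_values("trial", kind="stable")
    pairs: dict[str, tuple[float, float]] = {}
    excluded: list[str] = []
    for fid, grp in sub.groupby("fish_id", sort=True):
        vals = grp["value"].to_numpy()
        if len(vals) < 2:
            excluded.append(str(fid))
            continue
        order = np.argsort(-vals if direction == "max" else vals, kind="stable")
        pairs[str(fid)] = (float(vals[order[0]]), float(vals[order[1]]))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 fish with >= 2 valid trials, have {len(pairs)}")
    best = np.array([p[0] for p in pairs.values()])
    second = np.array([p[1] for p in pairs.values()])
    flags: list[str] = []
    if np.ptp(best) == 0 or np.ptp(second) == 0:
        r, p = float("nan"), float("nan")
        flags.append("constant_vector")
    elif np.allclose(best, second):
        r, p = 1.0, 0.0  # identical vectors: perfect repeatability limit
    else:
        r, p = sps.pearsonr(best, second)
    icc_res = icc_oneway(table, measure)
    return RepeatabilityReport(
        measure, direction, pairs, float(r), float(p),
        icc_res.icc, icc_res.ci95, len(pairs), excluded, flags + icc_res.flags,
    )


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    k0: float
    msb: float
    msw: float
    flags: list[str] = field(default_factory=list)


def icc_oneway(table: pd.DataFrame, measure: str) -> ICCResult:
    """One-way random-effects ICC(1,1) from the ANOVA decomposition.

    ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW), with k0 the
    harmonic-mean-adjusted trials per fish for unbalanced data, and an
    exact F-based 95% CI.  Trials within a fish are treated as
    exchangeable stimulations (no trial-specific effect), the natural
    variant for repeated identical stimulus presentations.
    """
    sub = _pivot(table, measure)
    groups = [g.to_numpy() for _, g in sub.groupby("fish_id")["value"]]
    groups = [g for g in groups if len(g) >= 1]
    a = len(groups)
    if a < 2:
        raise ValueError("ICC needs >= 2 fish")
    ki = np.array([len(g) for g in groups], dtype=float)
    n_tot = float(ki.sum())
    grand = float(np.concatenate(groups).mean())
    gmeans = np.array([g.mean() for g in groups])
    ssb = float(np.sum(ki * (gmeans - grand) ** 2))
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    msb = ssb / (a - 1)
    k0 = (n_tot - float(np.sum(ki**2)) / n_tot) / (a - 1)
    flags: list[str] = []
    if n_tot - a <= 0:
        raise ValueError("ICC needs at least one fish with >= 2 trials")
    msw = ssw / (n_tot - a)
    if msw == 0.0:
        icc = 1.0 if msb > 0 else float("nan")
        if msb <= 0:
            flags.append("degenerate_no_variance")
        return ICCResult(icc, (1.0, 1.0) if msb > 0 else (float("nan"),) * 2,
                         k0, msb, msw, flags)
    f_obs = msb / msw
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    lower_bound = -1.0 / (k0 - 1)
    if msb <= msw:
        flags.append("no_among_individual_signal")
        icc = max(icc, lower_bound)
    fl = f_obs / sps.f.ppf(0.975, a - 1, n_tot - a)
    fu = f_obs * sps.f.ppf(0.975, n_tot - a, a - 1)
    lo = (fl - 1) / (fl + k0 - 1)
    hi = (fu - 1) / (fu + k0 - 1)
    return ICCResult(float(icc), (float(lo), float(hi)), k0, msb, msw, flags)


@dataclass
class TrialOrderModelResult:
    measure: str
    transform: str                 # "identity" or "log"
    coefficients: dict[str, float]
    f_trial: float
    df_num: int
    df_den: float
    p_trial: float
    sigma2_fixed: float
    sigma2_id: float
    sigma2_resid: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_fish: int
    ddf_method: str
    flags: list[str] = field(default_factory=list)
    n_dropped_nonpositive: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "coefficients"}
        d["coefficients"] = dict(self.coefficients)
        return d


def fit_trial_order_model(
    table: pd.DataFrame,
    measure: str,
    transform: str = "auto",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    ddf_method: str = "within",
) -> TrialOrderModelResult:
    """Random-intercept LMM of trial order for one measure.

    Fixed effects: trial as a categorical factor (k-1 contrasts, so the
    joint test has numerator df k-1) plus the linear covariates; random
    intercept per fish; REML variance components.  The joint Wald F for
    the trial factor uses a containment denominator df
    N - n_fish - p_within by default (equals (n-1)(k-1) on balanced data
    with no within-fish covariates, matching the repeated-measures ANOVA);
    ``ddf_method="residual"`` uses N - rank(X).  Latency is natural-log
    transformed under ``transform="auto"``; non-positive responses are
    dropped with a note.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    sub = _pivot(table, measure).copy()
    if transform == "auto":
        transform = "log" if measure == "latency_ms" else "identity"
    if transform not in ("identity", "log"):
        raise ValueError(f"unknown transform {transform!r}")
    n_dropped = 0
    if transform == "log":
        bad = sub["value"] <= 0
        n_dropped = int(bad.sum())
        sub = sub[~bad]
        sub["y"] = np.log(sub["value"])
    else:
        sub["y"] = sub["value"]
    covariates = tuple(c for c in covariates if c in sub.columns and sub[c].notna().all())
    dropped_const = [c for c in covariates if sub[c].nunique() <= 1]
    covariates = tuple(c for c in covariates if c not in dropped_const)
    counts = sub.groupby("fish_id")["y"].count()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each fish needs >= 2 trials for the mixed model")

    flags: list[str] = [f"dropped_constant_covariate:{c}" for c in dropped_const]
    k = sub["trial"].nunique()
    q = k - 1
    n_obs = len(sub)
    n_fish = sub["fish_id"].nunique()

    if np.ptp(sub["y"].to_numpy()) == 0.0:
        return TrialOrderModelResult(
            measure, transform, {}, 0.0, q, float(n_obs - n_fish - q), 1.0,
            0.0, 0.0, 0.0, 0.0, 0.0, n_obs, n_fish, ddf_method,
            flags=["degenerate_constant_response"], n_dropped_nonpositive=n_dropped,
        )

    formula = "y ~ C(trial)" + "".join(f" + {c}" for c in covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.MixedLM.from_formula(formula, groups="fish_id", data=sub)
        try:
            res = model.fit(reml=True, method="lbfgs")
        except (np.linalg.LinAlgError, ValueError):
            res = model.fit(reml=True)

    fe = res.fe_params
    names = list(fe.index)
    trial_idx = [i for i, nm in enumerate(names) if nm.startswith("C(trial)")]
    b = fe.to_numpy()[trial_idx]
    v = res.cov_params().to_numpy()[np.ix_(trial_idx, trial_idx)]
    wald = float(b @ np.linalg.solve(v, b))
    f_trial = wald / q

    exog = model.exog
    if ddf_method == "within":
        p_within = q
        for c in covariates:
            within_var = sub.groupby("fish_id")[c].nunique()
            if (within_var > 1).any():
                p_within += 1
        df_den = float(n_obs - n_fish - p_within)
    elif ddf_method == "residual":
        df_den = float(n_obs - np.linalg.matrix_rank(exog))
    else:
        raise ValueError(f"unknown ddf_method {ddf_method!r}")
    p_trial = float(sps.f.sf(f_trial, q, df_den))

    sigma2_resid = float(res.scale)
    sigma2_id = float(np.asarray(res.cov_re)[0, 0])
    fitted_fixed = exog @ fe.to_numpy()
    sigma2_fixed = float(np.var(fitted_fixed, ddof=1))
    total = sigma2_fixed + sigma2_id + sigma2_resid
    r2m = sigma2_fixed / total if total > 0 else 0.0
    r2c = (sigma2_fixed + sigma2_id) / total if total > 0 else 0.0
    if sigma2_id <= 1e-10 * max(total, 1e-300):
        flags.append("boundary_random_intercept_variance")

    return TrialOrderModelResult(
        measure, transform, dict(fe), float(f_trial), q, df_den, p_trial,
        sigma2_fixed, sigma2_id, sigma2_resid, float(r2m), float(r2c),
        n_obs, n_fish, ddf_method, flags=flags, n_dropped_nonpositive=n_dropped,
    )


# ---------------------------------------------------------------------------
# study-level driver


def flag_weak_fish(
    table: pd.DataFrame,
    latency_threshold_ms: float = 200.0,
    bad_trial_fraction: float = 0.6,
) -> list[str]:
    """Fish with consistently weak / long-latency responses.

    A fish is flagged when its median latency exceeds the non-Mauthner
    threshold, or when at least ``bad_trial_fraction`` of its trials are
    non-responsive or lack a stage-1 reversal.  Flagged fish are excluded
    from the kinematic analyses but retained for latency.
    """
    flagged = []
    for fid, grp in table.groupby("fish_id"):
        lat = grp.loc[grp["measure"] == "latency_ms", "value"].dropna()
        if len(lat) and float(np.median(lat)) > latency_threshold_ms:
            flagged.append(str(fid))
            continue
        trials = grp["trial"].unique()
        if len(trials) == 0:
            continue
        bad = 0
        for t in trials:
            fl = " ".join(str(x) for x in grp.loc[grp["trial"] == t, "flag"].fillna(""))
            if "non_responsive" in fl or "no_reversal" in fl:
                bad += 1
        if bad / len(trials) >= bad_trial_fraction:
            flagged.append(str(fid))
    return flagged


@dataclass
class StudyReport:
    variation: dict[str, VariationReport]
    repeatability: dict[str, RepeatabilityReport]
    trial_order: dict[str, TrialOrderModelResult]
    excluded_fish: list[str]
    errors: dict[str, str]
    n_fish_total: int

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "excluded_fish": self.excluded_fish,
            "n_fish_total": self.n_fish_total,
            "variation": {m: r.to_dict() for m, r in self.variation.items()},
            "repeatability": {m: r.to_dict() for m, r in self.repeatability.items()},
            "trial_order": {m: r.to_dict() for m, r in self.trial_order.items()},
            "errors": self.errors,
        }


def summarize_study(
    table: pd.DataFrame,
    latency_threshold_ms: float = 200.0,
    direction: str | dict[str, str] = "max",
    ci_method: str = "t",
    ddf_method: str = "within",
    apply_exclusion: bool = True,
) -> StudyReport:
    """Run all three analyses for every measure present in the table.

    The weak-fish exclusion applies to the four kinematic measures only;
    latency is always analysed on all fish.  Per-measure failures are
    recorded in ``errors`` instead of aborting the other measures.
    """
    if table.empty:
        return StudyReport({}, {}, {}, [], {"all": "empty table"}, 0)
    excluded = flag_weak_fish(table, latency_threshold_ms) if apply_exclusion else []
    kin_table = table[~table["fish_id"].isin(excluded)]
    variation: dict[str, VariationReport] = {}
    repeat: dict[str, RepeatabilityReport] = {}
    order: dict[str, TrialOrderModelResult] = {}
    errors: dict[str, str] = {}
    measures = [m for m in ALL_MEASURES if (table["measure"] == m).any()]
    for m in measures:
        tab = table if m == "latency_ms" else kin_table
        dir_m = direction.get(m, "max") if isinstance(direction, dict) else direction
        for kind, fn in (
            ("variation", lambda: within_among_cv(tab, m, ci_method=ci_method)),
            ("repeatability", lambda: repeatability_best2(tab, m, direction=dir_m)),
            ("trial_order", lambda: fit_trial_order_model(tab, m, ddf_method=ddf_method)),
        ):
            try:
                out = fn()
            except Exception as exc:  # per-measure isolation
                errors[f"{m}:{kind}"] = str(exc)
                continue
            {"variation": variation, "repeatability": repeat, "trial_order": order}[kind][m] = out
    return StudyReport(variation, repeat, order, excluded, errors,
                       int(table["fish_id"].nunique()))
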