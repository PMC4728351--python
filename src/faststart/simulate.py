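"""Synthetic C-start escape trials and multi-fish experiments.

Two levels of generator:

* :func:`simulate_trajectory` — a single trial from a parametric kinematic
  model with closed-form ground truth.  The fish sits still through a
  pre-stimulus baseline, then (after the response latency) turns its
  heading by the stage-1 angle with a half-sine angular-velocity pulse,
  flips back by the opposite-signed stage-2 angle, while its speed rises
  as sin^2 to the peak, holds through the end of stage 2, and decays as a
  smooth cos^2 coast.  The CoM is the time integral of speed along the
  heading; the snout rides one body-segment length ahead of the CoM.
  Tracking error is emulated as isotropic Gaussian noise added to the
  stored coordinates only — the dynamics themselves are noise-free.

* :func:`simulate_population` — a fish x trial table of the five
  performance measures with controlled among- and within-individual
  coefficients of variation (lognormal individual and trial effects, so
  all values stay positive), an optional multiplicative trial-order trend,
  and protocol covariates drawn from the reference study's printed
  distributions (TL 11.53 +/- 0.53 cm; stimulus angle 81.3 +/- 25.4 deg;
  stimulus distance 22.8 +/- 3.7 cm).

* :func:`simulate_experiment` — a full synthetic study: per-fish mean
  kinematic parameters with among-individual variance, per-trial
  within-individual jitter, one tracked trajectory per trial.

The angular-velocity pulse is omega(t) = omega1 * sin(pi t / T1), which is
zero at both stage ends and single-signed, so the noise-free heading has
exactly one angular reversal per stage boundary.  The sin^2 speed rise
gives the closed forms peak tangential acceleration = pi u_max / (2 t_U)
and an elementary integral for the escape distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trajectory import TrackedTrajectory

__all__ = [
    "CStartModelParams",
    "GroundTruth",
    "PopulationDesign",
    "DEFAULT_MEASURE_MEANS",
    "simulate_trajectory",
    "simulate_population",
    "simulate_experiment",
]

#: Integration substeps per frame for the CoM position quadrature.
SUBSTEPS = 64

MEASURES = ("latency_ms", "d_esc_cm", "u_max_cm_s", "a_max_cm_s2", "turning_rate_deg_ms")

#: Baseline trial-level means used by the population generator.  Chosen as
#: realistic magnitudes for an ~11.5 cm damselfish filmed at 240 Hz:
#: latency ~30 ms, escape distance ~4 cm in 42 ms, peak speed ~150 cm/s,
#: peak acceleration ~8400 cm/s^2, stage-1 turning rate ~3.1 deg/ms.
DEFAULT_MEASURE_MEANS = {
    "latency_ms": 30.0,
    "d_esc_cm": 4.0,
    "u_max_cm_s": 150.0,
    "a_max_cm_s2": 8400.0,
    "turning_rate_deg_ms": 3.1,
}


@dataclass
class CStartModelParams:
    """Parameters of the single-trial kinematic model.

    Times in ms, lengths in cm, speeds cm/s, angles degrees.  The stage-2
    return angle must have the opposite sign of the stage-1 turn (C-bend
    then contralateral return flip) when both are nonzero.
    """

    latency_ms: float = 35.0
    stage1_duration_ms: float = 24.0        # T1
    stage2_duration_ms: float = 18.0        # T2
    turn_angle_deg: float = 75.0            # stage-1 heading change
    stage2_return_angle_deg: float = -42.0  # contralateral return flip
    u_max_cm_s: float = 150.0
    speed_rise_ms: float = 28.0             # motion onset -> peak speed (t_U)
    post_stage2_ms: float = 30.0            # cos^2 coast-down duration
    initial_heading_deg: float = 0.0
    initial_position_cm: tuple[float, float] = (0.0, 0.0)
    noise_sd_cm: float = 0.0
    body_length_snout_to_com_cm: float = 4.0
    frame_rate_hz: float = 240.0
    pre_stimulus_ms: float = 500.0
    tail_ms: float = 80.0                   # still tail after the coast-down
    stimulus_distance_cm: float = 22.8
    stimulus_angle_deg: float = 81.3
    analysis_window_ms: float = 42.0        # window the ground truth integrates over
    fish_id: str = "sim"
    trial_number: int = 1
    tl_cm: float = 11.53
    seed: int = 0

    def validate(self) -> None:
        vals = [
            self.latency_ms, self.stage1_duration_ms, self.stage2_duration_ms,
            self.turn_angle_deg, self.stage2_return_angle_deg, self.u_max_cm_s,
            self.speed_rise_ms, self.post_stage2_ms, self.noise_sd_cm,
            self.frame_rate_hz, self.pre_stimulus_ms, self.analysis_window_ms,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite model parameter")
        if min(self.latency_ms, self.stage1_duration_ms, self.stage2_duration_ms,
               self.speed_rise_ms, self.u_max_cm_s, self.noise_sd_cm,
               self.post_stage2_ms) < 0:
            raise ValueError("durations, speeds and noise must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.u_max_cm_s > 0 and self.speed_rise_ms <= 0:
            raise ValueError("speed_rise_ms must be positive when u_max > 0")
        if (self.turn_angle_deg != 0 and self.stage2_return_angle_deg != 0
                and self.turn_angle_deg * self.stage2_return_angle_deg >= 0):
            raise ValueError("stage-1 and stage-2 angles must have opposite signs")
        active = self.stage1_duration_ms + self.stage2_duration_ms + self.post_stage2_ms
        if self.analysis_window_ms > active + self.tail_ms:
            raise ValueError("analysis window longer than the simulated motion")


@dataclass
class GroundTruth:
    """Closed-form truth for one simulated trial (noise-free model)."""

    latency_ms: float           # realized latency, snapped to the frame grid
    u_max_cm_s: float
    a_max_cm_s2: float          # pi * u_max / (2 t_U), the tangential peak
    d_esc_cm: float             # integral of the speed profile over the window
    stage1_duration_ms: float
    turn_angle_deg: float
    turning_rate_deg_ms: float

    def to_dict(self) -> dict[str, float]:
        return {
            "latency_ms": self.latency_ms,
            "u_max_cm_s": self.u_max_cm_s,
            "a_max_cm_s2": self.a_max_cm_s2,
            "d_esc_cm": self.d_esc_cm,
            "stage1_duration_ms": self.stage1_duration_ms,
            "turn_angle_deg": self.turn_angle_deg,
            "turning_rate_deg_ms": self.turning_rate_deg_ms,
        }


def _speed_profile(t_s: np.ndarray, p: CStartModelParams) -> np.ndarray:
    """Speed (cm/s) as a function of time since motion onset (s)."""
    u = p.u_max_cm_s
    t_u = p.speed_rise_ms / 1000.0
    t_end = (p.stage1_duration_ms + p.stage2_duration_ms) / 1000.0
    t_dec = p.post_stage2_ms / 1000.0
    s = np.zeros_like(t_s)
    if u == 0.0:
        return s
    rise = (t_s >= 0) & (t_s < t_u)
    s[rise] = u * np.sin(np.pi * t_s[rise] / (2 * t_u)) ** 2
    plateau = (t_s >= t_u) & (t_s <= t_end)
    s[plateau] = u
    if t_dec > 0:
        dec = (t_s > t_end) & (t_s < t_end + t_dec)
        s[dec] = u * np.cos(np.pi * (t_s[dec] - t_end) / (2 * t_dec)) ** 2
    return s


def _heading_profile(t_s: np.ndarray, p: CStartModelParams) -> np.ndarray:
    """Heading (rad) vs time since motion onset (s): half-sine omega pulses."""
    th0 = math.radians(p.initial_heading_deg)
    d1 = math.radians(p.turn_angle_deg)
    d2 = math.radians(p.stage2_return_angle_deg)
    t1 = p.stage1_duration_ms / 1000.0
    t2 = p.stage2_duration_ms / 1000.0
    th = np.full_like(t_s, th0)
    if t1 > 0:
        in1 = (t_s >= 0) & (t_s < t1)
        th[in1] = th0 + d1 / 2 * (1 - np.cos(np.pi * t_s[in1] / t1))
    after1 = t_s >= t1
    th[after1] = th0 + d1
    if t2 > 0:
        in2 = (t_s >= t1) & (t_s < t1 + t2)
        th[in2] = th0 + d1 + d2 / 2 * (1 - np.cos(np.pi * (t_s[in2] - t1) / t2))
    th[t_s >= t1 + t2] = th0 + d1 + d2
    return th


def _speed_integral(w_s: float, p: CStartModelParams) -> float:
    """Closed-form integral of the speed profile over [0, w] seconds."""
    u = p.u_max_cm_s
    if u == 0.0 or w_s <= 0:
        return 0.0
    t_u = p.speed_rise_ms / 1000.0
    t_end = (p.stage1_duration_ms + p.stage2_duration_ms) / 1000.0
    t_dec = p.post_stage2_ms / 1000.0
    d = 0.0
    t = min(w_s, t_u)
    # integral of sin^2(pi t / 2 t_u)
    d += u * (t / 2 - (t_u / (2 * np.pi)) * math.sin(np.pi * t / t_u))
    if w_s > t_u:
        d += u * (min(w_s, t_end) - t_u)
    if w_s > t_end and t_dec > 0:
        tau = min(w_s - t_end, t_dec)
        d += u * (tau / 2 + (t_dec / (2 * np.pi)) * math.sin(np.pi * tau / t_dec))
    return d


def simulate_trajectory(params: CStartModelParams) -> tuple[TrackedTrajectory, GroundTruth]:
    """One synthetic trial: tracked trajectory plus closed-form ground truth.

    Motion onset is snapped to the frame grid (first frame at or after
    stimulus time + latency) and the realized latency is what the ground
    truth records: at 240 Hz the sub-frame phase of the onset is not
    observable, so the generator does not pretend to encode it.
    """
    p = params
    p.validate()
    fr = p.frame_rate_hz
    dt = 1.0 / fr
    rng = np.random.default_rng(p.seed)

    stim_frame = int(round(p.pre_stimulus_ms / 1000.0 * fr))
    onset_offset = int(math.ceil(p.latency_ms / 1000.0 * fr - 1e-9))
    onset_frame = stim_frame + onset_offset
    realized_latency_ms = onset_offset * 1000.0 / fr

    active_ms = p.stage1_duration_ms + p.stage2_duration_ms + p.post_stage2_ms
    n_frames = onset_frame + int(math.ceil((active_ms + p.tail_ms) / 1000.0 * fr)) + 1
    frames = np.arange(n_frames)
    time_s = frames * dt

    # fine-grid quadrature of the CoM velocity from motion onset onward
    n_after = n_frames - onset_frame
    fine_t = np.arange((n_after - 1) * SUBSTEPS + 1) * (dt / SUBSTEPS)
    speed = _speed_profile(fine_t, p)
    theta = _heading_profile(fine_t, p)
    vx = speed * np.cos(theta)
    vy = speed * np.sin(theta)
    h = dt / SUBSTEPS
    x = np.concatenate([[0.0], np.cumsum((vx[1:] + vx[:-1]) / 2 * h)])
    y = np.concatenate([[0.0], np.cumsum((vy[1:] + vy[:-1]) / 2 * h)])

    com = np.zeros((n_frames, 2))
    com[:, 0] = p.initial_position_cm[0]
    com[:, 1] = p.initial_position_cm[1]
    com[onset_frame:, 0] += x[::SUBSTEPS]
    com[onset_frame:, 1] += y[::SUBSTEPS]

    head = np.full(n_frames, math.radians(p.initial_heading_deg))
    head[onset_frame:] = theta[::SUBSTEPS]
    snout = com + p.body_length_snout_to_com_cm * np.column_stack(
        [np.cos(head), np.sin(head)]
    )

    stim_dir = math.radians(p.initial_heading_deg + p.stimulus_angle_deg)
    stimulus_xy = (
        p.initial_position_cm[0] + p.stimulus_distance_cm * math.cos(stim_dir),
        p.initial_position_cm[1] + p.stimulus_distance_cm * math.sin(stim_dir),
    )

    if p.noise_sd_cm > 0:
        com = com + rng.normal(0.0, p.noise_sd_cm, com.shape)
        snout = snout + rng.normal(0.0, p.noise_sd_cm, snout.shape)

    traj = TrackedTrajectory(
        frames=frames,
        time_s=time_s,
        com_xy_cm=com,
        snout_xy_cm=snout,
        frame_rate_hz=fr,
        stimulus_frame=stim_frame,
        stimulus_xy_cm=stimulus_xy,
        fish_id=p.fish_id,
        trial_number=p.trial_number,
        tl_cm=p.tl_cm,
    )

    turn = min(abs(p.turn_angle_deg), 360.0 - abs(p.turn_angle_deg)) \
        if abs(p.turn_angle_deg) > 180.0 else abs(p.turn_angle_deg)
    t1 = p.stage1_duration_ms
    a_max = (np.pi * p.u_max_cm_s / (2 * p.speed_rise_ms / 1000.0)
             if p.u_max_cm_s > 0 else 0.0)
    truth = GroundTruth(
        latency_ms=realized_latency_ms,
        u_max_cm_s=p.u_max_cm_s,
        a_max_cm_s2=a_max,
        d_esc_cm=_speed_integral(p.analysis_window_ms / 1000.0, p),
        stage1_duration_ms=t1,
        turn_angle_deg=turn,
        turning_rate_deg_ms=turn / t1 if t1 > 0 else 0.0,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# population-level generator


@dataclass
class PopulationDesign:
    """Design of a synthetic fish x trial experiment (measures table).

    ``among_cv`` / ``within_cv`` are target coefficients of variation of
    the per-fish means and of trials within a fish; scalars apply to every
    measure, dicts set them per measure.  ``trial_effect`` multiplies trial
    j by (1 + trial_effect * (j - 1)): a habituation/fatigue trend (0 =
    none).  Covariate means/sds default to the reference protocol's
    printed statistics.
    """

    n_fish: int = 14
    n_trials: int = 5
    among_cv: float | dict[str, float] = 0.30
    within_cv: float | dict[str, float] = 0.25
    trial_effect: float | dict[str, float] = 0.0
    tl_mean_cm: float = 11.53
    tl_sd_cm: float = 0.53
    angle_mean_deg: float = 81.3
    angle_sd_deg: float = 25.4
    distance_mean_cm: float = 22.8
    distance_sd_cm: float = 3.7
    covariate_slopes: dict[str, dict[str, float]] = field(default_factory=dict)
    measure_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEASURE_MEANS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_fish < 2 or self.n_trials < 2:
            raise ValueError("need at least 2 fish and 2 trials")
        for name in ("among_cv", "within_cv"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(c < 0 for c in vals):
                raise ValueError(f"{name} must be non-negative")

    def _per_measure(self, attr: str, measure: str) -> float:
        v = getattr(self, attr)
        return float(v.get(measure, 0.0)) if isinstance(v, dict) else float(v)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0.0:
        return np.ones(size)
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-s2 / 2, sigma=math.sqrt(s2), size=size)


def simulate_population(
    design: PopulationDesign, return_means: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format fish x trial x measure table with controlled variance.

    Each measure m and fish i gets a lognormal individual mean mu_i
    (population CV ~ among_cv); trial j's value is
    mu_i * eps_ij * (1 + trial_effect (j-1)) * exp(sum slope_c z_c)
    with lognormal eps_ij (CV ~ within_cv) and z_c the standardized
    covariates.  Deterministic under ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    fish_ids = [f"F{i + 1:02d}" for i in range(design.n_fish)]
    trials = np.arange(1, design.n_trials + 1)

    tl = rng.normal(design.tl_mean_cm, design.tl_sd_cm, design.n_fish)
    angle = np.clip(
        rng.normal(design.angle_mean_deg, design.angle_sd_deg,
                   (design.n_fish, design.n_trials)), 0.0, 180.0)
    dist = np.clip(
        rng.normal(design.distance_mean_cm, design.distance_sd_cm,
                   (design.n_fish, design.n_trials)), 1.0, None)

    cov_z = {
        "tl_cm": np.broadcast_to(
            ((tl - design.tl_mean_cm) / design.tl_sd_cm)[:, None],
            (design.n_fish, design.n_trials)),
        "initial_orientation_deg": (angle - design.angle_mean_deg) / design.angle_sd_deg,
        "initial_distance_cm": (dist - design.distance_mean_cm) / design.distance_sd_cm,
    }

    rows = []
    means_rows = []
    for measure in MEASURES:
        base = design.measure_means[measure]
        mu = base * _lognormal_factor(rng, design._per_measure("among_cv", measure),
                                      design.n_fish)
        eps = _lognormal_factor(rng, design._per_measure("within_cv", measure),
                                (design.n_fish, design.n_trials))
        trend = 1.0 + design._per_measure("trial_effect", measure) * (trials - 1)
        vals = mu[:, None] * eps * trend[None, :]
        slopes = design.covariate_slopes.get(measure, {})
        for cov, beta in slopes.items():
            vals = vals * np.exp(beta * cov_z[cov])
        for i, fid in enumerate(fish_ids):
            means_rows.append({"fish_id": fid, "measure": measure, "mu": mu[i]})
            for j, t in enumerate(trials):
                rows.append({
                    "fish_id": fid,
                    "trial": int(t),
                    "measure": measure,
                    "value": vals[i, j],
                    "tl_cm": tl[i],
                    "initial_orientation_deg": angle[i, j],
                    "initial_distance_cm": dist[i, j],
                    "flag": "",
                })
    table = pd.DataFrame(rows)
    if return_means:
        return table, pd.DataFrame(means_rows)
    return table


# ---------------------------------------------------------------------------
# full synthetic study: trajectories with among/within structure


def sample_cstart_params(
    rng: np.random.Generator,
    noise_sd_cm: float = 0.02,
    frame_rate_hz: float = 240.0,
) -> CStartModelParams:
    """One realistic random trial parameterization (no fish structure)."""
    t1 = float(np.clip(rng.normal(24.0, 2.0), 16.0, 32.0))
    t2 = float(np.clip(rng.normal(18.0, 1.5), 12.0, 24.0))
    turn = float(rng.uniform(40.0, 110.0)) * (1.0 if rng.random() < 0.5 else -1.0)
    ret = -turn * (t2 / t1) ** 2 * float(rng.normal(1.0, 0.05))
    u = float(np.clip(150.0 * _lognormal_factor(rng, 0.20, None), 60.0, 350.0))
    lat = float(np.clip(30.0 * _lognormal_factor(rng, 0.35, None), 8.0, 150.0))
    tl = float(rng.normal(11.53, 0.53))
    return CStartModelParams(
        latency_ms=lat,
        stage1_duration_ms=t1,
        stage2_duration_ms=t2,
        turn_angle_deg=turn,
        stage2_return_angle_deg=ret,
        u_max_cm_s=u,
        speed_rise_ms=float(np.clip(rng.normal(28.0, 1.5), 22.0, 34.0)),
        initial_heading_deg=float(rng.uniform(0.0, 360.0)),
        initial_position_cm=(float(rng.uniform(-5, 5)), float(rng.uniform(-5, 5))),
        noise_sd_cm=noise_sd_cm,
        body_length_snout_to_com_cm=0.35 * tl,
        frame_rate_hz=frame_rate_hz,
        stimulus_distance_cm=float(np.clip(rng.normal(22.8, 3.7), 5.0, None)),
        stimulus_angle_deg=float(np.clip(rng.normal(81.3, 25.4), 10.0, 170.0)),
        tl_cm=tl,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_experiment(
    n_fish: int = 14,
    n_trials: int = 5,
    seed: int = 0,
    noise_sd_cm: float = 0.02,
    frame_rate_hz: float = 240.0,
    among_cv: float = 0.30,
    within_cv: float = 0.15,
) -> list[tuple[TrackedTrajectory, GroundTruth]]:
    """A full synthetic study: n_fish x n_trials tracked trials.

    Per-fish mean peak speed, latency and turn magnitude carry
    among-individual lognormal variance; trials within a fish carry
    within-individual lognormal variance around those means.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[TrackedTrajectory, GroundTruth]] = []
    for i in range(n_fish):
        fid = f"F{i + 1:02d}"
        u_i = 150.0 * float(_lognormal_factor(rng, among_cv, None))
        lat_i = 30.0 * float(_lognormal_factor(rng, among_cv, None))
        turn_i = float(np.clip(75.0 * _lognormal_factor(rng, among_cv, None), 30.0, 160.0))
        tl = float(rng.normal(11.53, 0.53))
        for j in range(1, n_trials + 1):
            base = sample_cstart_params(rng, noise_sd_cm, frame_rate_hz)
            u = float(np.clip(u_i * _lognormal_factor(rng, within_cv, None), 60.0, 350.0))
            lat = float(np.clip(lat_i * _lognormal_factor(rng, within_cv, None), 8.0, 300.0))
            turn = float(np.clip(turn_i * _lognormal_factor(rng, within_cv, None), 25.0, 170.0))
            turn *= 1.0 if rng.random() < 0.5 else -1.0
            ret = -turn * (base.stage2_duration_ms / base.stage1_duration_ms) ** 2 \
                * float(rng.normal(1.0, 0.05))
            p = replace(
                base,
                u_max_cm_s=u,
                latency_ms=lat,
                turn_angle_deg=turn,
                stage2_return_angle_deg=ret,
                tl_cm=tl,
                body_length_snout_to_com_cm=0.35 * tl,
                fish_id=fid,
                trial_number=j,
            )
            out.append(simulate_trajectory(p))
    return out
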