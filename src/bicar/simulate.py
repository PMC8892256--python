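"""Closed-loop synthetic patient sessions.

A parametric subject model plays MineCart/Sakura through the force-map
controller.  Each reach (one falling crystal) is produced as a train of
minimum-jerk force pulses: after a sampled reaction delay the subject drives
the handlebar by pressing one side and lifting the other; fragmented
(multi-sub-movement) motion, per-arm weakness by hemiparesis side, tremor
noise and the load-cell/encoder quantization of the physical device are all
emulated, and every source of randomness is seeded.

Model summary
-------------
* The handlebar plant is quasi-static (the device's moving mass and speed are
  small): angular velocity is proportional to the measured force differential
  in excess of the effective rotation threshold,
  ``omega = mobility * (|F_r - F_l| - dF_eff)+``.
* A reach toward target ``theta_d`` is planned as ``K`` sequential sub-
  movements with geometrically decreasing amplitudes (each corrective pulse
  covers a fraction of the remaining error), every pulse bell-shaped
  (minimum-jerk speed profile), so the noiseless speed trace has exactly
  ``K`` local maxima.
* The profile's *reaction delay* is the latency from crystal spawn to
  detectable movement onset - the instant the planned speed first crosses 5%
  of its peak.  The pulse train is scheduled so this crossing lands exactly
  at the sampled delay, and the *movement time* is the span between the first
  and last 5%-of-peak crossings.  Per-reach ground-truth onset/settle times
  and realized sub-movement counts are logged for recovery testing.
* Weakness: the affected arm's press force saturates at
  ``arm_strength * (1 - severity)`` above the hold force; a saturated pulse
  moves the bar more slowly, the subject re-plans corrective pulses, and the
  crystal may be lost.  Fragmentation concentrates on the nonparetic side
  (compensatory overuse produces the irregular, peak-rich force profile seen
  on that side), while affected-side drives are feebler and smoother.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .game import (
    ControllerConfig,
    GameConfig,
    GameMode,
    GameState,
    ForceSample,
    Intent,
    classify_intent,
    effective_threshold,
    step_game,
)

__all__ = [
    "SubjectProfile",
    "SensorModel",
    "SessionLog",
    "InfeasibleConfigError",
    "simulate_session",
    "generate_reach_forces",
    "acquire",
    "healthy_profile",
    "post_stroke_profile",
    "save_session",
    "load_session",
    "minimum_jerk_speed",
]

ONSET_FRACTION = 0.05  # of a reach's peak speed; defines "detectable onset"


class InfeasibleConfigError(ValueError):
    """Controller demands a force differential the subject cannot produce."""


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of a synthetic participant.

    Times in seconds, forces in kgf.  ``reaction_delay_mean`` is the latency
    to detectable movement onset; ``movement_time_mean`` the onset-to-settle
    duration of an unimpeded reach.  ``submovements_mean`` >= 1 is the
    expected sub-movement count per reach (``K = 1 + Poisson(mean - 1)``).
    ``paresis_severity`` scales down the affected arm's available press force
    and adds ``severity * paresis_extra_delay`` to reaction time when that arm
    must drive.
    """

    reaction_delay_mean: float = 0.73
    reaction_delay_sd: float = 0.12
    movement_time_mean: float = 2.5
    movement_time_sd: float = 0.35
    arm_strength_left: float = 4.0
    arm_strength_right: float = 4.0
    hemiparesis_side: Literal["none", "left", "right"] = "none"
    paresis_severity: float = 0.0
    paresis_extra_delay: float = 0.5
    submovements_mean: float = 1.0
    tremor_sd: float = 0.02
    hold_force: float = 1.5       # static per-side share of the weighted bar
    lift_share: float = 0.4       # fraction of the differential taken by lifting
    mobility: float = 0.18        # rad/s of bar rotation per kgf of excess differential
    correction_fraction: float = 0.6  # remaining-error fraction left to later submovements

    def __post_init__(self) -> None:
        if self.reaction_delay_mean <= 0:
            raise ValueError("reaction delay mean must be positive")
        if self.arm_strength_left <= 0 or self.arm_strength_right <= 0:
            raise ValueError("arm strength scales must be positive")
        if not 0.0 <= self.paresis_severity < 1.0:
            raise ValueError("paresis severity must be in [0, 1)")
        if self.submovements_mean < 1.0:
            raise ValueError("mean sub-movement count must be >= 1")

    def press_capacity(self, side: Literal["left", "right"]) -> float:
        """Max press force above the hold force for one arm, after paresis."""
        strength = self.arm_strength_left if side == "left" else self.arm_strength_right
        if side == self.hemiparesis_side:
            strength *= 1.0 - self.paresis_severity
        return strength

    def hold_side(self, side: Literal["left", "right"]) -> float:
        """Static per-side share of the weighted handlebar.

        A hemiparetic subject shifts weight-bearing toward the nonparetic
        arm; the shift grows with severity while the total stays constant,
        and stays small enough that the resting differential never reaches
        the rotation threshold.
        """
        if self.hemiparesis_side == "none":
            return self.hold_force
        shift = 0.15 * self.paresis_severity * self.hold_force
        return self.hold_force - shift if side == self.hemiparesis_side else self.hold_force + shift


@dataclass(frozen=True)
class SensorModel:
    """Load-cell and encoder acquisition model of the physical device."""

    force_rate: float = 80.0        # Hz
    force_resolution: float = 0.025  # kgf per step
    force_capacity: float = 20.0     # kgf saturation
    encoder_ppr: int = 500           # pulses per revolution (incremental)

    def __post_init__(self) -> None:
        if self.force_resolution <= 0 or self.force_rate <= 0:
            raise ValueError("rate and resolution must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.force_rate

    @property
    def encoder_step(self) -> float:
        """Angular resolution assuming quadrature (4x) decoding, rad."""
        return 2.0 * math.pi / (4.0 * self.encoder_ppr)


@dataclass
class SessionLog:
    """One recorded game session: uniform-rate samples plus discrete events.

    ``samples`` columns: t_s, theta_rad, theta_d_rad, F_left_kgf, F_right_kgf,
    assist_level.  ``events`` are ``(t, kind, payload)`` with kind in
    {spawn, caught, lost, assist_change, overforce_warning}.  ``truth`` holds
    the simulator's per-reach ground truth (onset/settle times, drawn delay
    and movement time, realized sub-movement count) for recovery studies.
    """

    metadata: dict
    samples: pd.DataFrame
    events: list
    truth: list = field(default_factory=list)

    def validate(self) -> None:
        t = self.samples["t_s"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError("sample timestamps must be strictly increasing")
        n_spawn = sum(1 for e in self.events if e[1] == "spawn")
        n_res = sum(1 for e in self.events if e[1] in ("caught", "lost"))
        if n_res > n_spawn or n_spawn - n_res > 1:
            raise ValueError("every spawn must resolve as caught or lost")


def minimum_jerk_speed(tau: np.ndarray | float) -> np.ndarray | float:
    """Speed profile of a unit-displacement, unit-duration minimum-jerk pulse.

    ``30 (tau^2 - 2 tau^3 + tau^4)`` on [0, 1]: integrates to 1, peaks at
    1.875 at mid-pulse, zero speed and acceleration at both ends.
    """
    tau = np.clip(tau, 0.0, 1.0)
    return 30.0 * (tau**2 - 2.0 * tau**3 + tau**4)


_PEAK = 1.875  # peak of minimum_jerk_speed


def _bell_crossing(frac: float) -> float:
    """tau in (0, 0.5] where the unit bell first reaches ``frac`` of its peak."""
    if frac >= 1.0:
        return 0.5
    return brentq(lambda x: minimum_jerk_speed(x) - frac * _PEAK, 1e-12, 0.5)


# ---------------------------------------------------------------------------
# Sensor model
# ---------------------------------------------------------------------------

def acquire(
    true_forces: tuple[float, float], true_theta: float, sensors: SensorModel
) -> tuple[float, float, float]:
    """One acquisition: clip/quantize forces, quantize the encoder angle.

    Forces are clipped to ``[0, capacity]`` and rounded to the nearest
    multiple of the load-cell resolution; the angle is rounded to the nearest
    quadrature-decoded encoder step.
    """
    res = sensors.force_resolution
    out = []
    for f in true_forces:
        f = min(max(f, 0.0), sensors.force_capacity)
        out.append(round(f / res) * res)
    step = sensors.encoder_step
    theta_q = round(true_theta / step) * step
    return out[0], out[1], theta_q


# ---------------------------------------------------------------------------
# Reach planning
# ---------------------------------------------------------------------------

@dataclass
class _Pulse:
    start: float      # s, absolute session time
    duration: float   # s
    amplitude: float  # kgf of differential-force amplitude (signed: + = CCW)

    @property
    def end(self) -> float:
        return self.start + self.duration

    def peak_speed(self, mobility: float) -> float:
        return mobility * abs(self.amplitude) * _PEAK


@dataclass
class _Reach:
    t_spawn: float
    theta_d: float
    direction: int            # +1 CCW, -1 CW
    delay_drawn: float
    movement_time_drawn: float
    pulses: list = field(default_factory=list)
    n_planned: int = 0
    n_corrective: int = 0
    done_planning: bool = False

    def speed_truth_crossings(self, mobility: float) -> tuple[float, float]:
        """Ground-truth onset/settle: first/last 5%-of-peak crossing of the
        noiseless planned speed trace (pulses are disjoint in time)."""
        peaks = [p.peak_speed(mobility) for p in self.pulses]
        vstar = ONSET_FRACTION * max(peaks)
        first = next(p for p, pk in zip(self.pulses, peaks) if pk >= vstar)
        last = next(
            p for p, pk in zip(reversed(self.pulses), reversed(peaks)) if pk >= vstar
        )
        tau_on = _bell_crossing(vstar / first.peak_speed(mobility))
        tau_off = _bell_crossing(vstar / last.peak_speed(mobility))
        return first.start + tau_on * first.duration, last.end - tau_off * last.duration


def _plan_reach(
    t_now: float,
    t_spawn: float,
    theta_now: float,
    theta_d: float,
    profile: SubjectProfile,
    ctrl: ControllerConfig,
    tol_theta: float,
    rng: np.random.Generator,
) -> _Reach:
    delta = theta_d - theta_now
    direction = 1 if delta >= 0 else -1
    # CCW (+) is driven by pressing left, CW (-) by pressing right
    driving_side = "left" if direction > 0 else "right"

    delay = rng.normal(profile.reaction_delay_mean, profile.reaction_delay_sd)
    if driving_side == profile.hemiparesis_side:
        delay += profile.paresis_severity * profile.paresis_extra_delay
    delay = max(0.15, delay)
    mtime = max(0.5, rng.normal(profile.movement_time_mean, profile.movement_time_sd))

    lam = max(0.0, profile.submovements_mean - 1.0)
    if profile.hemiparesis_side != "none":
        if driving_side == profile.hemiparesis_side:
            lam *= 1.0 - profile.paresis_severity   # feeble, smoother push
        else:
            lam *= 1.0 + 2.0 * profile.paresis_severity  # compensatory overuse
    k = 1 + int(rng.poisson(lam))
    # keep the target unreached until the final sub-movement stays visible
    c = profile.correction_fraction
    while k > 1 and abs(delta) * c ** (k - 1) <= 1.5 * tol_theta:
        k -= 1

    if k == 1:
        amps_theta = [delta]
    else:
        amps_theta = [delta * (1 - c) * c**j for j in range(k - 1)]
        amps_theta.append(delta * c ** (k - 1))

    # unit-duration layout to find the 5%-crossing span, then scale durations
    peaks_unit = [abs(a) * _PEAK for a in amps_theta]  # proportional to true peaks
    vstar = ONSET_FRACTION * max(peaks_unit)
    j0 = next(i for i, p in enumerate(peaks_unit) if p >= vstar)
    jl = next(i for i in reversed(range(k)) if peaks_unit[i] >= vstar)
    tau_on = _bell_crossing(vstar / peaks_unit[j0])
    tau_off = _bell_crossing(vstar / peaks_unit[jl])
    o_first = j0 + tau_on
    o_last = jl + 1 - tau_off
    t_sub = mtime / (o_last - o_first)
    t_start = max(t_now + 1e-9, t_spawn + delay - o_first * t_sub)

    reach = _Reach(
        t_spawn=t_spawn,
        theta_d=theta_d,
        direction=direction,
        delay_drawn=delay,
        movement_time_drawn=mtime,
        n_planned=k,
    )
    for j, a in enumerate(amps_theta):
        amp_force = a / (profile.mobility * t_sub)  # signed kgf differential
        reach.pulses.append(_Pulse(t_start + j * t_sub, t_sub, amp_force))
    return reach


def _corrective_pulse(
    t_now: float,
    theta_now: float,
    reach: _Reach,
    profile: SubjectProfile,
    rng: np.random.Generator,
) -> None:
    err = reach.theta_d - theta_now
    pause = 0.25 + abs(rng.normal(0.0, 0.05))
    dur = min(1.5, max(0.4, profile.movement_time_mean * abs(err) / 0.5))
    amp = err / (profile.mobility * dur)
    reach.pulses.append(_Pulse(t_now + pause, dur, amp))
    reach.n_corrective += 1


# ---------------------------------------------------------------------------
# Force synthesis
# ---------------------------------------------------------------------------

def _subject_forces(
    t: float,
    reach: Optional[_Reach],
    profile: SubjectProfile,
    thr_eff: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Noiseless-then-tremored true forces at time ``t`` (left, right)."""
    hold_l, hold_r = profile.hold_side("left"), profile.hold_side("right")
    f_left, f_right = hold_l, hold_r
    if reach is not None:
        active = [p for p in reach.pulses if p.start <= t < p.end]
        in_train = reach.pulses and reach.pulses[0].start <= t < reach.pulses[-1].end
        u = 0.0
        direction = reach.direction
        if active:
            p = active[0]
            u = abs(p.amplitude) * float(
                minimum_jerk_speed((t - p.start) / p.duration)
            )
            direction = 1 if p.amplitude >= 0 else -1
        if in_train:
            press = "left" if direction > 0 else "right"
            cap = profile.press_capacity(press)
            hold_lift = hold_r if press == "left" else hold_l
            # the lifting arm cannot unload below ~0; any unmet lift demand is
            # rerouted to the pressing arm, which saturates at its capacity
            lift = min(profile.lift_share * u, hold_lift - 0.1)
            press_extra = min(thr_eff + u - lift, cap)
            if press == "left":
                f_left = hold_l + press_extra
                f_right = hold_r - lift
            else:
                f_right = hold_r + press_extra
                f_left = hold_l - lift
    if profile.tremor_sd > 0:
        f_left += rng.normal(0.0, profile.tremor_sd)
        f_right += rng.normal(0.0, profile.tremor_sd)
    return max(0.0, f_left), max(0.0, f_right)


def generate_reach_forces(
    profile: SubjectProfile,
    direction: Literal["CW", "CCW"],
    times: np.ndarray,
    rng: np.random.Generator,
    amplitude_rad: float = 0.5,
    delta_F: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Force traces (left, right) for one isolated reach.

    ``times`` are seconds since target presentation.  A reaction delay,
    sub-movement count and movement time are drawn from the profile; before
    the delay both arms stay at the baseline hold force, afterwards the
    driving side presses in minimum-jerk pulses while the other side lifts,
    with tremor noise and hemiparetic force scaling applied.
    """
    sign = 1 if direction == "CCW" else -1
    reach = _plan_reach(
        t_now=0.0,
        t_spawn=0.0,
        theta_now=0.0,
        theta_d=sign * amplitude_rad,
        profile=profile,
        ctrl=ControllerConfig(delta_F=delta_F),
        tol_theta=0.02,
        rng=rng,
    )
    fl = np.empty_like(times, dtype=float)
    fr = np.empty_like(times, dtype=float)
    for i, t in enumerate(times):
        fl[i], fr[i] = _subject_forces(float(t), reach, profile, delta_F, rng)
    return fl, fr


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

def _check_feasible(profile: SubjectProfile, ctrl: ControllerConfig) -> None:
    max_diff = (
        min(profile.press_capacity("left"), profile.press_capacity("right"))
        + profile.hold_force
        - 0.1
    )
    if ctrl.delta_F >= max_diff:
        raise InfeasibleConfigError(
            f"delta_F = {ctrl.delta_F} kgf exceeds the subject's achievable "
            f"force differential ({max_diff:.2f} kgf)"
        )


def simulate_session(
    profile: SubjectProfile,
    ctrl_cfg: ControllerConfig,
    sensors: SensorModel | None = None,
    duration: float = 300.0,
    seed: int = 0,
    game_cfg: GameConfig | None = None,
    subject_id: str = "synthetic",
    session_date: str = "2024-01-01T10:00:00",
) -> SessionLog:
    """Simulate one closed-loop game session and return its log.

    Deterministic for a given ``seed``: the game's crystal stream and the
    subject's draws use independent child streams of the seed, so two players
    (e.g. MineCart vs Sakura configs) see the same crystal sequence.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    sensors = sensors or SensorModel()
    game_cfg = game_cfg or GameConfig()
    _check_feasible(profile, ctrl_cfg)

    rng_game = np.random.default_rng([int(seed) % 2**31, 11])
    rng_subject = np.random.default_rng([int(seed) % 2**31, 23])

    dt = sensors.dt
    n_steps = int(round(duration / dt))
    state = GameState(fall_speed=game_cfg.fall_speed, assist_level=ctrl_cfg.assist_level)
    tol_theta = ctrl_cfg.tolerance / game_cfg.wagon_gain

    theta = 0.0
    theta_d = 0.0
    reach: Optional[_Reach] = None
    truth: list[dict] = []
    events: list = []
    n_events_seen = 0
    in_overforce = False
    drift_speed = 0.10      # rad/s toward target at assist level >= 2
    takeover_speed = 0.30   # rad/s at full takeover (level A_max)

    cols = {k: np.empty(n_steps) for k in
            ("t_s", "theta_rad", "theta_d_rad", "F_left_kgf", "F_right_kgf")}
    assist_col = np.empty(n_steps, dtype=int)

    def finalize_reach(r: _Reach, outcome: str) -> None:
        t_on, t_off = r.speed_truth_crossings(profile.mobility)
        vis = ONSET_FRACTION * max(p.peak_speed(profile.mobility) for p in r.pulses)
        n_visible = sum(1 for p in r.pulses if p.peak_speed(profile.mobility) >= vis)
        truth.append(
            {
                "t_spawn": r.t_spawn,
                "theta_d": r.theta_d,
                "direction": "CCW" if r.direction > 0 else "CW",
                "outcome": outcome,
                "delay_drawn": r.delay_drawn,
                "movement_time_drawn": r.movement_time_drawn,
                "t_onset_true": t_on,
                "t_settle_true": t_off,
                "n_submovements": n_visible,
                "n_planned": r.n_planned,
                "n_corrective": r.n_corrective,
            }
        )

    cfg = replace(ctrl_cfg, assist_level=state.assist_level)
    for i in range(n_steps):
        t = i * dt
        state.t = t
        cfg = replace(ctrl_cfg, assist_level=state.assist_level)
        thr_eff = effective_threshold(cfg)

        # --- subject
        f_left, f_right = _subject_forces(t, reach, profile, thr_eff, rng_subject)
        fl_q, fr_q, theta_q = acquire((f_left, f_right), theta, sensors)

        # --- controller: intent from the measured forces
        intent = classify_intent(ForceSample(t, fl_q, fr_q), cfg)
        if intent is Intent.OVERFORCE and not in_overforce:
            events.append((t, "overforce_warning", {}))
        in_overforce = intent is Intent.OVERFORCE

        # --- plant: quasi-static rotation from the excess differential
        omega = 0.0
        diff = fr_q - fl_q
        if intent is Intent.CW:
            omega = -profile.mobility * (diff - thr_eff)
        elif intent is Intent.CCW:
            omega = profile.mobility * (-diff - thr_eff)
        if state.assist_level >= 2 and state.crystal_active:
            err = theta_d - theta
            if abs(err) > tol_theta * 0.5:
                if state.assist_level >= cfg.A_max:
                    omega = takeover_speed * math.copysign(1.0, err)
                else:
                    omega += drift_speed * math.copysign(1.0, err)
        theta += omega * dt

        # --- record
        cols["t_s"][i] = t
        cols["theta_rad"][i] = theta_q
        cols["theta_d_rad"][i] = theta_d
        cols["F_left_kgf"][i] = fl_q
        cols["F_right_kgf"][i] = fr_q
        assist_col[i] = state.assist_level

        # --- game
        step_game(state, intent, dt, cfg, game_cfg, rng_game, theta=theta)
        while n_events_seen < len(state.events):
            ev_t, kind, payload = state.events[n_events_seen]
            n_events_seen += 1
            events.append((ev_t, kind, dict(payload)))
            if kind == "spawn":
                theta_d = game_cfg.theta_from_x(payload["crystal_x"])
                reach = _plan_reach(
                    t, ev_t, theta, theta_d, profile, cfg, tol_theta, rng_subject
                )
            elif kind in ("caught", "lost") and reach is not None:
                finalize_reach(reach, kind)
                reach = None

        # --- subject re-plans when the planned train missed the target
        if (
            reach is not None
            and state.crystal_active
            and reach.pulses
            and t > reach.pulses[-1].end + 0.1
            and not any(p.start <= t + 0.35 for p in reach.pulses if p.start > t)
            and abs(theta_d - theta) > tol_theta
        ):
            _corrective_pulse(t, theta, reach, profile, rng_subject)

    if reach is not None:  # session ended mid-reach
        finalize_reach(reach, "unresolved")

    samples = pd.DataFrame({**cols, "assist_level": assist_col})
    events.sort(key=lambda e: e[0])
    log = SessionLog(
        metadata={
            "subject_id": subject_id,
            "session_date": session_date,
            "game_mode": ctrl_cfg.mode.value,
            "seed": int(seed),
            "duration_s": duration,
            "score": state.score,
            "losses": state.losses,
            "controller": _cfg_dict(ctrl_cfg),
            "game": asdict(game_cfg),
            "sensors": asdict(sensors),
            "profile": asdict(profile),
        },
        samples=samples,
        events=events,
        truth=truth,
    )
    log.validate()
    return log


def _cfg_dict(cfg: ControllerConfig) -> dict:
    d = asdict(cfg)
    d["mode"] = cfg.mode.value
    return d


# ---------------------------------------------------------------------------
# Persistence: CSV of samples + JSON sidecar (metadata, events, truth)
# ---------------------------------------------------------------------------

def save_session(log: SessionLog, basepath: str) -> tuple[str, str]:
    """Write ``<base>.csv`` (samples) and ``<base>.json`` (metadata/events).

    Floats are written with 17 significant digits so the round trip through
    :func:`load_session` is lossless.
    """
    csv_path, json_path = f"{basepath}.csv", f"{basepath}.json"
    log.samples.to_csv(csv_path, index=False, float_format="%.17g")
    with open(json_path, "w") as fh:
        json.dump(
            {"metadata": log.metadata, "events": log.events, "truth": log.truth},
            fh,
            indent=1,
            sort_keys=True,
        )
    return csv_path, json_path


def load_session(basepath: str) -> SessionLog:
    samples = pd.read_csv(f"{basepath}.csv", float_precision="round_trip")
    samples["assist_level"] = samples["assist_level"].astype(int)
    with open(f"{basepath}.json") as fh:
        side = json.load(fh)
    events = [(e[0], e[1], e[2]) for e in side["events"]]
    return SessionLog(side["metadata"], samples, events, side.get("truth", []))


# ---------------------------------------------------------------------------
# Reference profiles (calibration targets, not patient measurements)
# ---------------------------------------------------------------------------

def healthy_profile(**overrides) -> SubjectProfile:
    """Healthy-adult calibration: ~0.73 s reaction, ~2.5 s movement, single
    sub-movement reaches, symmetric strength."""
    return replace(SubjectProfile(), **overrides) if overrides else SubjectProfile()


def post_stroke_profile(
    side: Literal["left", "right"] = "left", severity: float = 0.4, **overrides
) -> SubjectProfile:
    """Post-stroke calibration: ~1.03 s reaction, ~4.6 s movement, fragmented
    reaches (~4 sub-movements) and one-sided weakness."""
    base = SubjectProfile(
        reaction_delay_mean=1.03,
        reaction_delay_sd=0.25,
        movement_time_mean=4.6,
        movement_time_sd=0.8,
        arm_strength_left=3.5,
        arm_strength_right=3.5,
        hemiparesis_side=side,
        paresis_severity=severity,
        submovements_mean=4.1,
        tremor_sd=0.05,
    )
    return replace(base, **overrides) if overrides else base
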