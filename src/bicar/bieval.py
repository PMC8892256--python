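"""BiEval: movement segmentation and the 15 performance parameters.

Given a recorded session (angle, target angle and per-arm forces sampled at a
uniform rate, plus game events) the engine

1. estimates angular velocity, acceleration and jerk by Savitzky-Golay
   polynomial-smoothing differentiation of the encoder angle,
2. cuts the session into one movement segment per target change, locating the
   four landmarks ``T_0 <= T_i <= T_d <= T_f`` (target issued, movement onset,
   target reached, movement settled),
3. computes per-segment time, speed, smoothness and error parameters and
   session-level force and torque parameters,
4. discards per-parameter statistical outliers (1.5*IQR fence) before
   averaging, and
5. assembles everything with the game score/losses into a
   :class:`PerformanceReport`.

Onset is the first sustained instant with productive torque (per-arm effort
in the target direction) and angular speed above a threshold; settling is the
first sustained sub-threshold-speed instant after the target is reached.
Thresholds default to 5% of each segment's own peak speed, making the
landmarks invariant to movement amplitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter, find_peaks

from .kinematics import RobotGeometry
from .simulate import SessionLog

__all__ = [
    "SegmentationConfig",
    "MovementSegment",
    "PerformanceReport",
    "kinematic_derivatives",
    "segment_movements",
    "time_parameters",
    "speed_parameters",
    "smoothness_parameters",
    "error_parameter",
    "force_parameters",
    "torque_parameters",
    "validate_outliers",
    "session_report",
    "report_to_json",
    "report_from_json",
    "report_csv_row",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Derivative smoothing, landmark thresholds and peak-detection settings.

    Velocity thresholds are fractions of each segment's peak speed unless an
    absolute override (rad/s) is given.  ``peak_prominence`` is the fraction
    of a segment's peak speed a velocity local maximum must rise above its
    surroundings to count as a sub-movement; ``force_peak_prominence`` (kgf)
    plays the same role for force peaks.
    """

    smoothing_window_s: float = 0.35
    smoothing_polyorder: int = 3
    onset_velocity_fraction: float = 0.05
    end_velocity_fraction: float = 0.05
    onset_velocity_threshold: Optional[float] = None  # rad/s, absolute override
    end_velocity_threshold: Optional[float] = None
    peak_prominence: float = 0.10
    force_peak_prominence: float = 0.30
    position_tolerance_rad: Optional[float] = None  # default: game capture window
    sustain_samples: int = 3
    signed_jerk: bool = False  # published integrand is ambiguous; |J| by default

    def __post_init__(self) -> None:
        if self.smoothing_window_s <= 0:
            raise ValueError("smoothing window must be positive")
        for name in ("onset_velocity_fraction", "end_velocity_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MovementSegment:
    """One repetition: slices of the session between two target changes."""

    T_0: float
    T_i: Optional[float]
    T_d: Optional[float]
    T_f: Optional[float]
    direction: int  # +1 CCW, -1 CW
    theta_d: float
    t: np.ndarray
    theta: np.ndarray
    theta_d_series: np.ndarray
    omega: np.ndarray
    jerk: np.ndarray
    F_left: np.ndarray
    F_right: np.ndarray
    completed: bool = False

    @property
    def has_onset(self) -> bool:
        return self.T_i is not None

    def motion_slice(self) -> slice:
        """Index slice covering [T_i, T_f]."""
        if self.T_i is None or self.T_f is None:
            raise ValueError("segment has no detected motion window")
        i0 = int(np.searchsorted(self.t, self.T_i))
        i1 = int(np.searchsorted(self.t, self.T_f, side="right"))
        return slice(i0, max(i1, i0 + 2))


@dataclass
class PerformanceReport:
    """The BiEval parameter set for one session (None = undefined/marked)."""

    subject_id: str = ""
    session_date: str = ""
    T_r_ms: Optional[float] = None
    T_m_s: Optional[float] = None
    omega_m_rad_s: Optional[float] = None
    omega_p_rad_s: Optional[float] = None
    N_p: Optional[float] = None
    J_n: Optional[float] = None
    theta_err_rms_deg: Optional[float] = None
    F_p_left_kgf: Optional[float] = None
    F_p_right_kgf: Optional[float] = None
    delta_F_kgf: Optional[float] = None
    tau_p_left_kgfcm: Optional[float] = None
    tau_p_right_kgfcm: Optional[float] = None
    tau_cp_left_kgfcm: Optional[float] = None
    tau_cp_right_kgfcm: Optional[float] = None
    tau_total_kgfcm: Optional[float] = None
    delta_tau_kgfcm: Optional[float] = None
    score: int = 0
    losses: int = 0
    n_segments_used: int = 0
    n_segments_discarded: int = 0


PARAMETER_FIELDS = [
    "T_r_ms", "T_m_s", "omega_m_rad_s", "omega_p_rad_s", "N_p", "J_n",
    "theta_err_rms_deg", "F_p_left_kgf", "F_p_right_kgf", "delta_F_kgf",
    "tau_p_left_kgfcm", "tau_p_right_kgfcm", "tau_cp_left_kgfcm",
    "tau_cp_right_kgfcm", "tau_total_kgfcm", "delta_tau_kgfcm",
    "score", "losses",
]


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

def kinematic_derivatives(
    theta: np.ndarray, dt: float, cfg: SegmentationConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed angular velocity, acceleration and jerk on the sample grid.

    Savitzky-Golay differentiation: a polynomial of order
    ``smoothing_polyorder`` is fit in a sliding window of
    ``smoothing_window_s`` seconds and its derivatives evaluated at the
    window centre.  Exact for polynomials up to the fit order.
    """
    cfg = cfg or SegmentationConfig()
    theta = np.asarray(theta, dtype=float)
    window = int(round(cfg.smoothing_window_s / dt))
    if window % 2 == 0:
        window += 1
    window = max(window, cfg.smoothing_polyorder + 2 + (cfg.smoothing_polyorder % 2))
    if theta.size < window:
        raise ValueError(
            f"series of {theta.size} samples shorter than the {window}-sample "
            "smoothing window"
        )
    omega = savgol_filter(theta, window, cfg.smoothing_polyorder, deriv=1, delta=dt)
    alpha = savgol_filter(theta, window, cfg.smoothing_polyorder, deriv=2, delta=dt)
    jerk = savgol_filter(theta, window, cfg.smoothing_polyorder, deriv=3, delta=dt)
    return omega, alpha, jerk


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _sustained(mask: np.ndarray, n: int) -> Optional[int]:
    """First index where ``mask`` holds for ``n`` consecutive samples."""
    if n <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None
    conv = np.convolve(mask.astype(int), np.ones(n, dtype=int), mode="valid")
    idx = np.flatnonzero(conv == n)
    return int(idx[0]) if idx.size else None


def _hold_baselines(
    omega: np.ndarray, F_left: np.ndarray, F_right: np.ndarray
) -> tuple[float, float]:
    """Per-side hold force: median force while the bar is (nearly) still."""
    wmax = float(np.max(np.abs(omega))) if omega.size else 0.0
    still = np.abs(omega) < 0.05 * wmax if wmax > 0 else np.ones_like(omega, bool)
    if not still.any():
        still = np.ones_like(omega, bool)
    return float(np.median(F_left[still])), float(np.median(F_right[still]))


def _position_tolerance(log: SessionLog, cfg: SegmentationConfig) -> float:
    if cfg.position_tolerance_rad is not None:
        return cfg.position_tolerance_rad
    meta = log.metadata
    try:
        return meta["controller"]["tolerance"] / meta["game"]["wagon_gain"]
    except (KeyError, TypeError):
        return math.radians(3.0)


def segment_movements(
    log: SessionLog, cfg: SegmentationConfig | None = None
) -> list[MovementSegment]:
    """One segment per target change (crystal spawn).

    ``T_i`` is the first sustained instant after ``T_0`` with productive
    torque and supra-threshold speed toward the target; ``T_d`` the first
    instant the target is reached within the position tolerance; ``T_f`` the
    first sustained sub-threshold-speed instant after ``T_d``.  Segments that
    never reach the target keep ``T_d = T_f = None`` and are excluded from
    time/speed statistics.
    """
    cfg = cfg or SegmentationConfig()
    t = log.samples["t_s"].to_numpy()
    theta = log.samples["theta_rad"].to_numpy()
    theta_d = log.samples["theta_d_rad"].to_numpy()
    fl = log.samples["F_left_kgf"].to_numpy()
    fr = log.samples["F_right_kgf"].to_numpy()
    dt = float(np.median(np.diff(t)))
    omega, _, jerk = kinematic_derivatives(theta, dt, cfg)
    base_l, base_r = _hold_baselines(omega, fl, fr)
    pos_tol = _position_tolerance(log, cfg)
    # smooth the torque sign signal with the same window as the derivatives
    window = int(round(cfg.smoothing_window_s / dt)) | 1
    torque_ccw = savgol_filter(
        (fl - base_l) - (fr - base_r), max(window, 5), min(cfg.smoothing_polyorder, 3)
    )

    spawns = [(ev[0], ev[2]) for ev in log.events if ev[1] == "spawn"]
    segments: list[MovementSegment] = []
    for k, (t0, _payload) in enumerate(spawns):
        t_end = spawns[k + 1][0] if k + 1 < len(spawns) else t[-1]
        i0 = int(np.searchsorted(t, t0))
        i1 = int(np.searchsorted(t, t_end, side="right"))
        if i1 - i0 < 4:
            continue
        sl = slice(i0, i1)
        th_d = theta_d[min(i1 - 1, i0 + 2)]  # target set at the spawn instant
        direction = 1 if th_d - theta[i0] >= 0 else -1

        w = omega[sl]
        peak = float(np.max(np.abs(w)))
        onset_thr = (
            cfg.onset_velocity_threshold
            if cfg.onset_velocity_threshold is not None
            else cfg.onset_velocity_fraction * peak
        )
        end_thr = (
            cfg.end_velocity_threshold
            if cfg.end_velocity_threshold is not None
            else cfg.end_velocity_fraction * peak
        )

        seg = MovementSegment(
            T_0=t0, T_i=None, T_d=None, T_f=None,
            direction=direction, theta_d=float(th_d),
            t=t[sl], theta=theta[sl], theta_d_series=theta_d[sl],
            omega=w, jerk=jerk[sl], F_left=fl[sl], F_right=fr[sl],
        )
        if peak > 0:
            productive = (direction * w > onset_thr) & (direction * torque_ccw[sl] > 0)
            j_on = _sustained(productive, cfg.sustain_samples)
            if j_on is not None:
                seg.T_i = float(seg.t[j_on])
        if seg.T_i is not None:
            reached = np.abs(seg.theta - th_d) <= pos_tol
            reached[: int(np.searchsorted(seg.t, seg.T_i))] = False
            j_d = np.flatnonzero(reached)
            if j_d.size:
                seg.T_d = float(seg.t[j_d[0]])
                slow = np.abs(w) < end_thr
                slow[: j_d[0]] = False
                j_f = _sustained(slow, cfg.sustain_samples)
                seg.T_f = float(seg.t[j_f]) if j_f is not None else float(seg.t[-1])
                seg.completed = True
        segments.append(seg)
    return segments


# ---------------------------------------------------------------------------
# Outlier validation
# ---------------------------------------------------------------------------

def validate_outliers(values: Sequence[float]) -> tuple[list[float], list[float]]:
    """Split values into (kept, discarded) by the 1.5*IQR fence.

    With fewer than 4 values no decision is meaningful and all are kept.
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        return vals, []
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = [v for v in vals if lo <= v <= hi]
    discarded = [v for v in vals if not lo <= v <= hi]
    return kept, discarded


def _validated_mean(values: Sequence[float]) -> tuple[Optional[float], int]:
    kept, discarded = validate_outliers(values)
    if not kept:
        return None, len(discarded)
    return float(np.mean(kept)), len(discarded)


# ---------------------------------------------------------------------------
# Per-segment parameters
# ---------------------------------------------------------------------------

def time_parameters(
    segments: Sequence[MovementSegment], validate: bool = True
) -> tuple[Optional[float], Optional[float]]:
    """Mean reaction time T_r = T_i - T_0 (s) and movement time T_m = T_f - T_i (s)."""
    tr = [s.T_i - s.T_0 for s in segments if s.has_onset]
    tm = [s.T_f - s.T_i for s in segments if s.completed]
    if not validate:
        return (
            float(np.mean(tr)) if tr else None,
            float(np.mean(tm)) if tm else None,
        )
    return _validated_mean(tr)[0], _validated_mean(tm)[0]


def speed_parameters(segment: MovementSegment) -> tuple[float, float]:
    """Mean and peak absolute angular velocity over [T_i, T_f] (rad/s)."""
    w = np.abs(segment.omega[segment.motion_slice()])
    return float(np.mean(w)), float(np.max(w))


def smoothness_parameters(
    segment: MovementSegment, cfg: SegmentationConfig | None = None
) -> tuple[float, int]:
    """Normalized jerk J_n (s^-2) and velocity-peak count N_p over [T_i, T_f].

    ``J_n = (1/omega_p) * (1/(T_f - T_i)) * integral |J(t)| dt``; N_p counts
    local speed maxima with prominence at least ``peak_prominence`` of the
    segment's peak speed (at least 1 for any segment with motion).
    """
    cfg = cfg or SegmentationConfig()
    sl = segment.motion_slice()
    w = np.abs(segment.omega[sl])
    jerk = segment.jerk[sl]
    tt = segment.t[sl]
    omega_p = float(np.max(w))
    if omega_p <= 0:
        raise ValueError("smoothness undefined: zero peak velocity")
    integrand = jerk if cfg.signed_jerk else np.abs(jerk)
    jn = float(np.trapezoid(integrand, tt) / (tt[-1] - tt[0]) / omega_p)
    peaks, _ = find_peaks(w, prominence=cfg.peak_prominence * omega_p)
    return jn, max(int(peaks.size), 1)


def error_parameter(segment: MovementSegment) -> float:
    """RMS of the position error theta - theta_d over [T_i, T_f] (rad)."""
    sl = segment.motion_slice()
    err = segment.theta[sl] - segment.theta_d_series[sl]
    return float(np.sqrt(np.mean(err**2)))


# ---------------------------------------------------------------------------
# Session-level force and torque parameters
# ---------------------------------------------------------------------------

def force_parameters(
    log: SessionLog, cfg: SegmentationConfig | None = None
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Mean peak force per side and their asymmetry dF = F_p,left - F_p,right.

    Peaks are local maxima of each force series with prominence at least
    ``force_peak_prominence`` kgf; dF is positive when the left peaks are
    higher, negative otherwise, None when a side has no detectable peaks.
    """
    cfg = cfg or SegmentationConfig()
    out = []
    for col in ("F_left_kgf", "F_right_kgf"):
        f = log.samples[col].to_numpy()
        peaks, props = find_peaks(f, prominence=cfg.force_peak_prominence)
        out.append(float(np.mean(f[peaks])) if peaks.size else None)
    fp_l, fp_r = out
    delta = fp_l - fp_r if fp_l is not None and fp_r is not None else None
    return fp_l, fp_r, delta


def torque_parameters(
    log: SessionLog,
    segments: Sequence[MovementSegment],
    geom: RobotGeometry | None = None,
) -> dict[str, Optional[float]]:
    """Productive/counterproductive torque per side, total and asymmetry.

    Each side's torque contribution is its force deviation from the hold
    baseline times the handlebar half-width (kgf*cm), signed by the rotation
    it induces (left press turns the bar counterclockwise).  Within each
    movement window a side is *productive* when its torque sign matches the
    target direction; the total torque of a sample counts as productive only
    when both sides are.  ``delta_tau`` is positive when the left productive
    torque is higher.
    """
    geom = geom or RobotGeometry()
    lever_cm = geom.handlebar_width_Wg / 2.0 * 100.0
    omega_all = None
    fl = log.samples["F_left_kgf"].to_numpy()
    fr = log.samples["F_right_kgf"].to_numpy()
    t = log.samples["t_s"].to_numpy()
    dt = float(np.median(np.diff(t)))
    omega_all, _, _ = kinematic_derivatives(
        log.samples["theta_rad"].to_numpy(), dt
    )
    base_l, base_r = _hold_baselines(omega_all, fl, fr)

    p_l, p_r, cp_l, cp_r, totals = [], [], [], [], []
    for seg in segments:
        if not seg.has_onset or seg.T_f is None:
            continue
        sl = seg.motion_slice()
        tau_l = (seg.F_left[sl] - base_l) * lever_cm        # + = CCW
        tau_r = -(seg.F_right[sl] - base_r) * lever_cm      # press right = CW
        d = seg.direction
        prod_l, prod_r = tau_l * d > 0, tau_r * d > 0
        if prod_l.any():
            p_l.append(float(np.mean(np.abs(tau_l[prod_l]))))
        if prod_r.any():
            p_r.append(float(np.mean(np.abs(tau_r[prod_r]))))
        if (~prod_l).any():
            cp_l.append(float(np.mean(np.abs(tau_l[~prod_l]))))
        if (~prod_r).any():
            cp_r.append(float(np.mean(np.abs(tau_r[~prod_r]))))
        total = np.abs(tau_l + tau_r)
        total_signed = np.where(prod_l & prod_r, total, -total)
        totals.append(float(np.mean(total_signed)))

    def vmean(vals: list) -> Optional[float]:
        return _validated_mean(vals)[0] if vals else None

    tau_p_left, tau_p_right = vmean(p_l), vmean(p_r)
    return {
        "tau_p_left": tau_p_left,
        "tau_p_right": tau_p_right,
        "tau_cp_left": vmean(cp_l),
        "tau_cp_right": vmean(cp_r),
        "tau_total": vmean(totals),
        "delta_tau": (
            tau_p_left - tau_p_right
            if tau_p_left is not None and tau_p_right is not None
            else None
        ),
    }


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def session_report(
    log: SessionLog,
    cfg: SegmentationConfig | None = None,
    geom: RobotGeometry | None = None,
) -> PerformanceReport:
    """Compute the full BiEval parameter set for one session.

    Per-segment parameters pass through 1.5*IQR outlier validation before
    averaging; segments without detectable motion are marked, not raised, and
    a segment discarded by *any* parameter's fence counts once in
    ``n_segments_discarded``.
    """
    cfg = cfg or SegmentationConfig()
    segments = segment_movements(log, cfg)
    rep = PerformanceReport(
        subject_id=str(log.metadata.get("subject_id", "")),
        session_date=str(log.metadata.get("session_date", "")),
    )
    rep.score = sum(1 for e in log.events if e[1] == "caught")
    rep.losses = sum(1 for e in log.events if e[1] == "lost")

    complete = [s for s in segments if s.completed]
    onset = [s for s in segments if s.has_onset]
    rep.n_segments_used = len(complete)

    discarded = 0
    tr = [s.T_i - s.T_0 for s in onset]
    tm = [s.T_f - s.T_i for s in complete]
    v, d = _validated_mean(tr)
    rep.T_r_ms = v * 1e3 if v is not None else None
    discarded = max(discarded, d)
    v, d = _validated_mean(tm)
    rep.T_m_s = v
    discarded = max(discarded, d)

    if complete:
        wm, wp, jn, npk, err = [], [], [], [], []
        for s in complete:
            m, p = speed_parameters(s)
            wm.append(m)
            wp.append(p)
            j, k = smoothness_parameters(s, cfg)
            jn.append(j)
            npk.append(k)
            err.append(error_parameter(s))
        for attr, vals, scale in (
            ("omega_m_rad_s", wm, 1.0),
            ("omega_p_rad_s", wp, 1.0),
            ("J_n", jn, 1.0),
            ("N_p", npk, 1.0),
            ("theta_err_rms_deg", err, 180.0 / math.pi),
        ):
            v, d = _validated_mean(vals)
            setattr(rep, attr, v * scale if v is not None else None)
            discarded = max(discarded, d)

    rep.F_p_left_kgf, rep.F_p_right_kgf, rep.delta_F_kgf = force_parameters(log, cfg)
    taus = torque_parameters(log, segments, geom)
    rep.tau_p_left_kgfcm = taus["tau_p_left"]
    rep.tau_p_right_kgfcm = taus["tau_p_right"]
    rep.tau_cp_left_kgfcm = taus["tau_cp_left"]
    rep.tau_cp_right_kgfcm = taus["tau_cp_right"]
    rep.tau_total_kgfcm = taus["tau_total"]
    rep.delta_tau_kgfcm = taus["delta_tau"]
    rep.n_segments_discarded = discarded
    return rep


def report_to_json(report: PerformanceReport, path=None) -> str:
    """Serialize a report as JSON (written to ``path`` when given)."""
    text = json.dumps(asdict(report), indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def report_from_json(path) -> PerformanceReport:
    with open(path) as fh:
        return PerformanceReport(**json.load(fh))


def report_csv_row(reports: Sequence[PerformanceReport], path=None) -> pd.DataFrame:
    """Flatten reports to one CSV row per session for longitudinal tooling."""
    df = pd.DataFrame([asdict(r) for r in reports])
    if path is not None:
        df.to_csv(path, index=False)
    return df
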