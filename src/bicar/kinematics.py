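"""Cable kinematics for the three device setups.

The robot is a planar cable-driven structure: two cables leave fixed anchor
points ``A`` and ``B`` on a frame of width ``Wb`` and suspend either a single
handle (1-DOF / 2-DOF unilateral setups) or a rigid handlebar of width ``Wg``
(bimanual setup).

Coordinate convention (used everywhere in this package):

* origin at the midpoint of the anchor line A--B,
* x to the right, y measured **downward** from the anchor line, so any taut
  position has ``yp > 0``,
* handlebar rotation ``theta`` is positive **counterclockwise as seen by the
  user** facing the device; equivalently, positive theta lowers the *left*
  handlebar tip (lengthening the left cable ``L1``) and raises the right one.
  Clockwise rotation (negative theta) therefore shortens ``L1`` and lengthens
  ``L2``, matching the device's "left cable shorter => bar rotates clockwise"
  behaviour.

All lengths are metres and all angles radians unless a function says
otherwise.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "RobotGeometry",
    "PlanarPoint",
    "CableLengths",
    "TrajectorySpec",
    "HandlebarState",
    "InvalidPositionError",
    "InvalidOrientationError",
    "InconsistentLengthsError",
    "WorkspaceError",
    "cable_length_1dof",
    "planar_cable_lengths",
    "trajectory_points",
    "trajectory_cable_lengths",
    "interpolate_trajectory",
    "bimanual_cable_lengths",
    "handlebar_orientation",
    "theta_max",
    "published_model_discrepancy",
    "export_trajectory_csv",
]


class InvalidPositionError(ValueError):
    """Commanded position would slacken a cable or leave the workspace."""


class InvalidOrientationError(ValueError):
    """Handlebar pose outside the reachable orientation range."""


class InconsistentLengthsError(ValueError):
    """Cable-length pair incompatible with the geometry (arccos out of range)."""


class WorkspaceError(ValueError):
    """A generated trajectory point violates the workspace. Carries the index."""

    def __init__(self, index: int, message: str):
        super().__init__(f"trajectory point {index}: {message}")
        self.index = index


@dataclass(frozen=True)
class RobotGeometry:
    """Fixed-frame geometry.

    Parameters
    ----------
    frame_width_Wb:
        Distance between the two cable anchor points A and B (m).
    handlebar_width_Wg:
        Width of the handlebar between its two cable attachment points (m).
        Must be smaller than the frame width so the cables splay outward.
    """

    frame_width_Wb: float = 1.0
    handlebar_width_Wg: float = 0.5

    def __post_init__(self) -> None:
        if self.frame_width_Wb <= 0:
            raise ValueError("frame width Wb must be positive")
        if self.handlebar_width_Wg <= 0:
            raise ValueError("handlebar width Wg must be positive")
        if self.handlebar_width_Wg >= self.frame_width_Wb:
            raise ValueError("handlebar width Wg must be smaller than frame width Wb")

    @property
    def anchor_A(self) -> tuple[float, float]:
        """Left anchor, frame coordinates."""
        return (-self.frame_width_Wb / 2.0, 0.0)

    @property
    def anchor_B(self) -> tuple[float, float]:
        """Right anchor, frame coordinates."""
        return (self.frame_width_Wb / 2.0, 0.0)


@dataclass(frozen=True)
class PlanarPoint:
    """A commanded end-effector position; ``yp`` is the drop below the anchors."""

    xp: float
    yp: float
    zp: float = 0.0

    def validate(self) -> None:
        if self.yp <= 0:
            raise InvalidPositionError(
                f"yp = {self.yp} must be > 0 (cables must stay taut below the anchors)"
            )


@dataclass(frozen=True)
class CableLengths:
    """Lengths of the left (L1) and right (L2) cables, metres."""

    L1: float
    L2: float

    def __post_init__(self) -> None:
        if self.L1 <= 0 or self.L2 <= 0:
            raise ValueError("cable lengths must be strictly positive")


@dataclass(frozen=True)
class TrajectorySpec:
    """A discretized circular/polygonal trajectory.

    ``n_points_N`` vertices on a circle of diameter ``diameter_a`` centred at
    ``center``; ``n_points_N`` of 3, 4 or 5 gives a triangle, quadrilateral or
    pentagon. ``rotation_alpha`` rotates the whole polygon.
    """

    center: PlanarPoint
    diameter_a: float
    n_points_N: int
    rotation_alpha: float = 0.0
    interpolate: bool = False

    def __post_init__(self) -> None:
        if self.diameter_a < 0:
            raise ValueError("diameter a must be non-negative")
        if self.n_points_N < 2:
            raise ValueError("need at least 2 discretization points")


@dataclass(frozen=True)
class HandlebarState:
    """Handlebar pose for the bimanual setup: drop ``h`` and rotation ``theta``."""

    height_h: float
    angle_theta: float = 0.0

    def __post_init__(self) -> None:
        if self.height_h <= 0:
            raise ValueError("handlebar drop h must be positive")


# ---------------------------------------------------------------------------
# Setup I: single cable, pure vertical translation
# ---------------------------------------------------------------------------

def cable_length_1dof(point: PlanarPoint) -> float:
    """Cable length for the 1-DOF setup: the cable length equals the drop."""
    point.validate()
    return point.yp


# ---------------------------------------------------------------------------
# Setup II: two cables, planar translation
# ---------------------------------------------------------------------------

def planar_cable_lengths(
    point: PlanarPoint,
    geom: RobotGeometry,
    formula: Literal["euclidean", "published"] = "euclidean",
) -> CableLengths:
    """Cable lengths that place the handle at ``point`` in the planar setup.

    The two taut cables form a triangle with the frame, so each length is the
    Euclidean distance from its anchor to the commanded point.  The
    ``published`` formula is the trigonometric closed form
    ``L = yp / sin(atan(yp / (xp +/- Wb/2)))``, which agrees with the distance
    form everywhere it is defined but is singular when the point sits directly
    under an anchor (``xp = -/+ Wb/2``).
    """
    point.validate()
    ax, _ = geom.anchor_A
    bx, _ = geom.anchor_B
    if formula == "euclidean":
        L1 = math.hypot(point.xp - ax, point.yp)
        L2 = math.hypot(point.xp - bx, point.yp)
    elif formula == "published":
        for name, anchor_x in (("A", ax), ("B", bx)):
            if point.xp == anchor_x:
                raise InvalidPositionError(
                    f"point directly under anchor {name}: arctangent form undefined"
                )
        L1 = point.yp / math.sin(math.atan2(point.yp, point.xp - ax))
        L2 = point.yp / math.sin(math.atan2(point.yp, point.xp - bx))
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown formula {formula!r}")
    return CableLengths(L1, L2)


def trajectory_points(spec: TrajectorySpec, geom: RobotGeometry | None = None) -> list[PlanarPoint]:
    """Vertices of the discretized circular/polygonal trajectory.

    Vertex ``i`` (for ``i = 1..N``) sits at angle ``theta_i = i*2*pi/N + alpha``
    on the circle of diameter ``a`` centred at the trajectory centre.  When a
    geometry is supplied every vertex is workspace-checked and the offending
    index reported on failure.
    """
    pts: list[PlanarPoint] = []
    half = spec.diameter_a / 2.0
    for i in range(1, spec.n_points_N + 1):
        th = i * 2.0 * math.pi / spec.n_points_N + spec.rotation_alpha
        p = PlanarPoint(
            xp=spec.center.xp + half * math.cos(th),
            yp=spec.center.yp + half * math.sin(th),
            zp=spec.center.zp,
        )
        try:
            p.validate()
            if geom is not None and abs(p.xp) >= geom.frame_width_Wb / 2.0:
                raise InvalidPositionError(
                    f"|xp| = {abs(p.xp):.4f} outside the inter-anchor span"
                )
        except InvalidPositionError as exc:
            raise WorkspaceError(i, str(exc)) from exc
        pts.append(p)
    return pts


def interpolate_trajectory(
    points: Sequence[PlanarPoint], per_segment: int = 20
) -> list[PlanarPoint]:
    """Densify a closed polygon of trajectory points with a periodic cubic spline.

    ``per_segment`` interpolated points are produced for each polygon edge;
    the original vertices are retained exactly (they are the spline knots).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for periodic spline interpolation")
    n = len(points)
    xs = np.array([p.xp for p in points] + [points[0].xp])
    ys = np.array([p.yp for p in points] + [points[0].yp])
    u = np.arange(n + 1, dtype=float)
    sx = CubicSpline(u, xs, bc_type="periodic")
    sy = CubicSpline(u, ys, bc_type="periodic")
    dense_u = np.linspace(0.0, n, n * per_segment, endpoint=False)
    zp = points[0].zp
    return [PlanarPoint(float(sx(t)), float(sy(t)), zp) for t in dense_u]


def trajectory_cable_lengths(
    spec: TrajectorySpec, geom: RobotGeometry
) -> list[CableLengths]:
    """Cable-length pairs for each trajectory vertex (composition of the above)."""
    pts = trajectory_points(spec, geom)
    if spec.interpolate:
        pts = interpolate_trajectory(pts)
    return [planar_cable_lengths(p, geom) for p in pts]


# ---------------------------------------------------------------------------
# Setup III: bimanual handlebar (drop h, rotation theta)
# ---------------------------------------------------------------------------

def _handlebar_endpoints(
    state: HandlebarState, geom: RobotGeometry
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Left and right cable attachment points of the handlebar (frame coords)."""
    r = geom.handlebar_width_Wg / 2.0
    c, s = math.cos(state.angle_theta), math.sin(state.angle_theta)
    left = (-r * c, state.height_h + r * s)
    right = (r * c, state.height_h - r * s)
    return left, right


def theta_max(h: float, geom: RobotGeometry) -> float:
    """Largest |theta| with both cables taut and lengths monotone in theta.

    Bounded by the angle at which a handlebar tip would reach the anchor line
    (``asin(h / (Wg/2))`` when the half-width exceeds the drop) and by the
    geometric monotonicity limit ``atan(h / (Wb/2))``.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    r = geom.handlebar_width_Wg / 2.0
    lim = math.atan2(h, geom.frame_width_Wb / 2.0)
    if r > h:
        lim = min(lim, math.asin(h / r))
    return lim


def bimanual_cable_lengths(
    state: HandlebarState,
    geom: RobotGeometry,
    formula: Literal["geometric", "published"] = "geometric",
) -> CableLengths:
    """Cable lengths for handlebar drop ``h`` and rotation ``theta``.

    The default ``geometric`` model measures each cable as the distance from
    its anchor to the corresponding handlebar tip.  In closed form, with
    ``d = hypot(Wb/2, h)``, ``r = Wg/2`` and ``beta = atan2(h, Wb/2)``::

        L1^2 = d^2 + r^2 - 2 r d cos(theta + beta)
        L2^2 = d^2 + r^2 - 2 r d cos(theta - beta)

    The ``published`` variant implements the device paper's printed closed
    form verbatim; it differs from the geometric model by a constant
    ``Wg^2/4`` inside the square root (see :func:`published_model_discrepancy`).
    """
    tmax = theta_max(state.height_h, geom)
    if abs(state.angle_theta) > tmax:
        raise InvalidOrientationError(
            f"|theta| = {abs(state.angle_theta):.4f} rad exceeds theta_max = {tmax:.4f} rad"
        )
    if formula == "geometric":
        (lx, ly), (rx, ry) = _handlebar_endpoints(state, geom)
        ax, _ = geom.anchor_A
        bx, _ = geom.anchor_B
        L1 = math.hypot(lx - ax, ly)
        L2 = math.hypot(rx - bx, ry)
        return CableLengths(L1, L2)
    if formula == "published":
        wb2 = geom.frame_width_Wb / 2.0
        wg = geom.handlebar_width_Wg
        h = state.height_h
        d = math.hypot(wb2, h)
        beta = math.atan2(wb2, h)  # measured from vertical, as printed
        out = []
        for sign in (+1.0, -1.0):
            arg = math.pi / 2.0 + sign * state.angle_theta - beta
            sq = d * d + wg * (wg / 2.0 - d * math.cos(arg))
            if sq <= 0:
                raise InvalidOrientationError("published closed form: negative radicand")
            out.append(math.sqrt(sq))
        return CableLengths(out[0], out[1])
    raise ValueError(f"unknown formula {formula!r}")  # pragma: no cover


def handlebar_orientation(
    lengths: CableLengths,
    h: float,
    geom: RobotGeometry,
    formula: Literal["geometric", "published"] = "geometric",
) -> float:
    """Handlebar rotation recovered from the two measured cable lengths.

    Inverts the geometric model by the law of cosines: each length fixes the
    angle ``psi_j`` between the handlebar half pointing at tip ``j`` and the
    line from the bar centre to the corresponding anchor, and
    ``theta = (psi1 - psi2) / 2``.  Equal lengths give ``theta = 0``; swapping
    the lengths flips the sign.

    The ``published`` variant evaluates the printed inverse (a plain
    difference of the two arccos terms, with the matching ``2*Wg^2``
    constant); composed with the printed forward model it returns ``2*theta``.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    d = math.hypot(geom.frame_width_Wb / 2.0, h)
    if formula == "geometric":
        r = geom.handlebar_width_Wg / 2.0
        psis = []
        for L in (lengths.L1, lengths.L2):
            cosv = (d * d + r * r - L * L) / (2.0 * r * d)
            if not -1.0 <= cosv <= 1.0:
                raise InconsistentLengthsError(
                    f"length {L} incompatible with geometry (cos = {cosv:.6f})"
                )
            psis.append(math.acos(cosv))
        return (psis[0] - psis[1]) / 2.0
    if formula == "published":
        wb = geom.frame_width_Wb
        wg = geom.handlebar_width_Wg
        terms = []
        for L in (lengths.L1, lengths.L2):
            num = -4.0 * L * L + wb * wb + 2.0 * wg * wg + 4.0 * h * h
            den = 4.0 * wg * math.sqrt(wb * wb / 4.0 + h * h)
            cosv = num / den
            if not -1.0 <= cosv <= 1.0:
                raise InconsistentLengthsError(
                    f"length {L} incompatible with geometry (cos = {cosv:.6f})"
                )
            terms.append(math.acos(cosv))
        return terms[0] - terms[1]
    raise ValueError(f"unknown formula {formula!r}")  # pragma: no cover


def published_model_discrepancy(
    h: float, theta: float, geom: RobotGeometry
) -> dict[str, float]:
    """Quantify how the printed bimanual closed forms differ from geometry.

    Returns the squared-length offset of the printed forward model (a constant
    ``Wg^2/4``), the resulting length differences, and the angle returned by
    the printed inverse applied to the printed forward lengths (which comes
    out as ``2*theta``: the printed inverse omits the factor 1/2 relating the
    difference of the two anchor angles to the bar rotation).
    """
    state = HandlebarState(h, theta)
    geo = bimanual_cable_lengths(state, geom, formula="geometric")
    pub = bimanual_cable_lengths(state, geom, formula="published")
    theta_pub = handlebar_orientation(pub, h, geom, formula="published")
    return {
        "L1_geometric": geo.L1,
        "L1_published": pub.L1,
        "L2_geometric": geo.L2,
        "L2_published": pub.L2,
        "squared_length_offset": pub.L1**2 - geo.L1**2,
        "expected_offset_Wg2_over_4": geom.handlebar_width_Wg**2 / 4.0,
        "published_roundtrip_theta": theta_pub,
        "published_roundtrip_ratio": theta_pub / theta if theta != 0 else float("nan"),
    }


def export_trajectory_csv(
    path, spec: TrajectorySpec, geom: RobotGeometry
) -> None:
    """Write (index, x_m, y_m, L1_m, L2_m) rows for a trajectory."""
    pts = trajectory_points(spec, geom)
    if spec.interpolate:
        pts = interpolate_trajectory(pts)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "x_m", "y_m", "L1_m", "L2_m"])
        for i, p in enumerate(pts):
            L = planar_cable_lengths(p, geom)
            w.writerow([i, f"{p.xp:.9f}", f"{p.yp:.9f}", f"{L.L1:.9f}", f"{L.L2:.9f}"])
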