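"""Force-map controller and MineCart/Sakura game mechanics.

The bimanual games are driven by a *force map*: the two load cells measure the
downward force each arm applies to the handlebar, and the controller
classifies every sample into an intent.  To rotate, the force on one side must
exceed the other by a threshold ``delta_F`` while the opposite arm *lifts*
(its force stays below ``F_rot``); pressing too hard on one side
(above ``F_max``) triggers an over-force warning instead of motion.  Pressing
or lifting with both arms together translates the bar down or up.

The MineCart game maps handlebar rotation to a wagon that catches crystals
falling from the ceiling; Sakura Flowers is the same mechanic with a smaller
capture tolerance.  Assistance is assist-as-needed: the balance of the last
five object outcomes raises or lowers the assistance level, which first
shrinks the rotation threshold, then drifts the bar toward the target, and at
the top level performs the movement by itself.  Negative levels are resistive
(a larger threshold, i.e. a "heavier" bar).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Deque, Iterable, Optional
from collections import deque

import numpy as np

__all__ = [
    "GameMode",
    "Intent",
    "ControllerConfig",
    "GameConfig",
    "ForceSample",
    "GameState",
    "classify_intent",
    "effective_threshold",
    "update_assistance",
    "step_game",
    "minecart_config",
    "sakura_config",
]


class GameMode(str, enum.Enum):
    CONSTANT = "constant"       # crystals always at the same speed
    ACCELERATED = "accelerated"  # fall speed +10% every 10 points
    DYNAMIC = "dynamic"          # resistive assistance grows with the score


class Intent(str, enum.Enum):
    CW = "CW"
    CCW = "CCW"
    RAISE = "RAISE"
    LOWER = "LOWER"
    HOLD = "HOLD"
    OVERFORCE = "OVERFORCE"


@dataclass(frozen=True)
class ControllerConfig:
    """Force-map thresholds, capture tolerance and assistance settings.

    Forces in kgf.  ``tolerance`` is the capture half-window in game units
    (the wagon half-width relative to the crystal).  ``assist_level`` is the
    current level in ``[-A_max, +A_max]``; negative levels are resistive.
    """

    delta_F: float = 0.5
    F_rot: float = 2.0
    F_max: float = 6.0
    tolerance: float = 0.10
    assist_level: int = 0
    mode: GameMode = GameMode.CONSTANT
    # Fig.-7-style translation regions (axes unlabeled in the source figure;
    # defaults keep the ~1.5 kgf/side resting hold inside HOLD).
    raise_threshold: float = 1.0
    lower_threshold: float = 4.0
    # assist-as-needed adaptation on the balance of the last five outcomes
    A_max: int = 3
    assist_trigger: int = -1   # balance <= trigger: raise assistance
    assist_release: int = 3    # balance >= release: lower assistance
    auto_assist: bool = True
    # factor applied to delta_F per assistance level (0.5**level for level>0)
    assist_threshold_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.delta_F <= 0:
            raise ValueError("delta_F must be positive")
        if not 0 < self.F_rot < self.F_max:
            raise ValueError("need 0 < F_rot < F_max")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if abs(self.assist_level) > self.A_max:
            raise ValueError("assist_level outside [-A_max, A_max]")


@dataclass(frozen=True)
class GameConfig:
    """Playfield geometry and timing shared by MineCart and Sakura.

    Game x runs over ``[-halfwidth, +halfwidth]``; the wagon tracks the
    handlebar angle linearly with ``wagon_gain`` (full width over +/-30 deg by
    default).  A crystal spawned at height ``fall_height`` reaches the wagon
    plane after ``fall_height / fall_speed`` seconds.
    """

    halfwidth: float = 1.0
    fall_height: float = 1.0
    fall_speed: float = 1.0 / 7.0
    wagon_gain: float = 1.0 / math.radians(30.0)
    spawn_gap: float = 0.5            # pause between resolution and next spawn, s
    min_spawn_distance: float = 0.8   # new crystal at least this far from the last one
    accel_factor: float = 1.10        # accelerated mode: speed multiplier per 10 points
    accel_points: int = 10
    dynamic_points_per_level: int = 20

    # Handlebar rotation is positive counterclockwise (kinematics convention)
    # and clockwise rotation moves the wagon right, hence the sign flip.
    def x_from_theta(self, theta: float) -> float:
        return -theta * self.wagon_gain

    def theta_from_x(self, x: float) -> float:
        return -x / self.wagon_gain


@dataclass(frozen=True)
class ForceSample:
    """One load-cell sample: time and per-arm forces (kgf, non-negative)."""

    t: float
    F_left: float
    F_right: float


@dataclass
class GameState:
    """Mutable state of one MineCart/Sakura run."""

    wagon_x: float = 0.0
    crystal_x: float = 0.0
    crystal_y: float = 1.0
    fall_speed: float = 1.0 / 7.0
    score: int = 0
    losses: int = 0
    outcome_window: Deque[bool] = field(default_factory=lambda: deque(maxlen=5))
    assist_level: int = 0
    crystal_active: bool = False
    respawn_timer: float = 0.0
    events: list = field(default_factory=list)  # (t, kind, payload) tuples
    t: float = 0.0

    @property
    def resolved(self) -> int:
        return self.score + self.losses

    def balance_last5(self) -> int:
        """Caught minus lost over the (at most five) most recent outcomes."""
        return sum(1 if c else -1 for c in self.outcome_window)


def effective_threshold(cfg: ControllerConfig) -> float:
    """Rotation threshold after assistance scaling.

    Positive levels shrink ``delta_F`` geometrically (easier rotation),
    negative levels grow it (resistive, "heavier" bar); level 0 is identity.
    """
    return cfg.delta_F * cfg.assist_threshold_factor ** cfg.assist_level


def classify_intent(sample: ForceSample, cfg: ControllerConfig) -> Intent:
    """Map one force sample to an intent via the force map.

    Priority: over-force warning, then rotation (differential above the
    effective threshold with the lifting arm below ``F_rot``), then the
    two-arm translation regions, then HOLD.
    """
    if sample.F_left < 0 or sample.F_right < 0:
        raise ValueError("forces must be non-negative (load cells measure tension)")
    if sample.F_left > cfg.F_max or sample.F_right > cfg.F_max:
        return Intent.OVERFORCE
    thr = effective_threshold(cfg)
    diff = sample.F_right - sample.F_left
    if diff > thr and sample.F_left < cfg.F_rot:
        return Intent.CW
    if -diff > thr and sample.F_right < cfg.F_rot:
        return Intent.CCW
    if sample.F_left < cfg.raise_threshold and sample.F_right < cfg.raise_threshold:
        return Intent.RAISE
    if sample.F_left > cfg.lower_threshold and sample.F_right > cfg.lower_threshold:
        return Intent.LOWER
    return Intent.HOLD


def update_assistance(state: GameState, cfg: ControllerConfig) -> int:
    """Assist-as-needed update, called after each object resolves.

    The balance of the last five outcomes (caught minus lost) raises the level
    one step when it drops to ``assist_trigger`` or below, and lowers it one
    step (not below 0 - resistive levels are a deliberate therapist or
    dynamic-mode choice) when it reaches ``assist_release`` or above.  The
    result is clamped to ``[-A_max, +A_max]``.
    """
    level = state.assist_level
    bal = state.balance_last5()
    if bal <= cfg.assist_trigger:
        level += 1
    elif bal >= cfg.assist_release and level > 0:
        level -= 1
    return int(np.clip(level, -cfg.A_max, cfg.A_max))


def _spawn_crystal(state: GameState, game: GameConfig, rng: np.random.Generator) -> None:
    lo, hi = -game.halfwidth, game.halfwidth
    d = game.min_spawn_distance
    # Uniform over the playfield excluding a window around the previous
    # crystal.  Exactly one draw per spawn and no dependence on the player's
    # state, so a seed fully determines the crystal sequence.
    prev = state.crystal_x
    left_span = max(0.0, (prev - d) - lo)
    right_span = max(0.0, hi - (prev + d))
    if left_span + right_span <= 0:
        x = rng.uniform(lo, hi)
    else:
        u = rng.uniform(0.0, left_span + right_span)
        x = lo + u if u < left_span else (prev + d) + (u - left_span)
    state.crystal_x = float(x)
    state.crystal_y = game.fall_height
    state.crystal_active = True
    state.events.append((state.t, "spawn", {"crystal_x": state.crystal_x}))


def _resolve_crystal(
    state: GameState, cfg: ControllerConfig, game: GameConfig
) -> None:
    caught = abs(state.wagon_x - state.crystal_x) <= cfg.tolerance
    if caught:
        state.score += 1
        state.events.append((state.t, "caught", {"score": state.score}))
        if (
            cfg.mode is GameMode.ACCELERATED
            and state.score % game.accel_points == 0
        ):
            state.fall_speed *= game.accel_factor
        if cfg.mode is GameMode.DYNAMIC:
            state.assist_level = int(
                np.clip(-(state.score // game.dynamic_points_per_level), -cfg.A_max, 0)
            )
    else:
        state.losses += 1
        state.events.append((state.t, "lost", {"losses": state.losses}))
    state.outcome_window.append(caught)
    if cfg.auto_assist and cfg.mode is not GameMode.DYNAMIC:
        new_level = update_assistance(state, cfg)
        if new_level != state.assist_level:
            state.assist_level = new_level
            state.events.append((state.t, "assist_change", {"level": new_level}))
    state.crystal_active = False
    state.respawn_timer = game.spawn_gap


def step_game(
    state: GameState,
    intent: Intent,
    dt: float,
    cfg: ControllerConfig,
    game: GameConfig,
    rng: np.random.Generator,
    wagon_speed: float = 0.6,
    theta: Optional[float] = None,
) -> GameState:
    """Advance the game by ``dt`` seconds (mutates and returns ``state``).

    When a handlebar angle ``theta`` is given the wagon tracks it through
    ``wagon_gain`` (the normal closed-loop path); otherwise the wagon moves at
    ``wagon_speed`` in the intent direction (CW = right).  The active crystal
    falls by ``fall_speed * dt``; on reaching the wagon plane it is caught iff
    it lies within the capture tolerance (boundary inclusive), else lost, and
    a new crystal spawns after a short gap.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.t += dt
    if theta is not None:
        state.wagon_x = float(
            np.clip(game.x_from_theta(theta), -game.halfwidth, game.halfwidth)
        )
    elif intent is Intent.CW:
        state.wagon_x = min(game.halfwidth, state.wagon_x + wagon_speed * dt)
    elif intent is Intent.CCW:
        state.wagon_x = max(-game.halfwidth, state.wagon_x - wagon_speed * dt)
    if state.crystal_active:
        state.crystal_y -= state.fall_speed * dt
        if state.crystal_y <= 0.0:
            _resolve_crystal(state, cfg, game)
    else:
        state.respawn_timer -= dt
        if state.respawn_timer <= 0.0:
            _spawn_crystal(state, game, rng)
    return state


def minecart_config(**overrides) -> ControllerConfig:
    """Default MineCart controller configuration."""
    return replace(ControllerConfig(), **overrides) if overrides else ControllerConfig()


def sakura_config(**overrides) -> ControllerConfig:
    """Sakura Flowers: identical mechanics, considerably smaller capture tolerance."""
    base = ControllerConfig(tolerance=0.04)
    return replace(base, **overrides) if overrides else base
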