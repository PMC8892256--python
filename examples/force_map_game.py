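"""The force map and the MineCart assist-as-needed loop, sample by sample.

Classifies a few hand-force samples into intents, then lets a scripted
"perfect player" play accelerated-mode MineCart and prints how the fall
speed steps up by exactly 10% at every 10th point.
"""

import numpy as np

from bicar.game import (
    ControllerConfig,
    ForceSample,
    GameConfig,
    GameMode,
    GameState,
    Intent,
    classify_intent,
    minecart_config,
    step_game,
)

cfg = ControllerConfig()  # delta_F=0.5 kgf, F_rot=2.0 kgf, F_max=6.0 kgf
print("Force-map classification (forces in kgf):")
for fl, fr in [(1.5, 1.5), (1.2, 2.4), (2.4, 1.2), (0.4, 0.5), (1.0, 6.5)]:
    intent = classify_intent(ForceSample(0.0, fl, fr), cfg)
    print(f"  F_left={fl:4.1f}  F_right={fr:4.1f}  ->  {intent.value}")
# CW needs the right side to exceed the left by delta_F while the left lifts;
# exceeding F_max on either side only triggers a warning.

game = GameConfig(fall_speed=1.0, spawn_gap=0.1)
accel = minecart_config(mode=GameMode.ACCELERATED)
rng = np.random.default_rng(0)
state = GameState(fall_speed=game.fall_speed)
print("\nAccelerated MineCart with a perfect player:")
last = 0
while state.score < 25:
    step_game(state, Intent.HOLD, 1 / 80, accel, game, rng,
              theta=game.theta_from_x(state.crystal_x))
    if state.score // 10 != last // 10:
        print(f"  score {state.score:3d}: fall speed -> {state.fall_speed:.3f} "
              f"(= 1.1^{state.score // 10})")
    last = state.score
print(f"  final: score={state.score}, losses={state.losses} (perfect play loses nothing)")
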