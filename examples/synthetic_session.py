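"""Generate synthetic game sessions for a healthy and a hemiparetic subject.

Simulates five minutes of MineCart for each profile with the same seed and
prints score, losses and the recorded force asymmetry.  The hemiparetic
subject reacts later, moves slower, fragments the movement and loads the
nonparetic arm more - exactly the structure the evaluator is meant to detect.
"""

from bicar.game import ControllerConfig
from bicar.simulate import healthy_profile, post_stroke_profile, simulate_session

for name, profile in [
    ("healthy", healthy_profile()),
    ("post-stroke (left hemiparesis)", post_stroke_profile("left", severity=0.4)),
]:
    log = simulate_session(profile, ControllerConfig(), duration=300.0, seed=7)
    fl = log.samples["F_left_kgf"]
    fr = log.samples["F_right_kgf"]
    n_sub = sum(t["n_submovements"] for t in log.truth) / len(log.truth)
    print(f"{name}:")
    print(f"  score={log.metadata['score']}  losses={log.metadata['losses']}")
    print(f"  mean F_left={fl.mean():.3f} kgf  mean F_right={fr.mean():.3f} kgf")
    print(f"  ground-truth sub-movements per reach: {n_sub:.2f}")
# The weaker profile catches fewer crystals, shows lower force on the paretic
# (left) side, and needs several sub-movements per reach.
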