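"""Evaluate a simulated session with the BiEval metric engine.

Simulates a post-stroke session, segments it into repetitions and prints the
performance parameters: reaction/movement time, speeds, smoothness
(normalized jerk and velocity-peak count), RMS position error, peak forces
with their asymmetry, and the productive-torque split.
"""

from bicar.bieval import session_report
from bicar.game import ControllerConfig
from bicar.simulate import post_stroke_profile, simulate_session

log = simulate_session(
    post_stroke_profile("left", severity=0.4),
    ControllerConfig(auto_assist=False),
    duration=600.0,
    seed=3,
)
rep = session_report(log)

print(f"segments used={rep.n_segments_used}  discarded as outliers={rep.n_segments_discarded}")
print(f"T_r  = {rep.T_r_ms:7.1f} ms   (reaction time; healthy ~730 ms)")
print(f"T_m  = {rep.T_m_s:7.2f} s    (movement time; healthy ~2.5 s)")
print(f"w_m  = {rep.omega_m_rad_s:7.3f} rad/s, w_p = {rep.omega_p_rad_s:.3f} rad/s")
print(f"N_p  = {rep.N_p:7.2f} peaks (fragmentation; 1 = one smooth sub-movement)")
print(f"J_n  = {rep.J_n:7.2f} 1/s^2 (normalized jerk; lower = smoother)")
print(f"err  = {rep.theta_err_rms_deg:7.2f} deg  (RMS tracking error over movements)")
print(f"F_p  = {rep.F_p_left_kgf:.2f} / {rep.F_p_right_kgf:.2f} kgf,  dF = {rep.delta_F_kgf:+.2f} kgf")
print(f"tau_p = {rep.tau_p_left_kgfcm:.1f} / {rep.tau_p_right_kgfcm:.1f} kgf.cm (left/right productive)")
print(f"score = {rep.score}, losses = {rep.losses}")
# dF < 0: the left (paretic) arm produces lower peak forces - the subject
# compensates with the nonparetic right arm.
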