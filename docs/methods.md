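# Methods

This note documents the models, the synthetic-subject generator, the
numerical choices and the known limitations of the package.

## Coordinate and sign conventions

Origin at the midpoint of the anchor line A–B; x to the right, y measured
*downward*, so every taut position has `y > 0`. Handlebar rotation `θ` is
positive counterclockwise as seen by the user facing the device; positive
`θ` lowers the left handlebar tip, lengthening the left cable `L1`.
Clockwise rotation maps to the game wagon moving right. Internally
everything is metres, radians, seconds and kgf; the CLI accepts centimetres
and degrees; torques are reported in kgf·cm, reaction times in ms.

## Kinematics

Cable lengths are Euclidean distances from the anchors to the end-effector
attachment points; the bimanual closed form is the law of cosines with
`d = √((Wb/2)² + h²)`, `r = Wg/2`, `β = atan2(h, Wb/2)`:
`L_{1,2}² = d² + r² − 2rd·cos(θ ± β)`. The inverse recovers each anchor
angle `ψ_j = arccos((d² + r² − L_j²)/(2rd))` and returns `θ = (ψ1 − ψ2)/2`.
This pair is exactly self-inverse (tested to 1e-9 over a 50×50 grid of
`(h, θ)` and under geometry variation).

The device paper's printed closed forms are implemented verbatim behind
`formula="published"`. They differ from the geometric model in two ways,
quantified by `published_model_discrepancy`: the printed forward radicand
carries `Wg²/2` where the half-width derivation gives `Wg²/4` (a constant
offset of `Wg²/4` in `L²`), and the printed inverse omits the factor ½
relating the anchor-angle difference to the bar rotation, so composing the
two printed forms returns `2θ`. The geometric model is authoritative
throughout the package.

Orientation range: `θ_max = min(atan2(h, Wb/2), asin(h/r))` — beyond the
first bound a cable length stops being monotone in `θ` (the inverse would
be ambiguous), beyond the second a handlebar tip would cross the anchor
line. Positions with `y ≤ 0` are rejected; slack cables are not modelled,
and neither are dynamics (the physical device moves a small mass slowly, so
a quasi-static treatment is appropriate).

Trajectory discretization follows `θ_i = i·2π/N + α`; the optional
interpolation is a periodic cubic spline with 20 points per polygon edge
(configurable) — any smooth closed interpolant would do; periodic cubic is
the natural choice for closed trajectories.

## Controller and games

Force-map thresholds default to `ΔF = 0.5` kgf, `F_rot = 2.0` kgf,
`F_max = 6.0` kgf. The raise/lower (two-arm translation) regions are
separate thresholds, 1.0 and 4.0 kgf, chosen so the resting two-arm hold of
the weighted handlebar (≈1.5 kgf per side) classifies as HOLD. The capture
window is closed (`|wagon − crystal| ≤ tolerance`), tolerance 0.10 game
units for MineCart and 0.04 for Sakura (its defining difference). The wagon
maps the handlebar angle linearly, full playfield over ±30°.

Assist-as-needed: after each object resolves, the caught-minus-lost balance
of the last five outcomes raises the level by one when ≤ −1 and lowers it
by one when ≥ +3, within `[−3, +3]`. Level semantics: each positive level
halves the rotation threshold; levels ≥ 2 add a drift toward the target
(0.1 rad/s); level 3 performs the movement by itself (0.3 rad/s toward the
target). Negative levels double the threshold per step (resistive). The
automatic rule never drives the level below 0 — resistive operation is a
deliberate choice (therapist setting or dynamic mode,
`level = −min(3, score/20)`). The source device describes the mechanism but
not these numbers; all are configuration, not claims about the original.

Crystal spawns are uniform over the playfield excluding a ±0.8-unit window
around the *previous* crystal (guaranteeing a substantial reach) and consume
exactly one RNG draw each, so a seed fully determines the crystal sequence
independently of the player — this is what makes "same seed, different
tolerance" comparisons (MineCart vs Sakura) well posed.

## Synthetic subject model

The plant is quasi-static: `ω = mobility · (|F_right − F_left| − ΔF_eff)₊`
in the intent direction, with `mobility = 0.18` rad·s⁻¹·kgf⁻¹ chosen so
typical reaches produce peak forces of ≈3–4 kgf and peak speeds of
≈0.4–0.8 rad/s, the ranges a handlebar device of this geometry records.

A reach toward a new target is a train of `K` sequential minimum-jerk force
pulses. `K = 1 + Poisson(submovements_mean − 1)`; amplitudes decrease
geometrically (each corrective covers 60% of the remaining error, the last
pulse the rest), so the target stays unreached until the final sub-movement
and the noiseless speed trace has exactly `K` local maxima — giving `N_p` a
known ground truth. The pressing arm carries the threshold offset plus 60%
of the demanded differential, the other arm lifts the remaining 40%
(rerouted to the pressing arm where the lift would bottom out near zero).

**Reaction delay** is defined as the latency from target presentation to
*detectable onset*: the instant the planned speed first crosses 5% of its
peak. The pulse train is scheduled so this crossing lands exactly at the
sampled delay (`N(0.73, 0.12²)` s healthy, `N(1.03, 0.25²)` s post-stroke,
truncated at 0.15 s), and **movement time** (`N(2.5, 0.35²)` vs
`N(4.6, 0.8²)` s) is the span between the first and last 5%-of-peak
crossings. Ground-truth onset/settle times and realized sub-movement counts
are logged per reach, which is what makes parameter recovery a genuine
estimator check rather than a threshold-lag artefact.

**Hemiparesis** acts three ways, following the compensation pattern seen in
bimanual force recordings: the affected arm's press saturates at
`arm_strength · (1 − severity)`; weight-bearing shifts toward the nonparetic
arm (`±0.15 · severity · hold`, small enough that the resting differential
never reaches `ΔF`); and fragmentation concentrates on the nonparetic side
(sub-movement rate ×(1 + 2·severity) when the nonparetic arm drives,
×(1 − severity) when the paretic arm drives), reproducing the irregular,
peak-rich force profile on the nonparetic side and `δF` of the matching
sign. When the paretic arm must drive, `severity × 0.5 s` is added to the
reaction delay. A subject that misses the target after its planned train
re-plans corrective pulses (~0.25 s pause) until the object resolves.

The sensor model is the physical acquisition chain: forces clipped to the
20 kgf load-cell capacity and rounded to the 0.025 kgf resolution, the
angle rounded to the quadrature-decoded encoder step `2π/(4·500)`, both on
a unified 80 Hz grid (the handlebar games log force and angle on the same
tick). The default hold force (1.5 kgf/side) stands in for the handlebar's
central weight, whose magnitude the source does not state.

What the generator does *not* emulate: muscle dynamics and EMG, spasticity
beyond fragmentation statistics, fatigue within a session, vertical bar
translation during play, or out-of-plane pulling. Passing recovery tests
therefore show that the evaluator correctly measures the statistical
structure the generator encodes — not that it is clinically validated.

## BiEval numerics

Derivatives: Savitzky-Golay, 0.35 s window, order 3, analytic first/second/
third derivatives of the local fit. Onset/end thresholds default to 5% of
each segment's own peak speed (absolute overrides available); thresholds
relative to the segment's own peak keep the landmarks amplitude-invariant
and match the simulator's onset definition. Onset additionally requires the
smoothed inter-arm torque to be productive (signed toward the target) and
both conditions to hold for 3 consecutive samples (anti-chatter).
The position tolerance for `T_d` is the game capture tolerance mapped to
angle, tying the evaluator to the same success criterion as the game.

Normalized jerk integrates `|J(t)|`: the printed definition is ambiguous
about the sign, and a signed integral largely cancels over any movement
that starts and ends at rest; the signed variant is available behind
`signed_jerk=True`. The velocity-peak "integral" is read as a count of
local maxima of `|ω|` with prominence ≥ 10% of the segment's peak speed
(reported in peaks, minimum 1 for any segment with motion). Force peaks use
a 0.3 kgf absolute prominence — one load-cell resolution step above tremor
noise. Torque lever arm is `Wg/2`; per-side hold baselines are the median
force over near-still samples. The outlier rule is the 1.5·IQR fence,
applied per parameter across segments, never discarding when fewer than 4
values exist; on clean simulated sessions it removes well under 25% of
segments.

Sessions lacking any completed segment produce a report with marked
(`None`) parameters and event-derived score/losses rather than an error.

## Reporting

Weekly aggregation uses ISO calendar weeks of the session timestamps.
Percent excess is `round(100·(B_admission − A)/A)` per parameter, from the
stored group means. The admission-vs-discharge comparison is a two-sided
Wilcoxon signed-rank at 0.05 — the source names only the level; the
signed-rank test is the standard paired choice at n≈8 without normality
assumptions. Single-subject groups and all-zero differences yield no
p-value rather than a spurious one.

## Problem sizes

Tests and the acceptance script use 60–900 s sessions at 80 Hz (up to
~72k samples, 100–120 movement segments for recovery checks) and 40 seeded
replicates for the force-asymmetry sign rate; kinematic oracles use 1000
random positions and a 50×50 pose grid. All randomness flows from explicit
seeds; identical seeds reproduce sessions byte-for-byte.
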