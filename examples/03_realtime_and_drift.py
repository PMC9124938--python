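"""Beat-count (real-time) alpha1 and drift monitoring on a steady segment.

Real-time displays recompute alpha1 for every new beat over the prior 200
beats.  On a steady low-intensity segment the exponent should hold its level;
a sustained downward drift of alpha1 at constant external load is an
autonomic fatigue/durability signal.
"""

from fractalhrv import (
    RampSpec,
    Segment,
    alpha1_realtime_beats,
    alpha1_time_varying,
    generate_exercise_ramp,
    load_drift_summary,
)

spec = RampSpec(name="steady_30min", segments=(Segment(1800.0, 1.05, 850.0, 40.0),))
series, _ = generate_exercise_ramp(spec, seed=3)
print(f"steady segment: {series.n_beats} beats, {series.duration_s:.0f} s")

beat_mode = alpha1_realtime_beats(series)
print(f"real-time emissions: {len(beat_mode)} (one per beat after the 200th)")
print(f"beat-mode alpha1: mean {beat_mode['alpha1'].mean():.3f}, "
      f"sd {beat_mode['alpha1'].std():.3f}")

window_mode = alpha1_time_varying(series)
drift = load_drift_summary(window_mode)
print(f"\n2-min window mode: mean alpha1 {drift['mean_alpha1']:.3f} "
      f"at mean HR {drift['mean_hr']:.0f} bpm")
print(f"alpha1 drift: {drift['slope_per_h']:+.3f} per hour over {drift['n_windows']} windows")
print(
    "\nSingle-session slope estimates scatter by a few tenths per hour; a value\n"
    "compatible with zero says autonomic state is holding at this load.  In a\n"
    "fatiguing session the same analysis shows alpha1 sliding steadily toward\n"
    "0.5 at unchanged pace or power — deteriorating 'durability'."
)
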