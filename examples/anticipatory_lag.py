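"""Recover a planted anticipatory head-turn lead from head/vehicle yaw.

The lag estimator slides head yaw against vehicle yaw and reports the signed
delay maximizing their Pearson correlation; negative lags mean the head turns
*before* the vehicle (anticipation).
"""

from vrheadmotion import (
    HeadModelParams,
    TrackConfig,
    estimate_lag,
    estimate_lag_median_trace,
    generate_vehicle_trace,
    simulate_head_trace,
)

track = TrackConfig()
vehicle = generate_vehicle_trace(track, "fast", seed=3)

# a clean follower who anticipates turns by 750 ms
head = simulate_head_trace(
    vehicle, HeadModelParams(gain=1.0, lead_ms=750.0, noise_sd=0.0, drift_sd=0.0), seed=0
)
est = estimate_lag(head, vehicle)
print(f"noise-free lead:  lag = {est.lag_ms:+.1f} ms, peak r = {est.peak_r:.3f}")

# a realistic cohort: same lead, moderate wander, pooled median-trace estimate
traces = [
    simulate_head_trace(
        vehicle, HeadModelParams(gain=1.0, lead_ms=750.0, noise_sd=1.0), seed=i,
        participant_id=f"p{i}",
    )
    for i in range(30)
]
pooled = estimate_lag_median_trace(traces, vehicle)
print(f"30-person cohort: lag = {pooled.lag_ms:+.1f} ms, peak r = {pooled.peak_r:.3f}")
print("\nBoth estimates sit near -750 ms: heads turn about three quarters of a "
      "second before the vehicle does, i.e. the motion is anticipatory, not "
      "compensatory.")
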