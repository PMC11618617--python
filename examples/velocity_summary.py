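"""Per-axis head velocity summaries and the yaw-dominance contrast.

Mean absolute velocity (degrees/second) per lap and axis, with paired t-tests
showing that yaw motion dominates pitch and roll while following turns.
"""

from vrheadmotion import CohortConfig, generate_cohort
from vrheadmotion.kinematics import compare_axes, mean_absolute_velocity, velocity_frame

cohort = generate_cohort(CohortConfig(experiment=2, n_participants=10, seed=11))

summaries = []
for speed in ("slow", "fast"):
    for trace in cohort.analysis_traces(speed):
        s = mean_absolute_velocity(trace)
        s.speed_condition = speed
        summaries.append(s)

table = velocity_frame(summaries)
print(table.groupby(["speed_condition", "axis"]).mean_abs_velocity.mean().round(2))

for speed in ("slow", "fast"):
    tests = compare_axes(summaries, speed)
    for row in tests.itertuples():
        print(f"{speed:>5} {row.comparison}: t({row.df}) = {row.t:.2f}, p = {row.p:.2g}")
print("\nYaw velocity exceeds pitch and roll at both speeds: the track's turns "
      "drive left-right head motion, and faster playback drives faster heads.")
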