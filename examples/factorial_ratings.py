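"""Within-subjects factorial ANOVA of the self-report ratings.

Runs the direction x speed ANOVA on a synthetic cohort's vection ratings and
prints F, degrees of freedom, p, and partial eta squared per effect.
"""

from vrheadmotion import CohortConfig, generate_cohort, rm_anova
from vrheadmotion.io_formats import trial_records_frame

cohort = generate_cohort(CohortConfig(experiment=2, n_participants=36, seed=5))
records = trial_records_frame(cohort.records)
laps = records[records.speed.isin(["slow", "fast"])]  # baselines excluded

table = rm_anova(laps, "vection_magnitude", within=["direction", "speed"])
for row in table.itertuples():
    print(f"{row.effect:>16}: F({row.df_num}, {row.df_den}) = {row.F:6.2f}, "
          f"p = {row.p:.3g}, eta_p^2 = {row.eta_p_sq:.2f}")

means = laps.groupby("direction").vection_magnitude.mean().round(2)
print("\ncondition means:", means.to_dict())
print("The direction effect reflects the planted ordering: forward (expanding "
      "optic flow) feels most like self-motion, then reverse, then lateral; "
      "the speed effect reflects stronger vection on fast laps.")
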