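"""Generate a small synthetic driving study and write it to disk.

The dataset directory holds per-trial head telemetry CSVs, the two vehicle
laps, the trial-record table, and a ground-truth sidecar with the planted
parameters (which the analysis never reads).
"""

from pathlib import Path

from vrheadmotion import CohortConfig, generate_cohort, write_cohort

cohort = generate_cohort(CohortConfig(experiment=2, n_participants=8, seed=42))
out = Path("scratch_example_data")
write_cohort(cohort, out)

truth = cohort.ground_truth.per_participant
print(f"wrote {len(cohort.head_traces)} head traces and "
      f"{len(cohort.records)} trial records to {out}/")
print(truth.round(3).to_string(index=False))
print("\nEach row is one participant's planted head model: 'gain' scales how "
      "strongly they follow the track, 'lead_ms' is their anticipatory head "
      "turn in milliseconds, 'noise_sd' their idiosyncratic wander (degrees).")
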