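"""Paired task comparison across a synthetic cohort.

Simulates 10 participants who each perform the TUG and a straight walk with
a 10% higher scripted walking speed on the walk, runs the pipeline on every
session, and compares the per-participant metrics between tasks with paired
t contrasts and Sidak adjustment.  The walking-speed contrast should be
significant (the scripted effect), while stride duration and bobbing
frequency — identical between tasks — should not.
"""

import dataclasses

import numpy as np
import pandas as pd

import imugait as ig

rng = np.random.default_rng(5)
rows_tug, rows_walk = [], []
for i in range(10):
    sd = float(rng.uniform(1.0, 1.15))
    profile_tug = ig.GaitProfile(stride_duration=sd, stride_length=1.05 * sd)
    profile_walk = dataclasses.replace(profile_tug, stride_length=1.1 * profile_tug.stride_length)
    for prof, script, kind, rows in [
        (profile_tug, ig.TaskScript.tug(repeats=3), "tug", rows_tug),
        (profile_walk, ig.TaskScript.straight_walk(repeats=2), "walk", rows_walk),
    ]:
        sim = ig.simulate_session(prof, script, seed=int(rng.integers(2**31)))
        res = ig.process_session(sim.recordings, sim.events, task=kind)
        rows.append(
            {
                "walking_speed": res.gait.walking_speed,
                "stride_duration": float(np.mean(res.gait.stride_durations)),
                "bob_trunk": res.stabilization["trunk"].bobbing_frequency,
            }
        )

report = ig.task_comparison_report(pd.DataFrame(rows_tug), pd.DataFrame(rows_walk))
print(report.to_frame().to_string(index=False))
print(
    "\nSidak-adjusted p < 0.05 marks a task difference; only walking_speed"
    "\ncarries a scripted (10%) effect here."
)
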