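"""Generate one annotated synthetic gaze recording and look inside it.

The simulator plays out a scanpath over a 1920x1080 screen: lognormal
fixation dwells on a set of monitored targets, minimum-jerk saccades between
them, blinks (missing pupil samples at zero confidence) and occasional
single-sample collection dropouts. Lapse episodes are drawn as time spans
during which fixations lengthen, saccades widen, blinks become more frequent
and the pupil dilates.
"""

import numpy as np

from gazelapse import simulate as sim

params = sim.ScanpathParams()
episodes = sim.ForgettingEpisodeParams(episode_rate=12.0)  # 12 lapses/hour
rec = sim.simulate_recording(params, episodes, duration=600.0, seed=43)

print(f"samples:        {len(rec)} ({rec.t[-1] + 0.01:.0f} s at 100 Hz)")
print(f"planned fixations: {len(rec.planned_fixations)}")
print(f"lapse episodes: {len(rec.episodes)}")
for start, end in rec.episodes:
    print(f"  {start:7.1f} .. {end:7.1f} s  ({end - start:.1f} s)")

missing = np.isnan(rec.pupil)
print(f"missing pupil samples: {missing.sum()} "
      f"({100 * missing.mean():.2f} % of the recording)")
print(f"confidence during missing runs: "
      f"{np.unique(rec.confidence[missing])}")

sim.write_gaze_table(rec, "example_recording.csv")
sim.write_episode_sidecar(rec, "example_recording.episodes.csv")
print("wrote example_recording.csv (+ episode sidecar)")
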