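"""Turn windows into the 44-feature representation and event sequences.

Each window yields 23 time-related metrics (counts, totals, rates) and 21
time-independent ones (medians, ranges, moments, spatial statistics). The
features are min-max normalized into [0, 1] and grouped into overlapping
sequences of 6 consecutive windows — the classifier's input unit. A
sequence inherits the label of its final window.
"""

import numpy as np

from gazelapse import features as feats
from gazelapse import io as gio
from gazelapse import simulate as sim

rec = sim.simulate_recording(sim.ScanpathParams(),
                             sim.ForgettingEpisodeParams(episode_rate=12.0),
                             duration=600.0, seed=3)
gaze = gio.preprocess(rec.to_recording())
windows = gio.assign_labels(gio.slide_windows(gaze), gaze.episodes)

F, labels, starts = feats.windows_to_features(windows)
print(f"feature matrix: {F.shape} "
      f"({feats.N_TIME_RELATED} time-related + "
      f"{feats.N_TIME_INDEPENDENT} time-independent)")
print(f"labels: {np.bincount(labels)} (normal, lapse)")

show = ["fixation_count", "mean_fixation_duration", "blink_count",
        "mean_saccade_amplitude", "mean_pupil_diameter", "scanpath_length"]
print("\nfirst window:")
for name in show:
    print(f"  {name:26s} {F[0, feats.FEATURE_NAMES.index(name)]:10.3f}")

params = feats.fit_minmax(F)
Z = feats.apply_minmax(F, params)
print(f"\nnormalized range: [{Z.min():.3f}, {Z.max():.3f}]")

X, y = feats.assemble_sequences(Z, labels, length=6)
print(f"sequences: X={X.shape}, labels {np.bincount(y)}")
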