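"""Preprocess a recording and detect oculomotor events in one window.

Preprocessing classifies missing runs as blinks (50-500 ms at zero
confidence, linearly interpolated in the pupil channel) or collection
dropouts (filled with the local mean), then cuts the stream into 500-sample
windows sharing 100 samples. Fixations come from a dispersion-threshold
(I-DT) pass, saccades from consecutive fixation pairs.
"""

from gazelapse import events as ev
from gazelapse import io as gio
from gazelapse import simulate as sim

rec = sim.simulate_recording(sim.ScanpathParams(),
                             sim.ForgettingEpisodeParams(episode_rate=12.0),
                             duration=120.0, seed=7)
gaze = gio.preprocess(rec.to_recording())
windows = gio.assign_labels(gio.slide_windows(gaze), gaze.episodes)
print(f"{len(windows)} windows of {len(windows[0])} samples "
      f"(stride {windows[1].start_index - windows[0].start_index})")

w = windows[3]
fixations, saccades, blinks = ev.detect_events(w)
print(f"\nwindow at sample {w.start_index} (label={w.label}):")
print(f"  {len(fixations)} fixations, {len(saccades)} saccades, "
      f"{len(blinks)} blinks")
for f in fixations:
    print(f"  fixation ({f.x:7.1f}, {f.y:7.1f})  "
          f"{f.onset:6.2f}-{f.offset:6.2f} s  dur {f.duration:.2f} s")
for s in saccades:
    print(f"  saccade  amp {s.amplitude:6.1f} px  dur {s.duration:.3f} s  "
          f"speed {s.speed:7.0f} px/s")
for b in blinks:
    print(f"  blink    {b.onset:6.2f}-{b.offset:6.2f} s  dur {b.duration:.2f} s")
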