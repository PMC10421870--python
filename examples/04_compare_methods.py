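"""Cross-validated comparison of the hybrid model and its baselines.

A deliberately small benchmark: five 15-minute recordings with a raised
lapse rate, the sequences balanced by subsampling so chance accuracy is 0.5,
then 5-fold cross-validation with one recording held out per fold (sequences
overlap within a recording, so folds must follow recording boundaries). All
four methods share the same folds. Expect a minute or two of training on one
CPU; the full-scale protocol lives in scripts/acceptance.py.
"""

import logging

from gazelapse import simulate as sim
from gazelapse import train as tr

logging.basicConfig(level=logging.INFO, format="%(message)s")

episodes = sim.ForgettingEpisodeParams(episode_rate=12.0)
X, y, groups = tr.make_benchmark_dataset(5, 900.0, seed=11,
                                         episode_params=episodes,
                                         return_groups=True)
print(f"{X.shape[0]} balanced sequences of shape {X.shape[1:]} "
      f"from {len(set(groups))} recordings\n")

cfg = tr.TrainConfig(epochs=15, seed=11)
report = tr.run_methods(X, y, cfg, groups=groups)
print()
print(report.to_table())
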