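"""Simulate a ground-truthed movie and segment it frame by frame.

Builds a 60-frame 220x220 px movie (0.1 um/px, 5 s intervals) with
scripted fission and fusion events, runs top-hat flattening plus
mode + 3 sigma thresholding, and compares recovered object counts with
the ground truth.
"""

import numpy as np

from mitodyn import RunConfig, SceneParams, generate_movie, schedule_events, segment_movie

rng = np.random.default_rng(0)
events, n_used = schedule_events(n_fission=3, n_fusion=3, n_passing=0, n_frames=60, rng=rng)
params = SceneParams(n_objects=n_used + 4, events=events)
scene = generate_movie(params, seed=0)

labels, models = segment_movie(scene.movie, RunConfig(random_seed=0))

model = models[0]
print(f"threshold: mode(sqrt)={model.mode_sqrt:.2f}, sigma(sqrt)={model.sigma_sqrt:.2f}, "
      f"lower limit (raw intensity)={model.lower_limit_raw:.1f}")
for t in (0, 30, 59):
    print(f"frame {t:2d}: {len(scene.truth_labels[t].region_ids)} true objects, "
          f"{len(labels[t].region_ids)} segmented")
print("The threshold sits 3 background-SDs above the histogram mode in sqrt space;")
print("matching counts mean every organelle was found and none was split or merged.")
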