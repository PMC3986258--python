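"""Track perimeter and solidity backward from each event (P/P0, S/S0).

Qualifying 1-to-2 fissions and 2-to-1 fusions are followed backward
through the unique stable ancestor for up to 8 frames; ratios are
normalized to the frame just before the event and averaged with standard
errors.
"""

import numpy as np

from mitodyn import (
    SceneParams,
    classify_events,
    generate_movie,
    pre_event_traces,
    schedule_events,
    segment_movie,
)

rng = np.random.default_rng(3)
events_sched, n_used = schedule_events(4, 4, 0, 60, rng=rng)
scene = generate_movie(SceneParams(n_objects=n_used + 3, events=events_sched), seed=3)
labels, _ = segment_movie(scene.movie)
events, _ = classify_events(labels)

traces = pre_event_traces(events, labels)
for call in ("fission", "fusion"):
    sub = traces.summary[traces.summary["call"] == call].set_index("offset")
    line = "  ".join(f"{off}:{sub.loc[off, 'mean_P_ratio']:.3f}" for off in sub.index)
    print(f"{call:7s} mean P/P0 by frames before event -> {line}")
    print(f"{'':7s} n contributing at offset 8: {int(sub['n'].iloc[-1])}")
print("Scene objects keep a fixed shape before their scripted event, so the")
print("normalized traces stay at 1.0; on real movies, deviations before")
print("fission reveal pre-event remodeling of the organelle.")
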