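"""Pre-event morphology traces: perimeter and solidity tracked backward
in time from each 1-to-2 fission or 2-to-1 fusion event, normalized to
the values in the frame just before the event (P/P0, S/S0), and averaged
per time offset with standard errors.

Backward tracking follows the unique stable ancestor at every step: a
trace extends to an earlier frame only while the backward relation is
1-to-1, and terminates early (rather than imputing) when the identity of
the organelle becomes ambiguous; the number of contributing events is
reported per offset.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .events import EventRecord, relate_regions
from .morphometry import basic_shape_features
from .segmentation import LabelFrame


@dataclasses.dataclass
class TraceSet:
    """Per-event normalized traces and their per-offset summary.

    ``per_event``: one row per (event, offset) with the raw and normalized
    perimeter/solidity.  ``summary``: mean ± SE of P/P0 and S/S0 per
    offset and call, with the number of surviving traces n.  Offset 0 is
    the frame just before the event, offset k the k-th frame earlier.
    """

    per_event: pd.DataFrame
    summary: pd.DataFrame


def _qualifying(events: Sequence[EventRecord], labels: Sequence[LabelFrame]):
    """Restrict to 1→2 fissions and 2→1 fusions."""
    out = []
    graphs: dict[int, object] = {}
    for e in events:
        if e.call not in ("fission", "fusion"):
            continue
        t = e.frame_index
        if t not in graphs:
            graphs[t] = relate_regions(labels[t], labels[t + 1], (t, t + 1))
        g = graphs[t]
        if e.call == "fission":
            if len(g.descendants[e.region_id]) == 2:
                out.append(e)
        else:
            desc = g.descendants[e.region_id]
            if len(desc) == 1 and len(g.ancestors[next(iter(desc))]) == 2:
                out.append(e)
    return out


def pre_event_traces(
    events: Sequence[EventRecord],
    labels: Sequence[LabelFrame],
    config: RunConfig | None = None,
) -> TraceSet:
    """Build normalized perimeter/solidity traces over the
    ``pre_event_frames`` frames preceding each qualifying event."""
    config = config or RunConfig()
    qualifying = _qualifying(events, labels)
    if not qualifying:
        raise ValueError("no qualifying 1→2 fission or 2→1 fusion events")

    backward_graphs: dict[int, object] = {}

    def backward_step(t: int, region: int):
        """Unique stable ancestor of ``region`` at frame t, via the t-1→t
        relation; None if the backward identity is not 1→1."""
        if t - 1 < 0:
            return None
        if t not in backward_graphs:
            backward_graphs[t] = relate_regions(labels[t - 1], labels[t], (t - 1, t))
        g = backward_graphs[t]
        anc = g.ancestors.get(region, frozenset())
        if len(anc) != 1:
            return None
        a = next(iter(anc))
        if g.descendants[a] != frozenset({region}):
            return None
        return a

    rows = []
    for k, e in enumerate(qualifying):
        t, region = e.frame_index, e.region_id
        f0 = basic_shape_features(labels[t].mask(region), labels[t].pixel_size_um)
        p0, s0 = f0["perimeter_um"], f0["solidity"]
        rows.append((k, e.call, 0, p0, s0, 1.0, 1.0))
        cur_t, cur_r = t, region
        for offset in range(1, config.pre_event_frames + 1):
            anc = backward_step(cur_t, cur_r)
            if anc is None:
                break
            cur_t, cur_r = cur_t - 1, anc
            f = basic_shape_features(labels[cur_t].mask(cur_r), labels[cur_t].pixel_size_um)
            rows.append((k, e.call, offset, f["perimeter_um"], f["solidity"], f["perimeter_um"] / p0, f["solidity"] / s0))
    per_event = pd.DataFrame(
        rows,
        columns=["event", "call", "offset", "perimeter_um", "solidity", "p_ratio", "s_ratio"],
    )

    summaries = []
    for (call, offset), grp in per_event.groupby(["call", "offset"]):
        n = len(grp)
        summaries.append(
            {
                "offset": offset,
                "call": call,
                "mean_P_ratio": grp["p_ratio"].mean(),
                "se_P": grp["p_ratio"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                "mean_S_ratio": grp["s_ratio"].mean(),
                "se_S": grp["s_ratio"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                "n": n,
            }
        )
    summary = pd.DataFrame(summaries).sort_values(["call", "offset"]).reset_index(drop=True)
    return TraceSet(per_event, summary)
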