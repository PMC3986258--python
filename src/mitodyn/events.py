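"""Fission/fusion event detection by overlap relations and
weight-distribution scoring.

Two consecutive labeled frames are linked by a bipartite relation: a pair
(i in Frame 1, j in Frame 2) is related iff they overlap by at least one
pixel and i is (one of) the maximal-overlap Frame-1 regions for j, or j is
(one of) the maximal-overlap Frame-2 regions for i.  Each Frame-2 region
then carries a unit weight, split equally among its ancestors; the score
of a Frame-1 region is the sum of the weights it receives.  A score above
1 marks a region poised to undergo fission, below 1 fusion, exactly 1
neither.  A call is confirmed only if the score computed two frames ahead
agrees, which rejects transient one-frame contacts (the two-frame / 10 s
persistence requirement).

Scores are computed with exact rational arithmetic so the stable (== 1)
comparison and the weight-conservation invariant hold exactly.
"""

from __future__ import annotations

import dataclasses
import math
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .segmentation import LabelFrame


@dataclasses.dataclass
class RelationGraph:
    """Bipartite overlap relations between regions of two frames."""

    frame_pair: tuple[int, int]
    overlap_pixels: dict[tuple[int, int], int]
    ancestors: dict[int, frozenset[int]]   # Frame-2 region -> Frame-1 regions
    descendants: dict[int, frozenset[int]]  # Frame-1 region -> Frame-2 regions


def relate_regions(
    label_t: LabelFrame,
    label_next: LabelFrame,
    frame_pair: tuple[int, int] = (0, 1),
) -> RelationGraph:
    """Build the overlap relation between two labeled frames.

    All argmax ties are included; regions with zero overlap against every
    counterpart have no relations.
    """
    a = label_t.labels
    b = label_next.labels
    if a.shape != b.shape:
        raise ValueError(f"frame shape mismatch: {a.shape} vs {b.shape}")

    both = (a > 0) & (b > 0)
    ids_a = label_t.region_ids
    ids_b = label_next.region_ids
    overlap_all: dict[tuple[int, int], int] = {}
    if both.any():
        pair_codes = a[both].astype(np.int64) * (int(b.max()) + 1) + b[both].astype(np.int64)
        codes, counts = np.unique(pair_codes, return_counts=True)
        base = int(b.max()) + 1
        for code, count in zip(codes, counts):
            overlap_all[(int(code // base), int(code % base))] = int(count)

    # argmax (with ties) of overlap per Frame-2 region and per Frame-1 region
    best_for_b: dict[int, int] = {}
    best_for_a: dict[int, int] = {}
    for (i, j), n in overlap_all.items():
        best_for_b[j] = max(best_for_b.get(j, 0), n)
        best_for_a[i] = max(best_for_a.get(i, 0), n)
    related: set[tuple[int, int]] = set()
    for (i, j), n in overlap_all.items():
        if n == best_for_b[j] or n == best_for_a[i]:
            related.add((i, j))

    ancestors = {j: frozenset(i for (i, jj) in related if jj == j) for j in ids_b}
    descendants = {i: frozenset(j for (ii, j) in related if ii == i) for i in ids_a}
    overlap_pixels = {pair: overlap_all[pair] for pair in related}
    return RelationGraph(frame_pair, overlap_pixels, ancestors, descendants)


def score_regions(
    graph: RelationGraph,
    overlap_weighted: bool = False,
) -> tuple[dict[int, Fraction], dict[int, Fraction]]:
    """Distribute each Frame-2 region's unit weight among its ancestors.

    Returns ``(s_next, s_prev)``: ``s_next[j]`` is the equal-split share
    1/|A_j| each ancestor of Frame-2 region j receives (absent if j has no
    ancestors); ``s_prev[i]`` is the total weight Frame-1 region i
    receives (absent — undefined — if i has no descendants).  With
    ``overlap_weighted`` the weight of j is split proportionally to pixel
    overlap instead of equally.
    """
    s_next: dict[int, Fraction] = {}
    s_prev: dict[int, Fraction] = {}
    for j, anc in graph.ancestors.items():
        if anc:
            s_next[j] = Fraction(1, len(anc))
    for i, desc in graph.descendants.items():
        if not desc:
            continue
        total = Fraction(0)
        for j in desc:
            if overlap_weighted:
                denom = sum(graph.overlap_pixels[(ii, j)] for ii in graph.ancestors[j])
                total += Fraction(graph.overlap_pixels[(i, j)], denom)
            else:
                total += Fraction(1, len(graph.ancestors[j]))
        s_prev[i] = total
    return s_next, s_prev


@dataclasses.dataclass
class EventRecord:
    """One region at one frame with its next-frame and skip-frame scores."""

    frame_index: int
    region_id: int
    score_next: float
    score_skip: float  # NaN when undefined (no relation two frames ahead)
    call: str  # 'fission' | 'fusion' | 'stable' | 'unconfirmed'
    area_px: int


def _call(s: Fraction, s_skip: Fraction | None) -> str:
    if s == 1:
        return "stable"
    if s_skip is None:
        return "unconfirmed"
    if s > 1 and s_skip > 1:
        return "fission"
    if s < 1 and s_skip < 1:
        return "fusion"
    return "unconfirmed"


def classify_events(
    labels: Sequence[LabelFrame],
    config: RunConfig | None = None,
):
    """Score every region of every frame that has a frame two ahead.

    Returns ``(events, anomalies)``: one :class:`EventRecord` per Frame-1
    region with a defined next-frame score, and a log of appearances
    (Frame-2 regions with no ancestor) and disappearances (Frame-1 regions
    with no descendant) as ``(frame_index, region_id, kind)`` tuples —
    these are not events but usually indicate segmentation failures.
    """
    config = config or RunConfig()
    if len(labels) < 3:
        raise ValueError("event classification needs at least 3 frames")
    events: list[EventRecord] = []
    anomalies: list[tuple[int, int, str]] = []
    for t in range(len(labels) - 2):
        g1 = relate_regions(labels[t], labels[t + 1], (t, t + 1))
        g2 = relate_regions(labels[t], labels[t + 2], (t, t + 2))
        _, s1 = score_regions(g1, config.overlap_weighted_scores)
        _, s2 = score_regions(g2, config.overlap_weighted_scores)
        areas = dict(zip(*[list(x) for x in np.unique(labels[t].labels, return_counts=True)]))
        for i in labels[t].region_ids:
            if i not in s1:
                anomalies.append((t, i, "disappearance"))
                continue
            skip = s2.get(i)
            events.append(
                EventRecord(
                    frame_index=t,
                    region_id=i,
                    score_next=float(s1[i]),
                    score_skip=float(skip) if skip is not None else math.nan,
                    call=_call(s1[i], skip),
                    area_px=int(areas[i]),
                )
            )
        for j in labels[t + 1].region_ids:
            if not g1.ancestors[j]:
                anomalies.append((t + 1, j, "appearance"))
    return events, anomalies


def events_to_table(events: Sequence[EventRecord]) -> pd.DataFrame:
    """Tabulate event records (one row per region per scored frame)."""
    columns = ["frame", "region_id", "score_next", "score_skip", "call", "area_px"]
    rows = [
        (e.frame_index, e.region_id, e.score_next, e.score_skip, e.call, e.area_px)
        for e in events
    ]
    return pd.DataFrame(rows, columns=columns)
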