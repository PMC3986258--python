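"""Run configuration shared by every pipeline stage.

A single flat record holds the handful of fixed constants the analysis
depends on: the top-hat structuring element and iteration count, the
mode + k·sigma threshold rule, the binary clean/separate iteration counts,
the two-frame event persistence requirement, the 10 µm neighbourhood radius
for positional features, the neck-detection smoothing kernel, the random
forest size and per-split candidate count, and the number of pre-event
frames tracked for morphology traces.  The record round-trips through JSON
so a full run is reproducible from one artifact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path


@dataclasses.dataclass
class RunConfig:
    """Fixed parameters of the analysis.

    Attributes
    ----------
    tophat_size_px:
        Side of the square structuring element of the white top-hat (px).
    tophat_counts:
        Number of times erosion (then dilation) is iterated in the opening.
    threshold_sigma_mult:
        The lower intensity threshold sits this many background standard
        deviations above the mode, in square-root-transformed space.
    clean_iterations:
        Rounds of binary opening applied to the thresholded mask.
    separate_iterations:
        Rounds of watershed-based splitting of touching objects.
    persistence_frames:
        Frames an event's product configuration must persist (2 frames at
        5 s intervals = 10 s).
    neighbor_radius_um:
        Radius of the neighbourhood used for the neighbor-surface feature.
    neck_kernel_px:
        Width (FWHM, in boundary-index units) of the Gaussian used to
        smooth the boundary pairwise-distance matrix in neck detection.
    n_trees:
        Number of trees in the random forest.
    rf_split_candidates:
        Candidate features evaluated at each tree split (mtry).
    pre_event_frames:
        Frames tracked backward from an event for morphology traces.
    random_seed:
        Seed for every stochastic step (simulation, forest, permutation).
    threshold_per_frame:
        Recompute the intensity threshold on every frame instead of once
        on the first frame of the series.
    overlap_weighted_scores:
        Distribute each later-frame region's unit weight among its
        ancestors proportionally to pixel overlap instead of equally.
    perimeter_edge_pixel_count:
        Use the edge-pixel-count perimeter variant (boundary pixels ×
        pixel size) instead of the traced-boundary polygon length.
    """

    tophat_size_px: int = 3
    tophat_counts: int = 5
    threshold_sigma_mult: float = 3.0
    clean_iterations: int = 2
    separate_iterations: int = 3
    persistence_frames: int = 2
    neighbor_radius_um: float = 10.0
    neck_kernel_px: int = 5
    n_trees: int = 2000
    rf_split_candidates: int = 3
    pre_event_frames: int = 8
    random_seed: int = 0
    threshold_per_frame: bool = False
    overlap_weighted_scores: bool = False
    perimeter_edge_pixel_count: bool = False

    def __post_init__(self) -> None:
        for name in (
            "tophat_size_px",
            "tophat_counts",
            "clean_iterations",
            "separate_iterations",
            "persistence_frames",
            "neck_kernel_px",
            "n_trees",
            "rf_split_candidates",
            "pre_event_frames",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.threshold_sigma_mult <= 0:
            raise ValueError("threshold_sigma_mult must be > 0")
        if self.neighbor_radius_um <= 0:
            raise ValueError("neighbor_radius_um must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
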