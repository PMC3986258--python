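"""Shared fixtures: hand-built label stacks and small scene factories."""

from __future__ import annotations

import numpy as np
import pytest

from mitodyn import LabelFrame, RunConfig


def label_frame(array, pixel_size_um=0.1) -> LabelFrame:
    return LabelFrame(np.asarray(array, dtype=np.int32), pixel_size_um)


def two_squares(gap_cols: int = 4, size: int = 6, shape=(20, 30)):
    """Two square regions (ids 1, 2) separated by gap_cols background
    columns."""
    lab = np.zeros(shape, dtype=np.int32)
    r0 = 4
    lab[r0 : r0 + size, 2 : 2 + size] = 1
    c1 = 2 + size + gap_cols
    lab[r0 : r0 + size, c1 : c1 + size] = 2
    return lab


def merged_squares(gap_cols: int = 4, size: int = 6, shape=(20, 30), value: int = 3):
    """The rectangle covering both squares and the gap (a merged region)."""
    lab = np.zeros(shape, dtype=np.int32)
    r0 = 4
    lab[r0 : r0 + size, 2 : 2 + 2 * size + gap_cols] = value
    return lab


@pytest.fixture
def fast_config() -> RunConfig:
    """Small forest for classifier tests that do not probe forest size."""
    return RunConfig(n_trees=200, random_seed=0)


@pytest.fixture
def persistent_fusion_stack():
    """Two squares that merge at frame 1 and stay merged (a real fusion)."""
    frames = [two_squares()] + [merged_squares() for _ in range(3)]
    return [label_frame(f) for f in frames]


@pytest.fixture
def transient_contact_stack():
    """Two squares that touch at frame 1 only (a passing, not a fusion)."""
    frames = [two_squares(), merged_squares(), two_squares(), two_squares()]
    return [label_frame(f) for f in frames]
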