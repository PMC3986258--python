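"""Movie container and TIFF / CSV input-output.

The only required image dialect is TIFF: grayscale movies are multi-page
TIFF stacks (or a directory of single-page TIFFs ordered by name) and label
masks are written as 16-bit single-channel TIFF stacks.  Coordinates are
row-major 0-based pixel indices; a pixel is a unit square and conversions
to µm multiply by ``pixel_size_um``.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig


@dataclasses.dataclass
class Movie:
    """An ordered grayscale time series with physical metadata.

    frames: (T, H, W) non-negative intensity array.
    pixel_size_um: µm per pixel edge.
    frame_interval_s: seconds between frames.
    roi_mask: optional (H, W) boolean cell mask.
    nucleus_centroid: optional (row, col) of the nucleus in pixels.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    roi_mask: np.ndarray | None = None
    nucleus_centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise ValueError("frames must be a non-empty (T, H, W) array")
        if np.any(np.asarray(self.frames[0].shape) == 0):
            raise ValueError("frames must have non-zero height and width")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.frames.shape[1:]:
                raise ValueError("roi_mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def read_movie(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_s: float,
    roi_mask: np.ndarray | None = None,
    nucleus_centroid: tuple[float, float] | None = None,
) -> Movie:
    """Read a multi-page TIFF (or a directory of single-page TIFFs ordered
    by name) into a :class:`Movie`.  Integer intensities are preserved
    losslessly."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        pages = [tifffile.imread(f) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        frames = np.stack(pages)
    elif path.exists():
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValueError(f"expected a single-channel grayscale stack, got shape {frames.shape}")
    else:
        raise FileNotFoundError(str(path))
    return Movie(frames, pixel_size_um, frame_interval_s, roi_mask, nucleus_centroid)


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as a multi-page TIFF, keeping the input dtype."""
    tifffile.imwrite(Path(path), movie.frames)


def write_label_stack(labels: Sequence[np.ndarray], path: str | Path) -> None:
    """Write integer label frames as a 16-bit single-channel TIFF stack."""
    arr = np.stack([np.asarray(f) for f in labels])
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    tifffile.imwrite(Path(path), arr.astype(np.uint16))


def read_label_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.int64)


def write_tables(events: pd.DataFrame, features: pd.DataFrame, out_dir: str | Path) -> None:
    """Write ``events.csv`` and ``features.csv``.

    Column names are stable; floats are written at full round-trip
    precision so reruns with the same seed are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events.to_csv(out_dir / "events.csv", index=False)
    features.to_csv(out_dir / "features.csv", index=False)


def write_manifest(out_dir: str | Path, config: RunConfig, seed: int) -> None:
    """Write a JSON run manifest (config + seed + library versions)."""
    import numpy
    import pandas
    import skimage
    import sklearn

    from . import __version__

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": seed,
        "versions": {
            "mitodyn": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scikit-image": skimage.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
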