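"""Kymograph construction along a traced neurite path.

A kymograph collapses a time-lapse movie to a 2-D matrix (frame x position
along the neurite): a particle moving at constant velocity traces a line
whose slope is its velocity.  Column 0 is the soma end of the path by
convention, so anterograde motion (away from the soma) drifts toward
higher column indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import TimeLapseMovie

__all__ = ["NeuritePath", "Kymograph", "path_arclength_lut", "build_kymograph"]


class PathOutOfBoundsError(ValueError):
    """A path vertex lies outside the movie frame."""


@dataclass
class NeuritePath:
    """Hand-traced neurite polyline in image coordinates.

    ``vertices`` are (row, col) pixel coordinates, 0-based, ordered from the
    soma end outward.  ``sampling_width`` is the transverse band half-width
    (pixels) used for max-projection when building the kymograph.
    """

    vertices: np.ndarray
    neurite_class: str = "axon"
    sampling_width: int = 2

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("path requires >= 2 (row, col) vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.all(seg == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")

    @property
    def arc_length_px(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))

    @classmethod
    def straight(
        cls, row: float, col_start: float, col_end: float, **kwargs
    ) -> "NeuritePath":
        return cls(np.array([[row, col_start], [row, col_end]]), **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "NeuritePath":
        df = pd.read_csv(path)
        return cls(df[["row", "col"]].to_numpy(float), **kwargs)

    @classmethod
    def from_imagej_roi_text(cls, path: str | Path, **kwargs) -> "NeuritePath":
        """Read an ImageJ-style point list: whitespace/comma separated x y
        pairs per line, 0-based, x = column, y = row."""
        pts = []
        for line in Path(path).read_text().splitlines():
            line = line.strip().replace(",", " ")
            if not line:
                continue
            x, y = line.split()[:2]
            pts.append((float(y), float(x)))
        return cls(np.array(pts), **kwargs)


@dataclass
class Kymograph:
    """2-D (frame x position) intensity matrix with calibration."""

    matrix: np.ndarray
    pixel_size: float  # µm per column
    frame_interval: float  # s per row
    channel: str = "rna"
    path: NeuritePath | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[1]

    def write_tiff(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.matrix, dtype=np.float32))
        path.with_suffix(".json").write_text(
            json.dumps(
                {
                    "pixel_size_um": self.pixel_size,
                    "frame_interval_s": self.frame_interval,
                    "channel": self.channel,
                }
            )
        )

    @classmethod
    def read_tiff(cls, path: str | Path) -> "Kymograph":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            matrix=tifffile.imread(path),
            pixel_size=meta["pixel_size_um"],
            frame_interval=meta["frame_interval_s"],
            channel=meta["channel"],
        )


def path_arclength_lut(path: NeuritePath, pixel_size: float | None = None) -> np.ndarray:
    """Resample the polyline at unit-pixel arc-length spacing.

    Returns an array of shape (n_positions, 2) mapping kymograph column
    index j to the (row, col) image coordinate at arc length j pixels from
    the soma end.  n_positions = ceil(arc length in pixels), i.e.
    ceil(arc_length_um / pixel_size) for the movie's calibration.
    """
    verts = path.vertices
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n_positions = int(np.ceil(total))
    s = np.arange(n_positions, dtype=float)
    rows = np.interp(s, cum, verts[:, 0])
    cols = np.interp(s, cum, verts[:, 1])
    return np.column_stack([rows, cols])


def build_kymograph(movie: TimeLapseMovie, path: NeuritePath) -> Kymograph:
    """Max-project a transverse band along the path, per frame.

    For each arc-length sample point the kymograph value is the maximum
    intensity over the band of +/- sampling_width pixels perpendicular to
    the local path direction (nearest-pixel lookup); every output value is
    therefore an actual pixel value from the source frame.
    """
    n_frames, height, width = movie.frames.shape
    for k, (r, c) in enumerate(path.vertices):
        if not (0 <= r < height and 0 <= c < width):
            raise PathOutOfBoundsError(
                f"path vertex {k} at (row={r}, col={c}) lies outside the "
                f"{height}x{width} movie frame"
            )

    lut = path_arclength_lut(path)
    # local tangents -> unit normals
    tangents = np.gradient(lut, axis=0)
    norms = np.hypot(tangents[:, 0], tangents[:, 1])
    norms[norms == 0] = 1.0
    normals = np.column_stack([-tangents[:, 1] / norms, tangents[:, 0] / norms])

    w = int(path.sampling_width)
    offsets = np.arange(-w, w + 1, dtype=float)
    # (n_positions, band) index grids, clipped to the frame
    rows = np.rint(lut[:, 0][:, None] + offsets[None, :] * normals[:, 0][:, None]).astype(int)
    cols = np.rint(lut[:, 1][:, None] + offsets[None, :] * normals[:, 1][:, None]).astype(int)
    rows = np.clip(rows, 0, height - 1)
    cols = np.clip(cols, 0, width - 1)

    band = movie.frames[:, rows, cols]  # (n_frames, n_positions, band)
    matrix = band.max(axis=2).astype(float)

    return Kymograph(
        matrix=matrix,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
        channel=movie.channel,
        path=path,
    )
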