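"""Readers and writers for multimodal skin-microscopy data.

The on-disk stack format is a plain multi-page TIFF with channel-major page
order (all z planes of the first channel, then the second, ...) plus a JSON
sidecar (``<path>.json``) holding the physical calibration and labels.  This
keeps files readable by any TIFF viewer while avoiding the tag-dialect
ambiguity of embedded metadata.

Conventions: pixels are 0-based with origin at the top-left, ``x`` = column,
``y`` = row; depth index 0 is the shallowest plane (top of the stratum
corneum); all physical quantities are micrometres.  Intensities are held as
float32 regardless of the source bit depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: Channel names understood by the analysis modules.
KNOWN_CHANNELS = ("RCM", "TPF735", "TPF810", "SHG810")

#: Declared order of the study timepoints, baseline first.
TIMEPOINT_ORDER = ("baseline", "1h", "24h", "3d", "1w", "2w")


class CalibrationError(ValueError):
    """Raised when physical calibration is missing or non-positive."""


@dataclass
class MultimodalStack:
    """Co-registered multi-channel z-stack with micrometre calibration.

    Parameters
    ----------
    channels
        Mapping of channel name (subset of :data:`KNOWN_CHANNELS`) to a 3D
        float array of shape ``(z, y, x)``, arbitrary units, non-negative.
    pixel_size_xy
        Lateral pixel size in µm/pixel.
    z_step
        Axial spacing between planes in µm.
    fov_um
        Lateral field-of-view edge length in µm.
    session_id, timepoint
        Free-text labels identifying the imaging session.
    """

    channels: dict
    pixel_size_xy: float
    z_step: float
    fov_um: float = 200.0
    session_id: str = ""
    timepoint: str = "baseline"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        shapes = set()
        for name, arr in list(self.channels.items()):
            if name not in KNOWN_CHANNELS:
                raise ValueError(
                    f"unknown channel {name!r}; expected one of {KNOWN_CHANNELS}"
                )
            arr = np.asarray(arr, dtype=np.float32)
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be 3D (z, y, x)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {sorted(shapes)}")
        if not (self.pixel_size_xy > 0):
            raise CalibrationError("pixel_size_xy must be > 0")
        if not (self.z_step > 0):
            raise CalibrationError("z_step must be > 0")
        if not (self.fov_um > 0):
            raise CalibrationError("fov_um must be > 0")

    @property
    def shape(self) -> tuple:
        """(z, y, x) shape shared by all channels."""
        return next(iter(self.channels.values())).shape

    @property
    def depths_um(self) -> np.ndarray:
        """Depth of each plane in µm, index 0 = shallowest."""
        return np.arange(self.shape[0], dtype=float) * self.z_step


@dataclass
class FrameSeries:
    """Time series of 2D frames at a fixed depth (t, y, x)."""

    frames: np.ndarray
    pixel_size_xy: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3D (t, y, x)")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame series needs at least 2 frames")
        if not (self.pixel_size_xy > 0):
            raise CalibrationError("pixel_size_xy must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class CellAnnotations:
    """Manual dot annotations of cell centres within a counted region.

    ``area_px`` is the pixel area of the region the dots were counted in,
    carried in the annotation file itself so density never relies on an
    assumed region extent.
    """

    layer: str
    points: list = field(default_factory=list)
    area_px: int = 0

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("area_px must be > 0")
        for x, y in self.points:
            if x < 0 or y < 0:
                raise ValueError(f"annotation point ({x}, {y}) out of bounds")

    @property
    def n_cells(self) -> int:
        return len(self.points)


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: MultimodalStack, path) -> Path:
    """Write a stack as a channel-major multi-page TIFF + JSON sidecar.

    Returns the TIFF path.  ``read_stack`` inverts this exactly (bit-identical
    float32 pages, calibration preserved).
    """
    path = Path(path)
    names = list(stack.channels)
    pages = np.concatenate([stack.channels[n] for n in names], axis=0)
    tifffile.imwrite(path, pages)
    meta = {
        "channels": names,
        "n_planes": int(stack.shape[0]),
        "pixel_size_xy": float(stack.pixel_size_xy),
        "z_step": float(stack.z_step),
        "fov_um": float(stack.fov_um),
        "session_id": stack.session_id,
        "timepoint": stack.timepoint,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path, metadata: Mapping | None = None) -> MultimodalStack:
    """Read a channel-major multi-page TIFF written by :func:`write_stack`.

    ``metadata`` overrides the JSON sidecar; one of the two must supply
    ``channels``, ``n_planes``, ``pixel_size_xy`` and ``z_step`` — missing
    calibration raises :class:`CalibrationError` rather than defaulting.
    """
    path = Path(path)
    if metadata is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise CalibrationError(
                f"no calibration metadata: sidecar {sidecar} missing and none passed"
            )
        metadata = json.loads(sidecar.read_text())
    for key in ("channels", "n_planes", "pixel_size_xy", "z_step"):
        if key not in metadata:
            raise CalibrationError(f"calibration metadata lacks {key!r}")
    pages = np.asarray(tifffile.imread(path))
    if pages.ndim == 2:
        pages = pages[None]
    names = list(metadata["channels"])
    n_planes = int(metadata["n_planes"])
    if pages.shape[0] != n_planes * len(names):
        raise ValueError(
            f"page count {pages.shape[0]} does not match "
            f"{len(names)} channels x {n_planes} planes"
        )
    channels = {
        name: pages[i * n_planes : (i + 1) * n_planes] for i, name in enumerate(names)
    }
    return MultimodalStack(
        channels=channels,
        pixel_size_xy=float(metadata["pixel_size_xy"]),
        z_step=float(metadata["z_step"]),
        fov_um=float(metadata.get("fov_um", 200.0)),
        session_id=str(metadata.get("session_id", "")),
        timepoint=str(metadata.get("timepoint", "baseline")),
    )


def write_frames(series: FrameSeries, path) -> Path:
    """Write a frame series as a multi-page TIFF + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, series.frames)
    _sidecar_path(path).write_text(
        json.dumps({"pixel_size_xy": float(series.pixel_size_xy)})
    )
    return path


def read_frames(path, pixel_size_xy: float | None = None) -> FrameSeries:
    path = Path(path)
    if pixel_size_xy is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise CalibrationError(f"no pixel size: sidecar {sidecar} missing")
        pixel_size_xy = float(json.loads(sidecar.read_text())["pixel_size_xy"])
    return FrameSeries(frames=tifffile.imread(path), pixel_size_xy=pixel_size_xy)


def write_annotations(ann: CellAnnotations, path) -> Path:
    """Write dot annotations as CSV: one ``# area_px:`` header line, then
    ``layer,x,y`` rows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# area_px: {ann.area_px}\n")
        fh.write("layer,x,y\n")
        for x, y in ann.points:
            fh.write(f"{ann.layer},{x},{y}\n")
    return path


def read_annotations(path) -> CellAnnotations:
    """Read a dot-annotation CSV (``# area_px:`` header + layer,x,y rows)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "area_px" not in first:
            raise ValueError(f"{path}: first line must declare '# area_px: <count>'")
        area_px = int(first.split(":", 1)[1])
        df = pd.read_csv(fh)
    expected = {"layer", "x", "y"}
    if set(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}")
    layers = df["layer"].unique().tolist()
    if len(layers) > 1:
        raise ValueError(f"{path}: mixed layers {layers} in one annotation file")
    layer = layers[0] if layers else ""
    points = [(float(x), float(y)) for x, y in zip(df["x"], df["y"])]
    return CellAnnotations(layer=str(layer), points=points, area_px=area_px)


def read_landmarks(path) -> dict:
    """Read a landmark CSV (``session_id,point_id,x_um,y_um``) into a dict
    ``{session_id: {"p1": (x, y), "p2": (x, y)}}`` with coordinates in µm."""
    df = pd.read_csv(path)
    expected = {"session_id", "point_id", "x_um", "y_um"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    sessions: dict = {}
    for row in df.itertuples(index=False):
        pid = str(row.point_id)
        if pid not in ("p1", "p2"):
            raise ValueError(f"{path}: point_id must be p1 or p2, got {pid!r}")
        sessions.setdefault(str(row.session_id), {})[pid] = (
            float(row.x_um),
            float(row.y_um),
        )
    for sid, pts in sessions.items():
        if set(pts) != {"p1", "p2"}:
            raise ValueError(f"{path}: session {sid!r} lacks both p1 and p2")
    return sessions


def write_landmarks(sessions: Mapping, path) -> Path:
    rows = []
    for sid, pts in sessions.items():
        for pid in ("p1", "p2"):
            x, y = pts[pid]
            rows.append({"session_id": sid, "point_id": pid, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
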