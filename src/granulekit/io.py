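"""Calibrated image stacks, ROIs, run configuration and tabular I/O.

All pixel coordinates in this package are 0-based, ``(y, x)`` order, with
pixel centers at integer coordinates.  Physical distances derive from
``pixel_size_um``; times from ``frame_interval_s``.  Downstream analysis
consumes only the in-memory types defined here (:class:`ImageStack`,
:class:`Roi`, :class:`RunConfig`), never file paths.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger("granulekit")

AXES = "TZCYX"


class FormatError(ValueError):
    """Unreadable or malformed input file."""


class ConfigurationError(ValueError):
    """Required calibration or configuration value missing."""


class GeometryError(ValueError):
    """ROI geometry invalid or outside the image."""


class SchemaError(ValueError):
    """Records passed for tabulation do not share one schema."""


@dataclass
class ImageStack:
    """A calibrated fluorescence stack indexed ``(t, z, c, y, x)``.

    Intensities are kept on their raw scale (any bit depth; nothing is
    normalized).  ``frame_interval_s`` must be positive when there is more
    than one time point.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ValueError(f"pixels must be 5-D (t,z,c,y,x), got {self.pixels.ndim}-D")
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(
            np.isfinite(self.pixels)
        ):
            raise ValueError("pixel intensities must be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixel intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_frames > 1 and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0 for multi-frame stacks")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def plane(self, t: int = 0, z: int = 0, c: int = 0) -> np.ndarray:
        """Single 2-D plane ``(y, x)``."""
        return self.pixels[t, z, c]

    def max_z(self, t: int = 0, c: int = 0) -> np.ndarray:
        """Maximum-intensity z-projection of one frame/channel."""
        return self.pixels[t, :, c].max(axis=0)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class Roi:
    """A region of interest in pixel coordinates.

    ``kind`` is one of ``circle`` (center ``(y, x)`` + radius), ``polygon``
    (closed; vertices ``(y, x)``), or ``polyline`` (open path, used for
    neurites).  A pixel belongs to the ROI if its center lies inside the
    shape, boundary inclusive.
    """

    kind: str
    center: tuple[float, float] | None = None
    radius: float | None = None
    vertices: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "polygon", "polyline"):
            raise GeometryError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "circle":
            if self.center is None or self.radius is None or self.radius <= 0:
                raise GeometryError("circle ROI needs a center and radius > 0")
        else:
            self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
            n_min = 3 if self.kind == "polygon" else 2
            if self.vertices.shape[0] < n_min or self.vertices.shape[1] != 2:
                raise GeometryError(f"{self.kind} ROI needs >= {n_min} (y,x) vertices")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask for an image of the given ``(y, x)`` shape."""
        if self.kind == "polyline":
            raise GeometryError("a polyline has no interior; use a width-based sampler")
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        if self.kind == "circle":
            cy, cx = self.center
            return (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius**2
        from matplotlib.path import Path as MplPath

        path = MplPath(self.vertices[:, ::-1])  # MplPath wants (x, y)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        # tiny positive radius makes the boundary inclusive
        inside = path.contains_points(pts, radius=1e-9) | path.contains_points(
            pts, radius=-1e-9
        )
        return inside.reshape(shape)

    def recentered(self, center: tuple[float, float]) -> "Roi":
        if self.kind != "circle":
            raise GeometryError("only circle ROIs can be re-centered")
        return Roi("circle", center=center, radius=self.radius, label=self.label)


@dataclass
class RunConfig:
    """All tunable thresholds and calibration overrides, with defaults.

    Defaults equal the acquisition/analysis constants used throughout:
    0.084 um pixels (3x3 px = 0.252 um), 1.0878 s FRAP frames, 0.138 um/s
    transport speed floor, 50 px rolling-ball radius.
    """

    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    z_step_um: float | None = None
    seed: int = 0
    outdir: str = "."
    # granule detection
    k_sigma: float = 3.0
    min_granule_area_px: int = 9
    circ_threshold: float = 0.8
    # transport
    v_min_um_s: float = 0.138
    transport_dt_s: float = 4.84
    # colocalization / spots
    rolling_ball_radius_px: float = 50.0
    spot_psf_sigma_px: float = 1.3
    spot_threshold_factor: float = 6.0
    # FRAP
    frap_dt_s: float = 1.0878
    frap_n_pre: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Image stack I/O (TIFF / OME-TIFF)
# ---------------------------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with calibration metadata."""
    meta = {
        "axes": AXES,
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": stack.z_step_um,
        "PhysicalSizeZUnit": "µm",
        "TimeIncrement": stack.frame_interval_s,
        "TimeIncrementUnit": "s",
    }
    tifffile.imwrite(str(path), stack.pixels, ome=True, metadata=meta)


def _ome_float(xml: str, attr: str) -> float | None:
    m = re.search(rf'{attr}="([0-9.eE+-]+)"', xml)
    return float(m.group(1)) if m else None


def read_stack(path: str | Path, config: RunConfig | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF into a 5-D ``(t,z,c,y,x)`` :class:`ImageStack`.

    Axes are honored per file metadata, not raw array order; missing axes
    get length 1.  Calibration is taken from OME metadata, falling back to
    ``config`` overrides; a multi-frame file with neither raises
    :class:`ConfigurationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes.upper()
            ome = tf.ome_metadata
    except (tifffile.TiffFileError, ValueError) as exc:  # pragma: no cover - rare
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if data.dtype.kind not in "uif":
        raise FormatError(f"unsupported pixel type {data.dtype}")
    # Some writers emit axes letters outside TZCYX (e.g. S for samples).
    axes = axes.replace("S", "C").replace("Q", "T")
    if data.ndim != len(axes):
        raise FormatError(f"axes {axes!r} do not match array rank {data.ndim}")
    for ax in axes:
        if ax not in AXES:
            raise FormatError(f"unsupported axis {ax!r} in {path}")
    # insert missing axes, then order as TZCYX
    for ax in AXES:
        if ax not in axes:
            data = np.expand_dims(data, 0)
            axes = ax + axes
    data = np.moveaxis(data, [axes.index(a) for a in AXES], range(5))

    px = _ome_float(ome, "PhysicalSizeX") if ome else None
    dt = _ome_float(ome, "TimeIncrement") if ome else None
    dz = _ome_float(ome, "PhysicalSizeZ") if ome else None
    if config is not None:
        px = config.pixel_size_um if config.pixel_size_um is not None else px
        dt = config.frame_interval_s if config.frame_interval_s is not None else dt
        dz = config.z_step_um if config.z_step_um is not None else dz
    if px is None:
        raise ConfigurationError(
            f"{path}: no pixel size in metadata and no config override"
        )
    if dt is None:
        if data.shape[0] > 1:
            raise ConfigurationError(
                f"{path}: multi-frame stack without frame interval"
            )
        dt = 1.0
    return ImageStack(data, pixel_size_um=px, frame_interval_s=dt, z_step_um=dz or 1.0)


# ---------------------------------------------------------------------------
# ROI JSON
# ---------------------------------------------------------------------------


def write_rois(rois: Sequence[Roi], path: str | Path) -> None:
    out = []
    for r in rois:
        d: dict = {"kind": r.kind, "label": r.label}
        if r.kind == "circle":
            d["center"] = [float(r.center[0]), float(r.center[1])]
            d["radius"] = float(r.radius)
        else:
            d["vertices"] = np.asarray(r.vertices, dtype=float).tolist()
        out.append(d)
    with open(path, "w") as fh:
        json.dump({"rois": out}, fh, indent=1)


def read_rois(path: str | Path) -> list[Roi]:
    with open(path) as fh:
        data = json.load(fh)
    rois = []
    for d in data["rois"]:
        if d["kind"] == "circle":
            rois.append(
                Roi("circle", center=tuple(d["center"]), radius=d["radius"],
                    label=d.get("label", ""))
            )
        else:
            rois.append(Roi(d["kind"], vertices=np.asarray(d["vertices"]),
                            label=d.get("label", "")))
    return rois


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Dataclass records (one shared schema) to a DataFrame, input order kept."""
    records = list(records)
    if not records:
        return pd.DataFrame()
    if not dataclasses.is_dataclass(records[0]):
        return pd.DataFrame(records)
    fields0 = tuple(f.name for f in dataclasses.fields(records[0]))
    for r in records:
        if not dataclasses.is_dataclass(r) or tuple(
            f.name for f in dataclasses.fields(r)
        ) != fields0:
            raise SchemaError("records do not share one schema")
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=list(fields0))


def write_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write records (dataclasses, dicts, or a DataFrame) as CSV.

    Header always present (header-only file for an empty sequence); floats at
    full repr precision; row order = input order.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
    if df.empty and columns is not None:
        df = pd.DataFrame(columns=list(columns))
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
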