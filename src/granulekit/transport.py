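"""Kymographs, track linking, and granule-transport classification.

A granule is stationary when its mean frame-to-frame speed stays below the
minimum speed limit (default 0.138 um/s, the pixel size per second of the
transport acquisition); otherwise it is anterograde or retrograde by the
sign of its net along-axis displacement (positive = away from the soma).
Motile velocity is averaged over motile frames only (instantaneous speed at
or above the floor); the whole-track mean is also reported.  "Total
displacement" is emitted both as path length (sum of |step|) and as net
displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import GeometryError, ImageStack, Roi


@dataclass
class TransportConfig:
    v_min_um_s: float = 0.138
    dt_s: float = 4.84  # 484 s / 100 frames
    pixel_size_um: float = 0.138

    def __post_init__(self) -> None:
        if self.v_min_um_s <= 0 or self.dt_s <= 0:
            raise ValueError("v_min_um_s and dt_s must be > 0")


@dataclass
class Track:
    """One granule's along-neurite trajectory and its motion statistics."""

    track_id: int
    s_um: np.ndarray                 # position, um from soma (away = +)
    times_s: np.ndarray
    motion_class: str = ""           # stationary | anterograde | retrograde
    mean_speed_um_s: float = 0.0     # whole-track mean |step|/dt
    motile_velocity_um_s: float = 0.0  # mean |step|/dt over motile frames
    net_displacement_um: float = 0.0   # signed, end - start
    path_length_um: float = 0.0        # sum |step|
    n_burst_frames: int = 0
    tie_flag: bool = False


def build_kymograph(
    movie: ImageStack,
    neurite: Roi,
    width_px: int = 5,
    channel: int = 0,
) -> np.ndarray:
    """Position x time kymograph along a polyline neurite.

    Each frame is max-projected over z; for each 1-px arc-length sample
    along the polyline (soma end = row 0) the intensity is the maximum over
    the perpendicular width.  Columns are frames.
    """
    if neurite.kind != "polyline" or len(neurite.vertices) < 2:
        raise GeometryError("neurite must be a polyline with >= 2 vertices")
    verts = np.asarray(neurite.vertices, dtype=float)
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total < 2:
        raise GeometryError("polyline shorter than 2 px")
    n_samples = int(np.floor(total)) + 1
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    samples, normals = [], []
    for s in np.arange(n_samples, dtype=float):
        i = int(np.searchsorted(arc, s, side="right") - 1)
        i = min(i, len(seg) - 1)
        frac = (s - arc[i]) / seg_len[i]
        pt = verts[i] + frac * seg[i]
        tang = seg[i] / seg_len[i]
        samples.append(pt)
        normals.append(np.array([-tang[1], tang[0]]))
    samples = np.array(samples)
    normals = np.array(normals)
    offsets = np.arange(width_px) - (width_px - 1) / 2.0

    kymo = np.zeros((n_samples, movie.n_frames))
    coords_y = samples[:, None, 0] + offsets[None, :] * normals[:, None, 0]
    coords_x = samples[:, None, 1] + offsets[None, :] * normals[:, None, 1]
    for t in range(movie.n_frames):
        img = movie.max_z(t=t, c=channel)
        vals = ndimage.map_coordinates(
            img, [coords_y.ravel(), coords_x.ravel()], order=1, mode="nearest"
        ).reshape(n_samples, width_px)
        kymo[:, t] = vals.max(axis=1)
    return kymo


def link_tracks(
    detections: list[np.ndarray],
    cfg: TransportConfig,
    min_frames: int = 5,
) -> list[Track]:
    """Greedy nearest-neighbor linking of per-frame along-axis detections.

    ``detections[t]`` holds the along-axis positions (um) detected in frame
    ``t``.  Links are made frame-to-frame by smallest jump, capped at
    ``max(3 * v_min * dt, 2 * pixel_size)``; unlinked detections start new
    tracks; tracks shorter than ``min_frames`` are dropped.  Crossing tracks
    are resolved by minimal jump and may swap identities (documented
    limitation).
    """
    max_jump = max(3 * cfg.v_min_um_s * cfg.dt_s, 2 * cfg.pixel_size_um)
    active: list[dict] = []
    done: list[dict] = []
    for t, pos in enumerate(detections):
        pos = list(np.atleast_1d(np.asarray(pos, dtype=float)))
        # candidate (distance, track, detection) pairs, greedy by distance
        pairs = sorted(
            (abs(tr["s"][-1] - p), i_tr, i_p)
            for i_tr, tr in enumerate(active)
            for i_p, p in enumerate(pos)
            if abs(tr["s"][-1] - p) <= max_jump
        )
        used_tr: set[int] = set()
        used_p: set[int] = set()
        for dist, i_tr, i_p in pairs:
            if i_tr in used_tr or i_p in used_p:
                continue
            active[i_tr]["s"].append(pos[i_p])
            active[i_tr]["t"].append(t)
            used_tr.add(i_tr)
            used_p.add(i_p)
        still = []
        for i_tr, tr in enumerate(active):
            if i_tr in used_tr:
                still.append(tr)
            else:
                done.append(tr)
        active = still
        for i_p, p in enumerate(pos):
            if i_p not in used_p:
                active.append({"s": [p], "t": [t]})
    done.extend(active)
    tracks = []
    for i, tr in enumerate(d for d in done if len(d["s"]) >= min_frames):
        tracks.append(
            Track(track_id=i, s_um=np.array(tr["s"]),
                  times_s=np.array(tr["t"], dtype=float) * cfg.dt_s)
        )
    return tracks


def classify_track(track: Track, cfg: TransportConfig) -> Track:
    """Classify one track and fill its motion statistics (in place)."""
    s = np.asarray(track.s_um, dtype=float)
    if len(s) < 5:
        raise ValueError("need >= 5 frames per track")
    dt = np.diff(track.times_s)
    steps = np.diff(s)
    inst = np.abs(steps) / dt
    mean_speed = float(inst.mean())
    net = float(s[-1] - s[0])
    track.mean_speed_um_s = mean_speed
    track.net_displacement_um = net
    track.path_length_um = float(np.abs(steps).sum())
    motile_frames = inst >= cfg.v_min_um_s
    track.motile_velocity_um_s = (
        float(inst[motile_frames].mean()) if motile_frames.any() else 0.0
    )
    med = np.median(inst)
    track.n_burst_frames = int(np.sum(inst > 3 * med)) if med > 0 else 0
    if mean_speed < cfg.v_min_um_s:
        track.motion_class = "stationary"
    elif net > 0:
        track.motion_class = "anterograde"
    elif net < 0:
        track.motion_class = "retrograde"
    else:  # fast but zero net displacement: break the tie to stationary
        track.motion_class = "stationary"
        track.tie_flag = True
    return track


def classify_tracks(
    tracks: list[Track], cfg: TransportConfig | None = None
) -> tuple[list[Track], dict]:
    """Classify every track and compute cohort statistics.

    Cohort: class fractions (sum to 1), per-direction mean +/- SE motile
    velocity, and mean +/- SE path length and net displacement of motile
    tracks.
    """
    cfg = cfg or TransportConfig()
    for tr in tracks:
        classify_track(tr, cfg)
    n = len(tracks)
    cohort: dict = {"n_tracks": n}
    for cls in ("stationary", "anterograde", "retrograde"):
        cohort[f"frac_{cls}"] = (
            sum(t.motion_class == cls for t in tracks) / n if n else 0.0
        )
    def _mean_se(vals: list[float]) -> tuple[float, float]:
        v = np.asarray(vals, dtype=float)
        if len(v) == 0:
            return float("nan"), float("nan")
        return float(v.mean()), (
            float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        )
    for cls in ("anterograde", "retrograde"):
        vel = [t.motile_velocity_um_s for t in tracks if t.motion_class == cls]
        cohort[f"velocity_{cls}_mean"], cohort[f"velocity_{cls}_se"] = _mean_se(vel)
    motile = [t for t in tracks if t.motion_class != "stationary"]
    cohort["path_length_mean"], cohort["path_length_se"] = _mean_se(
        [t.path_length_um for t in motile]
    )
    cohort["net_displacement_mean"], cohort["net_displacement_se"] = _mean_se(
        [abs(t.net_displacement_um) for t in motile]
    )
    return tracks, cohort


def tracks_from_synthetic(raw_tracks: list[dict], dt_s: float = 4.84) -> list[Track]:
    """Adapt generator track dicts to :class:`Track` objects."""
    out = []
    for tr in raw_tracks:
        s = np.asarray(tr["s_um"], dtype=float)
        out.append(Track(track_id=tr["track_id"], s_um=s,
                         times_s=np.arange(len(s)) * dt_s))
    return out
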