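"""EB3 comet velocimetry from kymographs.

A kymograph maps a movie onto (position along a neurite path) x (time):
a particle moving at constant velocity becomes a straight streak whose
slope, scaled by the pixel size and frame interval, is its velocity.
Growth-cone-bound EB3 comets track growing microtubule plus ends, so
the streak slope reads out the plus-end growth velocity (typically
~0.2 µm/s in neurons).

Two readout modes are provided: manual endpoints on the kymograph
(faithful to the classic kymograph + velocity-macro workflow) and an
automatic streak tracker (peak linking across frames followed by a
least-squares slope fit) for analysis at scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks

from .io import px_to_um

#: Paths shorter than this are flagged (segment-length criterion, µm).
MIN_SEGMENT_UM = 20.0


@dataclass
class Kymograph:
    """Distance x time intensity map along a neurite path.

    Rows are positions along the path at 1 px steps, columns are frames.
    """

    map: np.ndarray
    pixel_size: float           # µm/px along the path
    frame_interval_s: float
    line_width_px: int = 3

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=np.float64)
        if self.map.ndim != 2:
            raise ValueError("kymograph map must be 2D")
        if self.path_length_um < MIN_SEGMENT_UM:
            warnings.warn(
                f"path shorter than {MIN_SEGMENT_UM} µm "
                f"({self.path_length_um:.1f} µm)"
            )

    @property
    def path_length_um(self) -> float:
        return px_to_um(self.map.shape[0], self.pixel_size)

    @property
    def n_frames(self) -> int:
        return self.map.shape[1]


@dataclass
class CometTrack:
    """A linear comet track between two (position px, frame) endpoints."""

    start: tuple[float, int]
    end: tuple[float, int]
    velocity_um_s: float
    n_points: int = 2


def _resample_path(polyline_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample an (x, y) polyline at 1 px arc-length steps.

    Returns (points (N, 2) as (row, col), unit normals (N, 2)).
    """
    poly = np.asarray(polyline_xy, dtype=np.float64)
    if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
        raise ValueError("polyline must be >= 2 points of (x, y)")
    rc = poly[:, ::-1]                      # (row, col)
    seg = np.diff(rc, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate polyline")
    s = np.arange(0.0, total, 1.0)
    rows = np.interp(s, cum, rc[:, 0])
    cols = np.interp(s, cum, rc[:, 1])
    pts = np.stack([rows, cols], axis=1)
    tang = np.gradient(pts, axis=0)
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    norm /= np.maximum(np.hypot(norm[:, 0], norm[:, 1])[:, None], 1e-12)
    return pts, norm


def build_kymograph(
    movie: np.ndarray,
    polyline_xy: np.ndarray,
    width_px: int = 3,
    pixel_size: float = 0.325,
    frame_interval_s: float = 2.0,
) -> Kymograph:
    """Kymograph along a polyline with perpendicular averaging.

    The path is resampled at 1 px steps; each kymograph pixel is the
    mean of ``width_px`` bilinear samples taken perpendicular to the
    path at that position, per frame.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError("movie must be (T, Y, X)")
    t, h, w = movie.shape
    pts, normals = _resample_path(polyline_xy)
    if (pts[:, 0].min() < -0.5 or pts[:, 0].max() > h - 0.5
            or pts[:, 1].min() < -0.5 or pts[:, 1].max() > w - 0.5):
        raise ValueError("polyline outside movie bounds")

    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    # sample coordinates: (n_positions, width) for rows and cols
    rows = pts[:, 0:1] + offsets[None, :] * normals[:, 0:1]
    cols = pts[:, 1:2] + offsets[None, :] * normals[:, 1:2]
    coords = np.stack([rows.ravel(), cols.ravel()])

    kym = np.empty((len(pts), t))
    for f in range(t):
        samples = ndi.map_coordinates(movie[f], coords, order=1, mode="nearest")
        kym[:, f] = samples.reshape(len(pts), width_px).mean(axis=1)
    return Kymograph(kym, pixel_size=pixel_size,
                     frame_interval_s=frame_interval_s, line_width_px=width_px)


def velocity_from_endpoints(
    kym: Kymograph, p0: tuple[float, int], p1: tuple[float, int]
) -> CometTrack:
    """Velocity from two (position px, frame) endpoints on the kymograph.

    |Δposition| · pixel_size / (Δframe · frame_interval); orientation of
    the path does not matter (absolute value contract).
    """
    (s0, f0), (s1, f1) = p0, p1
    for s, f in (p0, p1):
        if not (0 <= s <= kym.map.shape[0] and 0 <= f < kym.n_frames):
            raise ValueError("endpoint outside kymograph")
    dframe = abs(f1 - f0)
    if dframe == 0:
        raise ValueError("endpoints span zero frames")
    v = abs(s1 - s0) * kym.pixel_size / (dframe * kym.frame_interval_s)
    return CometTrack(start=(float(s0), int(f0)), end=(float(s1), int(f1)),
                      velocity_um_s=float(v))


def detect_comet_tracks(
    kym: Kymograph,
    min_track_frames: int = 5,
    max_jump_px: float = 4.0,
    peak_rel_height: float = 0.3,
) -> list[CometTrack]:
    """Automatic streak detection by per-frame peak linking.

    For every frame (column) the local intensity maxima above a relative
    height threshold are found; maxima in consecutive frames are linked
    greedily to the nearest peak within ``max_jump_px``.  Chains of at
    least ``min_track_frames`` points are fit with a least-squares line
    whose slope gives the velocity.
    """
    m = kym.map
    bg = np.median(m)
    amp = m.max() - bg
    if amp <= 0:
        return []
    thr = bg + peak_rel_height * amp
    peaks_per_frame: list[np.ndarray] = []
    for f in range(kym.n_frames):
        idx, _ = find_peaks(m[:, f], height=thr)
        peaks_per_frame.append(idx.astype(np.float64))

    # greedy nearest-neighbor linking across consecutive frames
    open_tracks: list[list[tuple[float, int]]] = []
    done: list[list[tuple[float, int]]] = []
    for f, peaks in enumerate(peaks_per_frame):
        unmatched = list(peaks)
        survivors = []
        for tr in open_tracks:
            last_pos, last_f = tr[-1]
            if f - last_f > 2:                  # allow 1-frame dropouts
                done.append(tr)
                continue
            if unmatched:
                d = [abs(p - last_pos) for p in unmatched]
                j = int(np.argmin(d))
                if d[j] <= max_jump_px * (f - last_f):
                    tr.append((unmatched.pop(j), f))
            survivors.append(tr)
        open_tracks = survivors
        for p in unmatched:
            open_tracks.append([(p, f)])
    done.extend(open_tracks)

    tracks = []
    for tr in done:
        if len(tr) < min_track_frames:
            continue
        pos = np.array([p for p, _ in tr])
        frm = np.array([f for _, f in tr])
        slope = np.polyfit(frm, pos, 1)[0]      # px / frame
        v = abs(slope) * kym.pixel_size / kym.frame_interval_s
        tracks.append(CometTrack(
            start=(float(pos[0]), int(frm[0])),
            end=(float(pos[-1]), int(frm[-1])),
            velocity_um_s=float(v), n_points=len(tr),
        ))
    return tracks


def measure_velocity(
    kym: Kymograph,
    endpoints: tuple[tuple[float, int], tuple[float, int]] | None = None,
    **auto_kwargs,
) -> tuple[list[CometTrack], float]:
    """Comet velocities from a kymograph.

    With ``endpoints`` the single track they define is measured (manual
    mode); otherwise streaks are detected automatically.  Returns
    (tracks, mean velocity µm/s) — the per-segment mean is the readout
    aggregated per well downstream.
    """
    if endpoints is not None:
        tracks = [velocity_from_endpoints(kym, *endpoints)]
    else:
        tracks = detect_comet_tracks(kym, **auto_kwargs)
    if not tracks:
        return [], float("nan")
    return tracks, float(np.mean([t.velocity_um_s for t in tracks]))
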