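"""Synthetic fluorescence-microscopy data with known ground truth.

Every input the analysis pipeline consumes can be generated here:
nuclei + dead-cell (PI) fields, neurite fields with a co-varying
acetylated-tubulin channel and synaptic puncta, fibril fields mixing
elongated rods with round blobs, bursting multi-neuron calcium
recordings with a terminal glutamate-response epoch, and comet movies of
constant-velocity particles along a neurite path.

Rendering model
---------------
Objects are drawn as hard shapes (ellipses, dilated random-walk tubes,
disks, Gaussian spots), smoothed with a small Gaussian standing in for
the microscope PSF, then corrupted with per-pixel Poisson shot noise and
Gaussian read noise on top of a constant background offset.  Intensities
are arbitrary detector units on a common scale (background ~20-100,
objects ~150-700).  Photobleaching, stage drift and a physically
realistic PSF are deliberately out of scope.

Determinism: identical parameters + seed give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, morphology
from skimage.measure import regionprops

from .io import FieldImage, area_um2, um_to_px, um2_to_px_area
from .calcium import CalciumRecording

DEFAULT_PIXEL_SIZE = 0.325   # µm/px, 40x objective class
DEFAULT_SHAPE = (1024, 1024)


@dataclass
class SynthGroundTruth:
    """Ground truth accompanying a rendered object set.

    Only the fields relevant to the generator that produced it are set.
    """

    seed: int
    pixel_size: float = DEFAULT_PIXEL_SIZE
    # nuclei fields
    nuclei: list[dict] | None = None          # centroid (r,c) px, area µm², is_dead
    # neurite fields
    neurite_mask: np.ndarray | None = None    # boolean truth mask
    neurite_area_um2: float | None = None
    spot_centroids: list[tuple[float, float]] | None = None
    n_spots: int | None = None
    coloc_rho: float | None = None
    # fibril fields
    fibril_particles: list[dict] | None = None  # area µm², circularity, is_fibril
    fibril_load_um2: float | None = None
    # calcium recordings
    is_neuron: np.ndarray | None = None
    is_active: np.ndarray | None = None
    active_fraction: float | None = None
    burst_times: np.ndarray | None = None     # population burst times, s
    event_times: list[np.ndarray] | None = None  # per cell
    sync_prob: float | None = None
    # comet movies
    comet_velocities: np.ndarray | None = None  # µm/s
    comet_offsets_px: np.ndarray | None = None
    polyline: np.ndarray | None = None          # (N, 2) of (x, y) px
    extra: dict[str, Any] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        """Plain-python dict for JSON serialization (large masks excluded)."""
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "neurite_mask":
                continue
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, list):
                v = [x.tolist() if isinstance(x, np.ndarray) else x for x in v]
            out[f.name] = v
        return out


def _add_noise(img: np.ndarray, rng: np.random.Generator,
               read_noise: float, shot_noise: bool = True) -> np.ndarray:
    """Poisson shot noise on the (non-negative) signal plus Gaussian read noise."""
    out = img.astype(np.float64)
    if shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if read_noise > 0:
        out = out + rng.normal(0.0, read_noise, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# nuclei / cytotoxicity fields
# ---------------------------------------------------------------------------

def synth_nuclei_field(
    n_cells: int,
    dead_fraction: float = 0.0,
    mean_area_um2: float = 120.0,
    crowding: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    amplitude: float = 600.0,
    background: float = 100.0,
    read_noise: float = 8.0,
    shot_noise: bool = True,
) -> tuple[FieldImage, FieldImage, SynthGroundTruth]:
    """Render a nuclear-counterstain field and its dead-cell (PI) channel.

    Exactly ``round(dead_fraction * n_cells)`` nuclei carry high PI
    signal.  With ``crowding > 0`` a fraction of nuclei is placed as
    touching pairs to exercise watershed splitting downstream.
    """
    if not 0.0 <= dead_fraction <= 1.0:
        raise ValueError("dead_fraction must be in [0, 1]")
    if not 0.0 <= crowding <= 1.0:
        raise ValueError("crowding must be in [0, 1]")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")

    rng = np.random.default_rng(seed)
    h, w = shape
    nuc = np.zeros(shape, dtype=np.float64)
    pi = np.zeros(shape, dtype=np.float64)

    mean_r_px = um_to_px(np.sqrt(mean_area_um2 / np.pi), pixel_size)
    margin = int(np.ceil(mean_r_px * 1.6)) + 2

    n_pairs = int(round(crowding * n_cells / 2.0))
    n_single = n_cells - 2 * n_pairs

    areas = mean_area_um2 * rng.uniform(0.85, 1.25, size=n_cells)
    radii = np.array([um_to_px(np.sqrt(a / np.pi), pixel_size) for a in areas])

    # dart-throwing placement with a minimum separation for singles;
    # pairs are placed touching (slightly overlapping) by their own radii
    centers: list[tuple[float, float]] = []
    min_sep = 2.6 * mean_r_px

    def _free(r, c, sep):
        return all((r - r0) ** 2 + (c - c0) ** 2 >= sep**2 for r0, c0 in centers)

    for _ in range(n_single):
        for _attempt in range(2000):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if _free(r, c, min_sep):
                break
        centers.append((r, c))
    for k in range(n_pairs):
        for _attempt in range(2000):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if _free(r, c, min_sep * 1.5):
                break
        theta = rng.uniform(0, 2 * np.pi)
        i1, i2 = n_single + 2 * k, n_single + 2 * k + 1
        d = 0.85 * (radii[i1] + radii[i2])
        centers.append((r, c))
        centers.append((r + d * np.sin(theta), c + d * np.cos(theta)))

    order = rng.permutation(len(centers))
    centers = [centers[i] for i in order]
    areas = areas[order]
    n_dead = int(round(dead_fraction * n_cells))
    dead_idx = set(rng.choice(n_cells, size=n_dead, replace=False).tolist()) \
        if n_dead else set()

    truth_nuclei = []
    for i, (r, c) in enumerate(centers):
        area = float(areas[i])
        area_px = um2_to_px_area(area, pixel_size)
        ecc = rng.uniform(0.75, 1.0)              # axis ratio b/a
        a = np.sqrt(area_px / (np.pi * ecc))
        b = a * ecc
        rot = rng.uniform(0, np.pi)
        rr, cc = draw.ellipse(r, c, a, b, shape=shape, rotation=rot)
        inten = amplitude * rng.uniform(0.8, 1.2)
        nuc[rr, cc] = np.maximum(nuc[rr, cc], inten)
        is_dead = i in dead_idx
        if is_dead:
            pi[rr, cc] = np.maximum(pi[rr, cc], inten)
        truth_nuclei.append(
            {"centroid": (float(r), float(c)), "area_um2": float(area),
             "is_dead": bool(is_dead)}
        )

    nuc = ndi.gaussian_filter(nuc, 1.5) + background
    pi = ndi.gaussian_filter(pi, 1.5) + background * 0.3
    nuc = _add_noise(nuc, rng, read_noise, shot_noise)
    pi = _add_noise(pi, rng, read_noise, shot_noise)

    truth = SynthGroundTruth(seed=seed, pixel_size=pixel_size,
                             nuclei=truth_nuclei)
    return (
        FieldImage(nuc, "nuclei", pixel_size),
        FieldImage(pi, "PI", pixel_size),
        truth,
    )


# ---------------------------------------------------------------------------
# neurite / synapse / colocalization fields
# ---------------------------------------------------------------------------

def _random_walk_path(rng, start, heading, n_steps, turn_sd, shape):
    """Persistent random walk at 1 px steps, reflected at image borders."""
    h, w = shape
    r, c = start
    pts = np.empty((n_steps, 2))
    for i in range(n_steps):
        heading += rng.normal(0.0, turn_sd)
        r += np.sin(heading)
        c += np.cos(heading)
        if r < 2 or r > h - 3:
            heading = -heading
            r = np.clip(r, 2, h - 3)
        if c < 2 or c > w - 3:
            heading = np.pi - heading
            c = np.clip(c, 2, w - 3)
        pts[i] = (r, c)
    return pts


def synth_neurite_field(
    total_neurite_length_um: float = 6000.0,
    synapse_density_true: float = 0.05,
    coloc_rho: float = 0.5,
    seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    trunk_fraction: float = 0.55,
    trunk_intensity: float = 180.0,
    branch_intensity: float = 45.0,
    background: float = 20.0,
    read_noise: float = 3.0,
    shot_noise: bool = True,
    spot_area_um2: float = 1.33,
    spot_amplitude: float = 150.0,
    n_subsize_spots: int = 0,
    subsize_spot_area_um2: float = 0.5,
    neurite_bleedthrough: float = 0.0,
) -> tuple[FieldImage, FieldImage, FieldImage, SynthGroundTruth]:
    """Render a neurite network with acetylated and synaptophysin channels.

    Neurites are persistent random-walk tubes in two intensity tiers:
    bright trunks (5 px wide) and faint branches (2 px), exercising the
    dual-mask segmentation design.  The acetylated channel equals a
    mixture of the (standardized) tubulin signal and independent noise
    inside the truth mask, calibrated so the within-mask sample Pearson
    correlation approaches ``coloc_rho``.  Synaptophysin puncta are
    placed on the mask at ``synapse_density_true`` spots per µm² of mask
    area; ``n_subsize_spots`` optionally adds puncta below the standard
    0.75 µm² particle filter as negative controls.
    """
    if synapse_density_true < 0:
        raise ValueError("synapse_density_true must be >= 0")
    if not -1.0 <= coloc_rho <= 1.0:
        raise ValueError("coloc_rho must be in [-1, 1]")

    rng = np.random.default_rng(seed)
    h, w = shape
    total_px = um_to_px(total_neurite_length_um, pixel_size)

    trunk_skel = np.zeros(shape, dtype=bool)
    branch_skel = np.zeros(shape, dtype=bool)
    trunk_pts_all = []

    budget = total_px * trunk_fraction
    while budget > 0:
        n_steps = int(min(budget, rng.uniform(200, 500)))
        if n_steps < 10:
            break
        start = (rng.uniform(5, h - 5), rng.uniform(5, w - 5))
        pts = _random_walk_path(rng, start, rng.uniform(0, 2 * np.pi),
                                n_steps, 0.06, shape)
        idx = np.round(pts).astype(int)
        trunk_skel[idx[:, 0], idx[:, 1]] = True
        trunk_pts_all.append(pts)
        budget -= n_steps

    trunk_pts = np.concatenate(trunk_pts_all) if trunk_pts_all else np.empty((0, 2))
    budget = total_px * (1.0 - trunk_fraction)
    while budget > 0 and len(trunk_pts):
        n_steps = int(min(budget, rng.uniform(60, 200)))
        if n_steps < 10:
            break
        start = trunk_pts[rng.integers(len(trunk_pts))]
        pts = _random_walk_path(rng, tuple(start), rng.uniform(0, 2 * np.pi),
                                n_steps, 0.15, shape)
        idx = np.round(pts).astype(int)
        branch_skel[idx[:, 0], idx[:, 1]] = True
        budget -= n_steps

    trunk_mask = morphology.dilation(trunk_skel, morphology.disk(2))
    branch_mask = morphology.dilation(branch_skel, morphology.disk(1))
    mask = trunk_mask | branch_mask

    render = np.where(trunk_mask, trunk_intensity, 0.0)
    render = np.where(branch_mask & ~trunk_mask, branch_intensity, render)
    tub = ndi.gaussian_filter(render, 1.0) + background
    tub = _add_noise(tub, rng, read_noise, shot_noise)

    # acetylated channel: within-mask correlation engineered to coloc_rho
    acet = rng.normal(0.0, 1.0, size=shape)
    tvals = tub[mask]
    if tvals.size > 1 and np.std(tvals) > 0:
        z = (tvals - tvals.mean()) / tvals.std()
        mix = coloc_rho * z + np.sqrt(max(0.0, 1 - coloc_rho**2)) * acet[mask]
        acet_img = np.full(shape, background, dtype=np.float64)
        acet_img[mask] = np.clip(100.0 + 40.0 * mix, 0, None)
    else:
        acet_img = np.full(shape, background, dtype=np.float64)
    acet_img = acet_img + rng.normal(0.0, read_noise * 0.5, size=shape)
    acet_img = np.clip(acet_img, 0, None)

    # synaptophysin channel: puncta on the mask + faint neurite glow
    mask_area = area_um2(int(mask.sum()), pixel_size)
    n_spots = int(round(synapse_density_true * mask_area))
    mask_coords = np.argwhere(mask)
    spot_centroids: list[tuple[float, float]] = []
    syn = neurite_bleedthrough * ndi.gaussian_filter(render, 1.0)
    occupied = np.zeros(shape, dtype=bool)

    def _place_spots(n, area, amp):
        r_px = np.sqrt(um2_to_px_area(area, pixel_size) / np.pi)
        placed = 0
        if len(mask_coords) == 0:
            return
        perm = rng.permutation(len(mask_coords))
        sep = int(np.ceil(4 * r_px)) + 2
        for j in perm:
            if placed >= n:
                break
            r, c = mask_coords[j]
            if occupied[max(0, r - sep):r + sep, max(0, c - sep):c + sep].any():
                continue
            rr, cc = draw.disk((r, c), r_px, shape=shape)
            syn[rr, cc] += amp
            occupied[r, c] = True
            spot_centroids.append((float(r), float(c)))
            placed += 1

    _place_spots(n_spots, spot_area_um2, spot_amplitude)
    n_main = len(spot_centroids)
    _place_spots(n_subsize_spots, subsize_spot_area_um2, spot_amplitude)

    # PSF sigma ~0.21*lambda/NA ~ 0.11 µm ~ 0.35 px at this calibration
    syn = ndi.gaussian_filter(syn, 0.35) + background
    syn = _add_noise(syn, rng, read_noise, shot_noise)

    truth = SynthGroundTruth(
        seed=seed, pixel_size=pixel_size, neurite_mask=mask,
        neurite_area_um2=mask_area, spot_centroids=spot_centroids,
        n_spots=n_main, coloc_rho=coloc_rho,
        extra={"total_neurite_length_um": total_neurite_length_um,
               "synapse_density_true": synapse_density_true,
               "n_subsize_spots": len(spot_centroids) - n_main},
    )
    return (
        FieldImage(tub, "tubulin", pixel_size),
        FieldImage(acet_img, "acetylated", pixel_size),
        FieldImage(syn, "synaptophysin", pixel_size),
        truth,
    )


# ---------------------------------------------------------------------------
# fibril fields
# ---------------------------------------------------------------------------

def synth_fibril_field(
    n_fibrils: int,
    n_round_blobs: int = 0,
    seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    rod_length_um: tuple[float, float] = (20.0, 28.0),
    rod_width_um: float = 1.6,
    blob_radius_um: tuple[float, float] = (2.6, 3.3),
    amplitude: float = 200.0,
    background: float = 20.0,
    read_noise: float = 3.0,
    shot_noise: bool = True,
) -> tuple[FieldImage, np.ndarray, SynthGroundTruth]:
    """Render an amyloid-dye field of curved rods plus round blobs.

    Rods are gently curved tubes sized so that area >= 15 µm² and
    circularity < 0.30 hold by construction; blobs are discs with
    circularity > 0.6, serving as negative controls for the particle
    filter.  The truth lists each particle's area and circularity as
    measured on its own noiseless render (Crofton perimeter).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    canvas = np.zeros(shape, dtype=bool)
    occupancy = np.zeros(shape, dtype=bool)
    particles: list[dict] = []
    rod_rad_px = max(1, int(round(um_to_px(rod_width_um / 2, pixel_size))))
    sep = morphology.disk(6)

    def _try_place(render_fn, max_attempts=200):
        for _ in range(max_attempts):
            piece = render_fn()
            if piece is None:
                continue
            grown = morphology.dilation(piece, sep)
            if not (grown & occupancy).any():
                canvas[piece] = True
                occupancy[grown] = True
                return piece
        return None

    def _rod():
        length_px = um_to_px(rng.uniform(*rod_length_um), pixel_size)
        margin = int(length_px) + 10
        if margin * 2 >= min(h, w):
            return None
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        heading = rng.uniform(0, 2 * np.pi)
        curv = rng.uniform(-0.01, 0.01)
        skel = np.zeros(shape, dtype=bool)
        for _ in range(int(length_px)):
            heading += curv
            r += np.sin(heading)
            c += np.cos(heading)
            if not (2 <= r < h - 2 and 2 <= c < w - 2):
                return None
            skel[int(round(r)), int(round(c))] = True
        return morphology.dilation(skel, morphology.disk(rod_rad_px))

    def _blob():
        rad = um_to_px(rng.uniform(*blob_radius_um), pixel_size)
        m = int(rad) + 5
        r = rng.uniform(m, h - m)
        c = rng.uniform(m, w - m)
        piece = np.zeros(shape, dtype=bool)
        rr, cc = draw.disk((r, c), rad, shape=shape)
        piece[rr, cc] = True
        return piece

    def _measure(piece, is_fibril):
        props = regionprops(piece.astype(np.uint8))[0]
        per = props.perimeter_crofton
        a_um2 = area_um2(props.area, pixel_size)
        circ = float(np.clip(4 * np.pi * props.area / per**2, 0, 1)) if per > 0 else 1.0
        particles.append({"area_um2": float(a_um2), "circularity": circ,
                          "centroid": tuple(map(float, props.centroid)),
                          "is_fibril": bool(is_fibril)})

    for _ in range(n_fibrils):
        piece = _try_place(_rod)
        if piece is not None:
            _measure(piece, True)
    for _ in range(n_round_blobs):
        piece = _try_place(_blob)
        if piece is not None:
            _measure(piece, False)

    img = ndi.gaussian_filter(canvas.astype(np.float64) * amplitude, 1.0) + background
    img = _add_noise(img, rng, read_noise, shot_noise)

    load = sum(p["area_um2"] for p in particles if p["is_fibril"])
    truth = SynthGroundTruth(seed=seed, pixel_size=pixel_size,
                             fibril_particles=particles,
                             fibril_load_um2=float(load))
    return FieldImage(img, "pFTAA", pixel_size), canvas, truth


# ---------------------------------------------------------------------------
# calcium recordings
# ---------------------------------------------------------------------------

def synth_calcium_recording(
    n_cells: int = 50,
    neuron_fraction: float = 0.8,
    active_fraction: float = 0.6,
    burst_rate_per_min: float = 3.0,
    sync_prob: float = 0.9,
    duration_s: float = 260.0,
    fps: float = 2.0,
    glut_window_s: float = 20.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    transient_amplitude: float = 0.5,
    decay_tau_s: float = 1.5,
    jitter_sd_s: float = 0.15,
    glut_factor: float = 3.0,
) -> tuple[CalciumRecording, SynthGroundTruth]:
    """Simulate a bursting multi-neuron calcium recording.

    Population burst times follow a Poisson process at
    ``burst_rate_per_min``; each active neuron joins each burst with
    probability ``sync_prob``.  Calcium transients have an instantaneous
    rise and exponential decay (tau 1.5 s, spanning ~3 frames at 2 fps)
    on a baseline of 1 with Gaussian noise.  During the final
    ``glut_window_s`` seconds every neuron — and only neurons — shows a
    sustained glutamate response, modeled as a step of
    ``glut_factor x transient_amplitude`` held to the end of the
    recording; non-neuronal cells stay flat except for noise.
    """
    for name, v in [("neuron_fraction", neuron_fraction),
                    ("active_fraction", active_fraction),
                    ("sync_prob", sync_prob)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    n_frames = int(round(duration_s * fps))
    if n_frames < 10:
        raise ValueError("duration_s * fps must give at least 10 frames")
    if burst_rate_per_min < 0 or noise_sd < 0 or n_cells < 0:
        raise ValueError("invalid negative parameter")

    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    stim_start = n_frames - int(round(glut_window_s * fps))
    spont_end_s = stim_start / fps

    n_neurons = int(round(n_cells * neuron_fraction))
    n_active = int(round(n_neurons * active_fraction))
    is_neuron = np.zeros(n_cells, dtype=bool)
    is_neuron[:n_neurons] = True
    is_active = np.zeros(n_cells, dtype=bool)
    active_ids = rng.choice(n_neurons, size=n_active, replace=False) \
        if n_active else np.array([], dtype=int)
    is_active[active_ids] = True

    # homogeneous Poisson process on the spontaneous epoch
    rate_per_s = burst_rate_per_min / 60.0
    n_bursts = rng.poisson(rate_per_s * spont_end_s)
    burst_times = np.sort(rng.uniform(2.0, spont_end_s - 2.0, size=n_bursts)) \
        if n_bursts else np.array([])

    traces = np.ones((n_cells, n_frames), dtype=np.float64)
    event_times: list[np.ndarray] = []
    for i in range(n_cells):
        ev = []
        if is_active[i]:
            joins = rng.random(len(burst_times)) < sync_prob
            for bt in burst_times[joins]:
                et = bt + rng.normal(0.0, jitter_sd_s)
                et = float(np.clip(et, 0.0, spont_end_s - 1e-3))
                ev.append(et)
                resp = np.where(t >= et,
                                np.exp(-(t - et) / decay_tau_s), 0.0)
                traces[i] += transient_amplitude * resp
        if is_neuron[i]:
            traces[i, stim_start:] += glut_factor * transient_amplitude
        event_times.append(np.sort(np.asarray(ev)))

    f0 = rng.uniform(0.8, 1.2, size=n_cells)
    traces = traces * f0[:, None]
    traces += rng.normal(0.0, noise_sd, size=traces.shape) * f0[:, None]

    rec = CalciumRecording(
        traces=traces, fps=fps, duration_s=duration_s,
        stim_window=(stim_start, n_frames),
        cell_ids=[f"cell{i:03d}" for i in range(n_cells)],
    )
    truth = SynthGroundTruth(
        seed=seed, is_neuron=is_neuron, is_active=is_active,
        active_fraction=active_fraction, burst_times=burst_times,
        event_times=event_times, sync_prob=sync_prob,
        extra={"burst_rate_per_min": burst_rate_per_min,
               "spontaneous_duration_s": spont_end_s},
    )
    return rec, truth


def synth_calcium_movie(
    rec: CalciumRecording,
    shape: tuple[int, int] = (256, 256),
    cell_radius_px: float = 6.0,
    gain: float = 100.0,
    background: float = 10.0,
    read_noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a recording as a movie plus matching ROI label image.

    Each cell is a disk whose per-frame mean equals
    ``background + gain * trace``; with ``read_noise = 0`` trace
    extraction recovers the rendered amplitudes exactly (up to disk
    rasterization).  Returns (movie (T, Y, X), roi label image (Y, X)).
    """
    rng = np.random.default_rng(seed)
    n_cells, n_frames = rec.traces.shape
    h, w = shape
    rois = np.zeros(shape, dtype=np.int32)
    centers = []
    margin = int(cell_radius_px) + 3
    for i in range(n_cells):
        for _ in range(5000):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all((r - r0) ** 2 + (c - c0) ** 2 > (2.5 * cell_radius_px) ** 2
                   for r0, c0 in centers):
                break
        centers.append((r, c))
        rr, cc = draw.disk((r, c), cell_radius_px, shape=shape)
        rois[rr, cc] = i + 1

    movie = np.full((n_frames, h, w), background, dtype=np.float64)
    for i in range(n_cells):
        m = rois == i + 1
        movie[:, m] += gain * rec.traces[i][:, None]
    if read_noise > 0:
        movie += rng.normal(0.0, read_noise, size=movie.shape)
    return movie, rois


# ---------------------------------------------------------------------------
# comet movies
# ---------------------------------------------------------------------------

def synth_comet_movie(
    n_comets: int = 10,
    velocity_um_s: float = 0.2,
    path_length_um: float = 40.0,
    frame_interval_s: float = 2.0,
    n_frames: int = 31,
    seed: int = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    spot_sigma_px: float = 1.3,
    amplitude: float = 150.0,
    background: float = 20.0,
    read_noise: float = 3.0,
    shot_noise: bool = True,
) -> tuple[np.ndarray, np.ndarray, SynthGroundTruth]:
    """Render plus-end comets advancing along a gently curved neurite path.

    Comets are Gaussian spots moving at constant ``velocity_um_s`` with
    staggered start offsets chosen so every comet stays on the path for
    the whole movie.  Returns (movie (T, Y, X), polyline (N, 2) of
    (x, y) px, truth with per-comet velocities).
    """
    if velocity_um_s < 0:
        raise ValueError("velocity must be >= 0")
    rng = np.random.default_rng(seed)
    path_len_px = um_to_px(path_length_um, pixel_size)

    # gently curved path across a canvas sized to fit it
    n_pts = int(np.ceil(path_len_px))
    heading = rng.uniform(0, 2 * np.pi)
    curv = rng.uniform(-0.004, 0.004)
    pts = np.empty((n_pts, 2))
    r = c = 0.0
    for i in range(n_pts):
        heading += curv
        r += np.sin(heading)
        c += np.cos(heading)
        pts[i] = (r, c)
    pad = 8.0
    pts[:, 0] -= pts[:, 0].min() - pad
    pts[:, 1] -= pts[:, 1].min() - pad
    h = int(np.ceil(pts[:, 0].max() + pad))
    w = int(np.ceil(pts[:, 1].max() + pad))

    v_px_frame = um_to_px(velocity_um_s * frame_interval_s, pixel_size)
    travel = v_px_frame * (n_frames - 1)
    usable = max(path_len_px - travel - 4.0, 0.0)
    base = np.linspace(0.0, usable, n_comets, endpoint=True) if n_comets else []
    offsets = np.asarray([b + rng.uniform(-0.5, 0.5) for b in base])
    offsets = np.clip(offsets, 0, max(usable, 0))

    movie = np.full((n_frames, h, w), background, dtype=np.float64)
    half = int(np.ceil(4 * spot_sigma_px))
    for f in range(n_frames):
        frame = movie[f]
        for off in offsets:
            s = off + v_px_frame * f
            if not 0 <= s < n_pts - 1:
                continue
            i0 = int(s)
            frac = s - i0
            rr = pts[i0, 0] * (1 - frac) + pts[i0 + 1, 0] * frac
            cc = pts[i0, 1] * (1 - frac) + pts[i0 + 1, 1] * frac
            r0, r1 = int(rr) - half, int(rr) + half + 1
            c0, c1 = int(cc) - half, int(cc) + half + 1
            ys, xs = np.mgrid[max(0, r0):min(h, r1), max(0, c0):min(w, c1)]
            frame[ys, xs] += amplitude * np.exp(
                -((ys - rr) ** 2 + (xs - cc) ** 2) / (2 * spot_sigma_px**2)
            )
    for f in range(n_frames):
        movie[f] = _add_noise(movie[f], rng, read_noise, shot_noise)

    polyline_xy = pts[:, ::-1].copy()   # (x, y) convention for path files
    truth = SynthGroundTruth(
        seed=seed, pixel_size=pixel_size,
        comet_velocities=np.full(len(offsets), velocity_um_s),
        comet_offsets_px=offsets, polyline=polyline_xy,
        extra={"frame_interval_s": frame_interval_s,
               "path_length_um": path_length_um},
    )
    return movie, polyline_xy, truth
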