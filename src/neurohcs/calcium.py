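"""Functional-connectivity analysis of calcium imaging recordings.

Workflow: traces are extracted as per-frame ROI means, normalized to
ΔF/F0 against a rolling low-percentile baseline, and gated into neurons
vs non-neuronal cells by their response to a terminal glutamate pulse
(neurons respond with a sustained calcium rise; glia do not).  Peaks are
detected per neuron, then network-level metrics are computed: the
percentage of active neurons, the frequency of synchronous network
bursts, and the burst correlation — the mean of the off-diagonal
pairwise Pearson correlation matrix between all neuron traces in the
field of view.

Fields with fewer than 5 active neurons are flagged "not determined"
(ND) and their burst metrics reported as undefined.

The peak and burst criteria are reconstructions (the detection
parameters are not fixed by any published standard); all thresholds are
exposed and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks

#: Fewer active neurons than this per field -> network metrics "not determined".
ND_MIN_ACTIVE = 5


@dataclass
class CalciumRecording:
    """cells x frames fluorescence matrix with acquisition metadata.

    ``stim_window`` is the (start, stop) frame interval of the terminal
    glutamate stimulation epoch; it is ``None`` for recordings with a
    genetically encoded, neuron-restricted indicator, where no
    pharmacological gating is needed.
    """

    traces: np.ndarray
    fps: float
    duration_s: float
    stim_window: tuple[int, int] | None = None
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=np.float64))
        n_frames = self.traces.shape[1]
        if n_frames != int(round(self.duration_s * self.fps)):
            raise ValueError(
                f"frames ({n_frames}) != round(duration_s * fps) "
                f"({int(round(self.duration_s * self.fps))})"
            )
        if self.stim_window is not None:
            s, e = self.stim_window
            if not (0 <= s < e <= n_frames):
                raise ValueError("stim_window outside recording")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i:03d}" for i in range(self.traces.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def spont_slice(self) -> slice:
        """Frames of spontaneous activity (stimulation epoch excluded)."""
        if self.stim_window is None:
            return slice(0, self.n_frames)
        return slice(0, self.stim_window[0])


@dataclass
class CellClassification:
    is_neuron: np.ndarray
    #: subpopulation label per cell; None for non-neurons
    subpopulation: list[str | None] | None = None
    #: True when no stimulation window was present and all cells were kept
    ungated: bool = False

    def __post_init__(self) -> None:
        self.is_neuron = np.asarray(self.is_neuron, dtype=bool)
        if self.subpopulation is not None:
            for lbl, neu in zip(self.subpopulation, self.is_neuron):
                if lbl is not None and not neu:
                    raise ValueError("subpopulation defined for a non-neuron")


@dataclass
class EventTrains:
    """Per-neuron sorted peak times (s) and the ΔF/F0 traces they came from."""

    peak_times: list[np.ndarray]
    dff: np.ndarray
    fps: float
    analyzed_duration_s: float


@dataclass
class NetworkActivityMetrics:
    pct_active: float
    n_active: int
    n_neurons: int
    burst_frequency: float      # bursts/min; NaN when ND
    burst_correlation: float    # mean pairwise Pearson r; NaN when ND
    nd_flag: bool
    subgroup: str | None = None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# trace extraction and normalization
# ---------------------------------------------------------------------------

def extract_traces(
    movie: np.ndarray,
    rois: np.ndarray,
    fps: float,
    stim_window: tuple[int, int] | None = None,
) -> CalciumRecording:
    """Per-frame mean intensity within each labeled ROI.

    Empty ROI labels are excluded with a warning.
    """
    movie = np.asarray(movie)
    rois = np.asarray(rois)
    if movie.ndim != 3 or rois.shape != movie.shape[1:]:
        raise ValueError("movie must be (T, Y, X) with matching ROI geometry")
    present = set(np.unique(rois).tolist()) - {0}
    kept, ids = [], []
    for lab in range(1, int(rois.max()) + 1):
        if lab not in present:
            warnings.warn(f"ROI {lab} is empty; excluded")
            continue
        kept.append(lab)
        ids.append(f"roi{int(lab):03d}")
    traces = np.empty((len(kept), movie.shape[0]))
    for t in range(movie.shape[0]):
        means = ndi.mean(movie[t], labels=rois, index=kept)
        traces[:, t] = means
    return CalciumRecording(
        traces=traces, fps=fps, duration_s=movie.shape[0] / fps,
        stim_window=stim_window, cell_ids=ids,
    )


def delta_f_over_f(
    traces: np.ndarray,
    fps: float,
    baseline_percentile: float = 10.0,
    baseline_window_s: float = 30.0,
) -> np.ndarray:
    """ΔF/F0 with F0 a rolling low-percentile baseline per cell."""
    traces = np.atleast_2d(np.asarray(traces, dtype=np.float64))
    if np.isnan(traces).all(axis=1).any():
        raise ValueError("all-NaN trace")
    win = max(3, int(round(baseline_window_s * fps)))
    f0 = ndi.percentile_filter(traces, baseline_percentile, size=(1, win),
                               mode="nearest")
    f0 = np.where(np.abs(f0) < 1e-12, 1e-12, f0)
    return (traces - f0) / f0


def _robust_sd(x: np.ndarray, axis=None) -> np.ndarray:
    """1.4826 x median absolute deviation (consistent for a Gaussian)."""
    med = np.median(x, axis=axis, keepdims=True)
    return 1.4826 * np.median(np.abs(x - med), axis=axis)


# ---------------------------------------------------------------------------
# neuron gating
# ---------------------------------------------------------------------------

def classify_glutamate_responders(
    rec: CalciumRecording,
    response_factor: float = 5.0,
    baseline_percentile: float = 10.0,
) -> CellClassification:
    """Gate neurons by their sustained response to the glutamate pulse.

    A cell is a neuron when its mean ΔF/F0 inside the stimulation window
    exceeds ``response_factor`` times the robust SD of its pre-stimulus
    ΔF/F0.  Without a stimulation window (neuron-restricted indicator
    mode) classification is skipped: all cells are retained and the
    result is flagged ``ungated``.
    """
    if rec.stim_window is None:
        warnings.warn("no stimulation window: glutamate gating skipped, "
                      "all cells retained")
        return CellClassification(
            is_neuron=np.ones(rec.n_cells, dtype=bool), ungated=True
        )
    s, e = rec.stim_window
    dff = delta_f_over_f(rec.traces, rec.fps,
                         baseline_percentile=baseline_percentile)
    pre = dff[:, :s]
    sd = np.maximum(_robust_sd(pre, axis=1), 1e-9)
    resp = dff[:, s:e].mean(axis=1)
    return CellClassification(is_neuron=resp > response_factor * sd)


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def detect_peaks(
    trace: np.ndarray,
    fps: float,
    baseline_percentile: float = 10.0,
    k_mad: float = 4.0,
    min_prominence: float = 0.05,
    stim_window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Peak times (s) of one trace; the stimulation epoch is excluded.

    The trace is normalized to ΔF/F0; peaks are local maxima exceeding
    ``k_mad`` robust SDs of the spontaneous ΔF/F0 with at least
    ``min_prominence`` prominence.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ValueError("detect_peaks expects a single trace")
    if len(trace) < 10:
        raise ValueError("need at least 10 frames")
    if np.isnan(trace).all():
        raise ValueError("all-NaN trace")
    dff = delta_f_over_f(trace[None], fps,
                         baseline_percentile=baseline_percentile)[0]
    spont = dff[:stim_window[0]] if stim_window is not None else dff
    # the low-percentile baseline leaves dff noise centered above zero,
    # so the detection threshold is anchored at the median
    thr = float(np.median(spont)) + k_mad * max(float(_robust_sd(spont)), 1e-9)
    idx, _ = find_peaks(spont, height=thr, prominence=min_prominence)
    return idx / fps


def event_trains(
    rec: CalciumRecording,
    cls: CellClassification,
    baseline_percentile: float = 10.0,
    k_mad: float = 4.0,
    min_prominence: float = 0.05,
) -> EventTrains:
    """Detect peaks for every gated neuron (non-neurons get empty trains)."""
    dff = delta_f_over_f(rec.traces, rec.fps,
                         baseline_percentile=baseline_percentile)
    trains = []
    for i in range(rec.n_cells):
        if cls.is_neuron[i]:
            trains.append(detect_peaks(
                rec.traces[i], rec.fps, baseline_percentile,
                k_mad, min_prominence, rec.stim_window,
            ))
        else:
            trains.append(np.array([]))
    analyzed = rec.spont_slice.stop / rec.fps
    return EventTrains(peak_times=trains, dff=dff, fps=rec.fps,
                       analyzed_duration_s=analyzed)


# ---------------------------------------------------------------------------
# network metrics
# ---------------------------------------------------------------------------

def percent_active(
    trains: EventTrains, cls: CellClassification
) -> tuple[float, int, bool]:
    """(% of neurons with >= 1 peak, active count, ND flag).

    Returns NaN percentage when there are no neurons at all.
    """
    neuron_idx = np.flatnonzero(cls.is_neuron)
    if neuron_idx.size == 0:
        return float("nan"), 0, True
    n_active = sum(len(trains.peak_times[i]) > 0 for i in neuron_idx)
    pct = 100.0 * n_active / neuron_idx.size
    return pct, int(n_active), n_active < ND_MIN_ACTIVE


def detect_network_bursts(
    trains: EventTrains,
    cls: CellClassification,
    bin_s: float = 1.0,
    participation_frac: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Synchronous network bursts from pooled event trains.

    Windows of length ``bin_s`` in which the fraction of *active*
    neurons firing reaches ``participation_frac`` qualify; the window
    slides at the frame step so a synchronous volley is never split
    across a fixed bin edge, and overlapping/adjacent qualifying
    windows merge into one burst.  Frequency is bursts per minute of
    analyzed (spontaneous) recording.  With fewer than 5 active neurons
    the result is ND: (empty, NaN).
    """
    neuron_idx = np.flatnonzero(cls.is_neuron)
    active = [i for i in neuron_idx if len(trains.peak_times[i]) > 0]
    if len(active) < ND_MIN_ACTIVE:
        return np.array([]), float("nan")
    dt = 1.0 / trains.fps
    n_steps = int(np.ceil(trains.analyzed_duration_s / dt))
    win = max(1, int(round(bin_s / dt)))
    # per-frame participation: distinct active neurons with a peak in
    # the window starting at that frame
    frame_sets = np.zeros((len(active), n_steps), dtype=bool)
    for k, i in enumerate(active):
        f = np.clip((trains.peak_times[i] / dt).astype(int), 0, n_steps - 1)
        frame_sets[k, f] = True
    kernel = np.ones(win)
    counts = np.stack([
        np.convolve(row, kernel, mode="same") > 0 for row in frame_sets
    ]).sum(axis=0)
    qualifying = counts >= participation_frac * len(active)
    lab, n_bursts = ndi.label(qualifying)
    burst_times = np.array([
        dt * np.flatnonzero(lab == k).mean()
        for k in range(1, n_bursts + 1)
    ])
    freq = n_bursts / (trains.analyzed_duration_s / 60.0)
    return burst_times, freq


def burst_correlation(
    rec: CalciumRecording,
    cls: CellClassification,
    trains: EventTrains | None = None,
    active_only: bool = False,
) -> float:
    """Mean off-diagonal pairwise Pearson r between neuron ΔF/F0 traces.

    Computed on the spontaneous epoch only.  Constant traces are
    excluded with a warning; fewer than 2 usable neurons gives NaN.
    By default all glutamate-gated neurons enter the matrix
    (``active_only`` restricts it to neurons with >= 1 peak).
    """
    idx = np.flatnonzero(cls.is_neuron)
    if active_only and trains is not None:
        idx = np.array([i for i in idx if len(trains.peak_times[i]) > 0],
                       dtype=int)
    dff = delta_f_over_f(rec.traces, rec.fps)[:, rec.spont_slice]
    keep = []
    for i in idx:
        if np.std(dff[i]) < 1e-12:
            warnings.warn(f"constant trace for cell {i}; excluded from "
                          "burst correlation")
            continue
        keep.append(i)
    if len(keep) < 2:
        return float("nan")
    cc = np.corrcoef(dff[keep])
    off = cc[~np.eye(len(keep), dtype=bool)]
    return float(off.mean())


def network_metrics(
    rec: CalciumRecording,
    cls: CellClassification,
    trains: EventTrains | None = None,
    bin_s: float = 1.0,
    participation_frac: float = 0.5,
    subgroup: str | None = None,
) -> NetworkActivityMetrics:
    """All network metrics for one field (optionally one subgroup)."""
    if trains is None:
        trains = event_trains(rec, cls)
    pct, n_active, nd = percent_active(trains, cls)
    if nd:
        freq, corr = float("nan"), float("nan")
    else:
        _, freq = detect_network_bursts(trains, cls, bin_s, participation_frac)
        corr = burst_correlation(rec, cls, trains)
    return NetworkActivityMetrics(
        pct_active=pct, n_active=n_active,
        n_neurons=int(cls.is_neuron.sum()),
        burst_frequency=freq, burst_correlation=corr,
        nd_flag=bool(nd), subgroup=subgroup,
    )


def subpopulation_metrics(
    rec: CalciumRecording,
    cls: CellClassification,
    bin_s: float = 1.0,
    participation_frac: float = 0.5,
) -> dict[str, NetworkActivityMetrics]:
    """Network metrics per neuronal subpopulation within the same field.

    Subgroups (e.g. aggregate-positive vs -negative neurons) are
    analyzed simultaneously; empty subgroups are skipped with a notice.
    The whole-network result is included under the key ``"all"``.
    """
    if cls.subpopulation is None:
        raise ValueError("classification carries no subpopulation labels")
    trains = event_trains(rec, cls)
    out = {"all": network_metrics(rec, cls, trains, bin_s, participation_frac)}
    groups = sorted({g for g in cls.subpopulation if g is not None})
    for g in groups:
        member = np.array([
            neu and (lbl == g)
            for neu, lbl in zip(cls.is_neuron, cls.subpopulation)
        ])
        if not member.any():
            warnings.warn(f"subpopulation {g!r} empty; skipped")
            continue
        sub_cls = CellClassification(is_neuron=member)
        out[g] = network_metrics(rec, sub_cls, trains, bin_s,
                                 participation_frac, subgroup=g)
    return out
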