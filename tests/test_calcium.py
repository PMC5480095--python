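import numpy as np
import pytest

from neurohcs import calcium, synthgen
from neurohcs.calcium import (
    CalciumRecording, CellClassification, burst_correlation,
    classify_glutamate_responders, detect_network_bursts, detect_peaks,
    event_trains, extract_traces, network_metrics, percent_active,
    subpopulation_metrics,
)


def make_rec(traces, fps=2.0, stim=None):
    traces = np.atleast_2d(np.asarray(traces, float))
    return CalciumRecording(traces=traces, fps=fps,
                            duration_s=traces.shape[1] / fps,
                            stim_window=stim)


class TestExtractTraces:
    def test_constant_movie_constant_traces(self):
        movie = np.full((10, 16, 16), 7.0)
        rois = np.zeros((16, 16), np.int32)
        rois[2:6, 2:6] = 1
        rec = extract_traces(movie, rois, fps=2.0)
        assert np.allclose(rec.traces, 7.0)

    def test_single_pixel_roi_equals_pixel_series(self, rng):
        movie = rng.random((20, 8, 8))
        rois = np.zeros((8, 8), np.int32)
        rois[3, 4] = 1
        rec = extract_traces(movie, rois, fps=2.0)
        assert np.allclose(rec.traces[0], movie[:, 3, 4])

    def test_empty_roi_label_warned(self, rng):
        movie = rng.random((10, 8, 8))
        rois = np.zeros((8, 8), np.int32)
        rois[0, 0] = 2  # label 1 absent
        with pytest.warns(UserWarning, match="ROI 1"):
            rec = extract_traces(movie, rois, fps=1.0)
        assert rec.n_cells == 1

    def test_recovers_rendered_amplitudes(self):
        rec, _ = synthgen.synth_calcium_recording(n_cells=6, seed=3)
        movie, rois = synthgen.synth_calcium_movie(rec, shape=(128, 128),
                                                   seed=3)
        back = extract_traces(movie, rois, fps=rec.fps,
                              stim_window=rec.stim_window)
        # mean within disk = background + gain * trace
        for i in range(6):
            fitted = (back.traces[i] - 10.0) / 100.0
            assert np.allclose(fitted, rec.traces[i], atol=1e-6)


class TestGlutamateGating:
    def test_flat_cell_is_non_neuron(self, rng):
        flat = 1.0 + 0.02 * rng.standard_normal(520)
        cls = classify_glutamate_responders(make_rec(flat, stim=(480, 520)))
        assert not cls.is_neuron[0]

    def test_matches_truth_at_default_noise(self):
        rec, truth = synthgen.synth_calcium_recording(n_cells=40, seed=9)
        cls = classify_glutamate_responders(rec)
        assert np.array_equal(cls.is_neuron, truth.is_neuron)

    def test_no_stim_window_retains_all_flagged(self, rng):
        rec = make_rec(rng.random((4, 100)) + 1.0)
        with pytest.warns(UserWarning, match="gating skipped"):
            cls = classify_glutamate_responders(rec)
        assert cls.ungated
        assert cls.is_neuron.all()


class TestDetectPeaks:
    def test_pure_noise_high_k_rarely_fires(self, rng):
        fired = 0
        for _ in range(20):
            trace = 1.0 + 0.02 * rng.standard_normal(520)
            fired += len(detect_peaks(trace, fps=2.0, k_mad=5.0)) > 0
        assert fired <= 1

    def test_single_large_transient_single_peak(self, rng):
        trace = 1.0 + 0.01 * rng.standard_normal(400)
        t = np.arange(400) / 2.0
        trace += 0.8 * np.where(t >= 100, np.exp(-(t - 100) / 1.5), 0)
        peaks = detect_peaks(trace, fps=2.0)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(100.0, abs=1.0)

    def test_event_count_recovery(self):
        rec, truth = synthgen.synth_calcium_recording(
            n_cells=30, neuron_fraction=1.0, active_fraction=1.0,
            sync_prob=1.0, burst_rate_per_min=2.0, seed=21)
        active = np.flatnonzero(truth.is_active)
        errs = []
        for i in active[:10]:
            peaks = detect_peaks(rec.traces[i], rec.fps,
                                 stim_window=rec.stim_window)
            errs.append(abs(len(peaks) - len(truth.event_times[i])))
        assert max(errs) <= 1

    def test_all_nan_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.full(50, np.nan), fps=2.0)


class TestPercentActive:
    def _trains(self, peak_lists, n_neurons):
        cls = CellClassification(np.ones(n_neurons, bool))
        trains = calcium.EventTrains(
            peak_times=[np.asarray(p, float) for p in peak_lists],
            dff=np.zeros((n_neurons, 10)), fps=2.0,
            analyzed_duration_s=240.0)
        return trains, cls

    def test_silent_network(self):
        trains, cls = self._trains([[]] * 10, 10)
        pct, n, nd = percent_active(trains, cls)
        assert pct == 0.0 and n == 0 and nd

    def test_six_of_ten_active(self):
        trains, cls = self._trains([[1.0]] * 6 + [[]] * 4, 10)
        pct, n, nd = percent_active(trains, cls)
        assert pct == 60.0 and n == 6 and not nd

    def test_nd_below_five_active(self):
        trains, cls = self._trains([[1.0]] * 4 + [[]] * 6, 10)
        _, n, nd = percent_active(trains, cls)
        assert n == 4 and nd

    def test_zero_neurons_undefined(self):
        trains, _ = self._trains([[]], 1)
        cls = CellClassification(np.zeros(1, bool))
        pct, _, nd = percent_active(trains, cls)
        assert np.isnan(pct) and nd


class TestNetworkBursts:
    def test_silent_gives_nd(self):
        cls = CellClassification(np.ones(10, bool))
        trains = calcium.EventTrains([np.array([])] * 10,
                                     np.zeros((10, 10)), 2.0, 240.0)
        times, freq = detect_network_bursts(trains, cls)
        assert len(times) == 0 and np.isnan(freq)

    def test_recovers_planted_rate(self):
        freqs, truths = [], []
        for s in range(6):
            rec, truth = synthgen.synth_calcium_recording(seed=200 + s)
            cls = classify_glutamate_responders(rec)
            trains = event_trains(rec, cls)
            _, f = detect_network_bursts(trains, cls)
            freqs.append(f)
            truths.append(len(truth.burst_times) / 4.0)
        # the detector should track each recording's realized burst count
        assert np.allclose(freqs, truths, atol=0.5)

    def test_bin_halving_keeps_isolated_bursts(self):
        cls = CellClassification(np.ones(6, bool))
        times = [np.array([10.0, 60.0, 130.0])] * 6
        trains = calcium.EventTrains(times, np.zeros((6, 10)), 2.0, 240.0)
        _, f1 = detect_network_bursts(trains, cls, bin_s=1.0)
        _, f2 = detect_network_bursts(trains, cls, bin_s=0.5)
        assert f1 == f2 == pytest.approx(3 / 4.0)


class TestBurstCorrelation:
    def test_identical_traces(self, rng):
        base = 1.0 + 0.1 * rng.standard_normal(200)
        rec = make_rec(np.tile(base, (4, 1)))
        cls = CellClassification(np.ones(4, bool))
        assert burst_correlation(rec, cls) == pytest.approx(1.0)

    def test_opposite_fluctuations(self, rng):
        # ΔF/F0 renormalization slightly distorts an exact negation,
        # so the pairwise correlation approaches but does not equal -1
        a = 1.0 + 0.1 * rng.standard_normal(200)
        rec = make_rec(np.stack([a, 2.0 - a]))
        cls = CellClassification(np.ones(2, bool))
        assert burst_correlation(rec, cls) < -0.9

    def test_monotone_in_sync_prob(self):
        means = []
        for sp in (0.2, 0.5, 0.9):
            vals = [burst_correlation(
                *(lambda r, t: (r, classify_glutamate_responders(r)))(
                    *synthgen.synth_calcium_recording(
                        sync_prob=sp, seed=300 + s)))
                for s in range(5)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_metric_affine_invariance(self):
        """Gain/offset on the raw traces leaves all metrics unchanged."""
        rec, _ = synthgen.synth_calcium_recording(n_cells=20, seed=31)
        scaled = CalciumRecording(
            traces=3.7 * rec.traces, fps=rec.fps,
            duration_s=rec.duration_s, stim_window=rec.stim_window)
        cls1 = classify_glutamate_responders(rec)
        cls2 = classify_glutamate_responders(scaled)
        assert np.array_equal(cls1.is_neuron, cls2.is_neuron)
        m1 = network_metrics(rec, cls1)
        m2 = network_metrics(scaled, cls2)
        assert m1.pct_active == m2.pct_active
        assert m1.burst_frequency == pytest.approx(m2.burst_frequency,
                                                   nan_ok=True)
        assert m1.burst_correlation == pytest.approx(
            m2.burst_correlation, abs=1e-9, nan_ok=True)


class TestSubpopulations:
    def _with_labels(self, seed, sync_a=0.9, sync_b=0.9):
        rec_a, tr_a = synthgen.synth_calcium_recording(
            n_cells=20, neuron_fraction=1.0, sync_prob=sync_a, seed=seed)
        rec_b, tr_b = synthgen.synth_calcium_recording(
            n_cells=20, neuron_fraction=1.0, sync_prob=sync_b, seed=seed + 1)
        traces = np.vstack([rec_a.traces, rec_b.traces])
        rec = CalciumRecording(traces, rec_a.fps, rec_a.duration_s,
                               rec_a.stim_window)
        cls = CellClassification(
            np.ones(40, bool),
            subpopulation=["pos"] * 20 + ["neg"] * 20)
        return rec, cls

    def test_exchangeable_subgroups_similar(self):
        rec, cls = self._with_labels(400)
        out = subpopulation_metrics(rec, cls)
        assert abs(out["pos"].pct_active - out["neg"].pct_active) <= 15.0

    def test_sync_ordering_between_subgroups(self):
        diffs = []
        for s in (410, 420, 430):
            rec, cls = self._with_labels(s, sync_a=0.9, sync_b=0.2)
            out = subpopulation_metrics(rec, cls)
            diffs.append(out["pos"].burst_correlation
                         - out["neg"].burst_correlation)
        assert np.mean(diffs) > 0

    def test_single_member_subgroup_undefined_correlation(self):
        rec, _ = synthgen.synth_calcium_recording(
            n_cells=5, neuron_fraction=1.0, seed=5)
        cls = CellClassification(
            np.ones(5, bool), subpopulation=["a"] * 4 + ["b"])
        out = subpopulation_metrics(rec, cls)
        assert np.isnan(out["b"].burst_correlation)

    def test_label_on_non_neuron_rejected(self):
        with pytest.raises(ValueError):
            CellClassification(np.array([True, False]),
                               subpopulation=["a", "a"])
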