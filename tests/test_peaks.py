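"""Peak detection, per-peak WLC fitting, and trace selection."""

import numpy as np
import pytest

import rejmech as rm
from rejmech.peaks import (
    AnalysisError,
    DetectionParams,
    SelectionCriteria,
    TraceAnalysis,
    fit_all_peaks,
    select_trace,
)


def composite_wlc_trace(lcs=(60.0, 90.0), peak_forces=(150.0, 400.0), dx=0.05):
    """Noiseless piecewise-WLC sawtooth: one segment per contour length,
    each rising to its peak force before the chain lengthens."""
    xs, fs = [0.0], [0.0]
    x = 0.5
    for lc, fpk in zip(lcs, peak_forces):
        params = rm.WLCParams(0.4, lc, 298.0)
        x_end = rm.invert_wlc(fpk, params)
        seg = np.arange(x, x_end, dx)
        xs.extend(seg)
        fs.extend(rm.wlc_force(seg, params))
        x = x_end
    # post-detachment baseline
    tail = np.arange(x, x + 10, dx)
    xs.extend(tail)
    fs.extend(np.zeros(tail.size))
    md = rm.TraceMetadata(trace_id="composite")
    return rm.ForceExtensionTrace(np.array(xs), np.array(fs), md)


class TestFindPeaks:
    def test_flat_trace_has_no_peaks(self):
        t = rm.ForceExtensionTrace(
            np.arange(100.0), np.zeros(100), rm.TraceMetadata("flat"))
        assert rm.find_peaks(t).size == 0

    def test_composite_two_peaks(self):
        t = composite_wlc_trace()
        idx = rm.find_peaks(t, DetectionParams(smooth_window=1))
        assert idx.size == 2

    def test_close_peaks_thinned_keeping_higher(self):
        # two maxima 2 nm apart; min_separation 10 nm keeps the higher one
        x = np.arange(0, 40, 0.1)
        f = np.zeros_like(x)
        f[(x > 19) & (x < 20)] = 80.0
        f[(x > 21) & (x < 22)] = 100.0
        t = rm.ForceExtensionTrace(x, f, rm.TraceMetadata("twin"))
        idx = rm.find_peaks(t, DetectionParams(min_separation=10.0, smooth_window=1))
        assert idx.size == 1
        assert f[idx[0]] == 100.0

    def test_simulated_trace_counts_match_truth(self, i27_batch):
        # unfolding events + detachment, in >= 95% of clean default-noise traces
        good = 0
        for trace, events in i27_batch:
            idx = rm.find_peaks(trace)
            good += idx.size == len(events)
        assert good / len(i27_batch) >= 0.95


class TestFitAllPeaks:
    def test_composite_delta_lc(self):
        t = composite_wlc_trace()
        idx = rm.find_peaks(t, DetectionParams(smooth_window=1))
        events = fit_all_peaks(t, idx, smooth_window=1)
        assert len(events) == 2
        assert events[1].delta_Lc == pytest.approx(30.0, abs=0.1)
        assert events[0].fitted_Lc == pytest.approx(60.0, abs=0.1)

    def test_single_peak_has_undefined_delta(self):
        t = composite_wlc_trace(lcs=(60.0,), peak_forces=(300.0,))
        idx = rm.find_peaks(t, DetectionParams(smooth_window=1))
        events = fit_all_peaks(t, idx, smooth_window=1)
        assert len(events) == 1
        assert events[0].delta_Lc is None

    def test_no_peaks_is_an_error(self):
        t = composite_wlc_trace()
        with pytest.raises(AnalysisError):
            fit_all_peaks(t, np.array([], dtype=int))

    def test_telescoping_conservation(self, i27_analyses):
        # sum of increments equals last minus first fitted Lc, exactly
        for a in i27_analyses:
            deltas = [p.delta_Lc for p in a.peaks if p.delta_Lc is not None]
            total = a.peaks[-1].fitted_Lc - a.peaks[0].fitted_Lc
            assert sum(deltas) == pytest.approx(total, abs=1e-9)

    def test_simulated_i27_delta_lc_near_geometry(self, i27_analyses):
        deltas = [
            p.delta_Lc for a in i27_analyses if a.accepted
            for p in a.unfolding_peaks if p.label == "I27" and p.delta_Lc is not None
        ]
        assert np.mean(deltas) == pytest.approx(28.085, abs=4.0)


class TestSelection:
    def _analysis(self, detachment=450.0, flags=()):
        peak = rm.PeakEvent(0, 100.0, detachment, 120.0)
        a = TraceAnalysis("t", [peak], detachment_force=detachment,
                          initial_Lc=120.0)
        a.flags = list(flags)
        return a

    def test_low_detachment_rejected_with_reason(self):
        a = select_trace(self._analysis(detachment=150.0))
        assert not a.accepted
        assert "detachment_below_threshold" in a.reasons

    def test_clean_high_detachment_accepted(self):
        assert select_trace(self._analysis(detachment=450.0)).accepted

    def test_unclean_start_rejected_when_required(self):
        a = select_trace(self._analysis(flags=["unclean_start"]))
        assert "unclean_start" in a.reasons
        relaxed = SelectionCriteria(require_clean_start=False)
        assert select_trace(self._analysis(flags=["unclean_start"]), relaxed).accepted

    def test_expected_peak_count_enforced(self, i27_analyses):
        crit = SelectionCriteria(expected_peak_count=5, expected_peak_label="I27")
        for a in i27_analyses:
            verdict = select_trace(a, crit)
            n = rm.count_fingerprint_peaks(a, "I27")
            assert verdict.accepted == (n == 5 and "unclean_start" not in a.flags
                                        and a.detachment_force >= 200)

    def test_selection_monotone_in_detachment_threshold(self):
        # raising the threshold can never turn a rejection into acceptance
        for det in (150.0, 250.0, 450.0):
            accepted = [
                select_trace(self._analysis(detachment=det),
                             SelectionCriteria(detachment_min=thr)).accepted
                for thr in (100.0, 200.0, 300.0, 500.0)
            ]
            assert accepted == sorted(accepted, reverse=True)


class TestFirstPeak:
    def test_spacer_measurement(self, i27_analyses):
        vals = [rm.first_peak_contour_length(a) for a in i27_analyses if a.accepted]
        # five folded I27 (22 nm) + 108-residue REJd4 coil (39.4 nm)
        assert np.mean(vals) == pytest.approx(61.4, rel=0.05)

    def test_artifact_correction_subtracts_span(self, i27_analyses):
        a = i27_analyses[0]
        assert (rm.first_peak_contour_length(a, subtract_artifact_span=20.0)
                == pytest.approx(rm.first_peak_contour_length(a) - 20.0))

    def test_no_peaks_signalled(self):
        a = TraceAnalysis("empty", [], 0.0, float("nan"))
        with pytest.raises(AnalysisError):
            rm.first_peak_contour_length(a)
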