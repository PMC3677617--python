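"""From raw sawtooth traces to fitted, selectable unfolding events.

The pipeline mirrors how force-extension recordings are analysed by hand:
detect the force peaks of the sawtooth, fit the rising worm-like-chain
segment that precedes each peak to measure its contour length Lc, difference
consecutive Lc values into contour-length increments (ΔLc), and keep only
traces that pass the published selection rules (clean initial extension,
detachment force above 200 pN, optionally an expected fingerprint peak
count).

The "clean initial force extension" criterion is qualitative in the
experimental protocol; the quantitative proxy used here is the absence of
force excursions larger than the detection prominence inside the proximal
nonspecific-adhesion window (10-30 nm). See docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .config import DEFAULT_PERSISTENCE_LENGTH, DEFAULT_TEMPERATURE
from .traces import ForceExtensionTrace
from .wlc import FitError, fit_wlc_segment

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "PeakEvent",
    "SelectionCriteria",
    "TraceAnalysis",
    "AnalysisError",
    "find_peaks",
    "fit_all_peaks",
    "select_trace",
    "first_peak_contour_length",
    "analyze_trace",
]


class AnalysisError(RuntimeError):
    """Raised when a trace cannot be analysed at all (e.g. every fit failed)."""


@dataclass(frozen=True)
class DetectionParams:
    """Peak-detection thresholds.

    Defaults sit below the smallest force population of interest (~60 pN)
    but above the instrument noise floor.
    """

    min_force: float = 30.0  # pN
    min_prominence: float = 20.0  # pN
    min_separation: float = 5.0  # nm
    smooth_window: int = 7  # samples, moving average applied before detection


@dataclass
class PeakEvent:
    """One unfolding (or detachment) force peak.

    ``delta_Lc`` is the backward contour-length increment, Lc of this peak
    minus Lc of the previous one (undefined for the first peak).
    ``released_gain`` is the forward increment — the contour released by
    *this* event, i.e. the next peak's Lc minus this one's (undefined for
    the final, detachment peak). ``resolved`` is False when the domain
    identity of the peak cannot be established (overlapping fingerprints).
    """

    index_in_trace: int
    extension_at_peak: float
    peak_force: float
    fitted_Lc: float
    delta_Lc: float | None = None
    released_gain: float | None = None
    label: str | None = None
    resolved: bool = True
    fit_residual_norm: float = 0.0


@dataclass(frozen=True)
class SelectionCriteria:
    """Trace-selection rules."""

    detachment_min: float = 200.0  # pN
    max_proximal_artifact: float = 30.0  # nm
    require_clean_start: bool = True
    expected_peak_count: int | None = None
    expected_peak_label: str | None = None  # count only events with this label

    def __post_init__(self) -> None:
        if self.detachment_min <= 0:
            raise ValueError(f"detachment_min must be positive, got {self.detachment_min}")


@dataclass
class TraceAnalysis:
    """Ordered fitted events plus the selection verdict for one trace."""

    trace_id: str
    peaks: list[PeakEvent]
    detachment_force: float
    initial_Lc: float
    accepted: bool = False
    reasons: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    construct_name: str | None = None

    @property
    def unfolding_peaks(self) -> list[PeakEvent]:
        """All events except the final detachment peak."""
        return self.peaks[:-1]

    def to_dict(self) -> dict:
        return {
            "trace_id": self.trace_id,
            "accepted": self.accepted,
            "reasons": list(self.reasons),
            "flags": list(self.flags),
            "construct_name": self.construct_name,
            "detachment_force": self.detachment_force,
            "initial_Lc": self.initial_Lc,
            "peaks": [
                {
                    "index_in_trace": p.index_in_trace,
                    "extension_at_peak": p.extension_at_peak,
                    "peak_force": p.peak_force,
                    "fitted_Lc": p.fitted_Lc,
                    "delta_Lc": p.delta_Lc,
                    "released_gain": p.released_gain,
                    "label": p.label,
                    "resolved": p.resolved,
                }
                for p in self.peaks
            ],
        }


def _smooth(force: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return force.astype(float)
    window = min(window, force.size if force.size % 2 else force.size - 1)
    if window % 2 == 0:
        window -= 1
    if window <= 1:
        return force.astype(float)
    kernel = np.ones(window) / window
    padded = np.pad(force.astype(float), window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def find_peaks(
    trace: ForceExtensionTrace, params: DetectionParams = DetectionParams()
) -> np.ndarray:
    """Indices of retained force peaks, ordered by extension.

    Local maxima of the smoothed force with height >= min_force and
    prominence >= min_prominence; peaks closer than min_separation (nm of
    extension) are thinned keeping the higher one (ties broken by lower
    extension); each retained peak must be followed by a force drop of at
    least min_prominence before the next retained peak.
    """
    force = _smooth(trace.force, params.smooth_window)
    idx, _props = scipy.signal.find_peaks(
        force, height=params.min_force, prominence=params.min_prominence
    )
    if idx.size == 0:
        return idx
    # Thin by extension separation: greedy by height desc, extension asc.
    order = sorted(range(idx.size), key=lambda i: (-force[idx[i]], trace.extension[idx[i]]))
    kept: list[int] = []
    for i in order:
        x = trace.extension[idx[i]]
        if all(abs(x - trace.extension[idx[j]]) >= params.min_separation for j in kept):
            kept.append(i)
    kept_idx = np.sort(idx[kept])
    # Require a genuine force drop between consecutive retained peaks.
    while True:
        drop_ok = True
        for a in range(len(kept_idx) - 1):
            i, j = kept_idx[a], kept_idx[a + 1]
            valley = float(np.min(force[i : j + 1]))
            if force[i] - valley < params.min_prominence:
                # insufficient release after the smaller of the two: drop it
                victim = i if force[i] <= force[j] else j
                kept_idx = kept_idx[kept_idx != victim]
                drop_ok = False
                break
        if drop_ok:
            break
    return kept_idx


def fit_all_peaks(
    trace: ForceExtensionTrace,
    peak_indices: np.ndarray,
    p_fixed: float | None = DEFAULT_PERSISTENCE_LENGTH,
    temperature: float = DEFAULT_TEMPERATURE,
    smooth_window: int = 7,
) -> list[PeakEvent]:
    """WLC-fit the rising segment preceding each peak.

    Each fit window runs from the previous force minimum (or the trace
    start) up to two samples before the peak — the peak top is rounded by
    cantilever dynamics and is excluded. Windows shorter than 4 samples are
    skipped with a warning. ΔLc is the difference of consecutive fitted
    contour lengths.
    """
    if len(peak_indices) == 0:
        raise AnalysisError("no peaks to fit")
    smoothed = _smooth(trace.force, smooth_window)
    events: list[PeakEvent] = []
    prev_peak = 0
    for peak in np.asarray(peak_indices, dtype=int):
        lo = prev_peak
        if events:
            seg = smoothed[prev_peak:peak]
            lo = prev_peak + int(np.argmin(seg)) if seg.size else prev_peak
        hi = peak - 1  # exclusive end: drops the 2 samples before the top
        if hi - lo < 4:
            logger.warning(
                "trace %s: fit window before peak at index %d has <4 samples; skipped",
                trace.metadata.trace_id, int(peak),
            )
            prev_peak = peak
            continue
        pts = np.column_stack([trace.extension[lo:hi], trace.force[lo:hi]])
        try:
            fit = fit_wlc_segment(pts, p_fixed=p_fixed, temperature=temperature)
        except FitError as exc:
            logger.warning(
                "trace %s: WLC fit before peak at index %d failed (%s); skipped",
                trace.metadata.trace_id, int(peak), exc,
            )
            prev_peak = peak
            continue
        x_peak = float(trace.extension[peak])
        lc = max(fit.params.contour_length_Lc, x_peak * (1.0 + 1e-9))
        events.append(
            PeakEvent(
                index_in_trace=int(peak),
                extension_at_peak=x_peak,
                peak_force=float(smoothed[peak]),
                fitted_Lc=lc,
                fit_residual_norm=fit.residual_norm,
            )
        )
        prev_peak = peak
    if not events:
        raise AnalysisError(
            f"trace {trace.metadata.trace_id}: every peak fit failed or was skipped"
        )
    for prev, cur in zip(events, events[1:]):
        cur.delta_Lc = cur.fitted_Lc - prev.fitted_Lc
        prev.released_gain = cur.delta_Lc
    return events


def select_trace(
    analysis: TraceAnalysis, criteria: SelectionCriteria = SelectionCriteria()
) -> TraceAnalysis:
    """Apply the selection rules; returns the analysis with verdict filled in.

    Reason codes enumerate *every* violated rule. Selection is monotone in
    ``detachment_min``: raising it can only reject more traces.
    """
    reasons: list[str] = []
    if not analysis.peaks:
        reasons.append("no_peaks")
    if analysis.detachment_force < criteria.detachment_min:
        reasons.append("detachment_below_threshold")
    if criteria.require_clean_start and "unclean_start" in analysis.flags:
        reasons.append("unclean_start")
    if criteria.expected_peak_count is not None:
        if criteria.expected_peak_label is None:
            count = len(analysis.unfolding_peaks)
        else:
            count = sum(
                1 for p in analysis.unfolding_peaks
                if p.label == criteria.expected_peak_label
            )
        if count != criteria.expected_peak_count:
            reasons.append("peak_count_mismatch")
    analysis.reasons = reasons
    analysis.accepted = not reasons
    return analysis


def first_peak_contour_length(
    analysis: TraceAnalysis, subtract_artifact_span: float | None = None
) -> float:
    """Fitted Lc of the first force peak — the spacer measurement.

    Optionally corrected by subtracting the configured proximal-artifact
    span (10-30 nm) when the contact point is known to be contaminated.
    """
    if not analysis.peaks:
        raise AnalysisError(f"trace {analysis.trace_id}: no fitted peaks")
    lc = analysis.peaks[0].fitted_Lc
    if subtract_artifact_span is not None:
        lc -= subtract_artifact_span
    return lc


def _flag_unclean_start(
    trace: ForceExtensionTrace, detection: DetectionParams, window_nm: float
) -> bool:
    """Excursion of prominence >= min_prominence inside the proximal window."""
    mask = trace.extension < window_nm
    if mask.sum() < 3:
        return False
    seg = _smooth(trace.force[mask], detection.smooth_window)
    idx, _ = scipy.signal.find_peaks(seg, prominence=detection.min_prominence)
    return idx.size > 0


def analyze_trace(
    trace: ForceExtensionTrace,
    detection: DetectionParams = DetectionParams(),
    criteria: SelectionCriteria = SelectionCriteria(),
    p_fixed: float | None = DEFAULT_PERSISTENCE_LENGTH,
    temperature: float | None = None,
) -> TraceAnalysis:
    """Full per-trace pipeline: detect, fit, and select."""
    if temperature is None:
        temperature = trace.metadata.temperature
    idx = find_peaks(trace, detection)
    if idx.size == 0:
        analysis = TraceAnalysis(
            trace_id=trace.metadata.trace_id,
            peaks=[],
            detachment_force=0.0,
            initial_Lc=float("nan"),
            construct_name=trace.metadata.construct_name,
        )
        return select_trace(analysis, criteria)
    events = fit_all_peaks(
        trace, idx, p_fixed=p_fixed, temperature=temperature,
        smooth_window=detection.smooth_window,
    )
    analysis = TraceAnalysis(
        trace_id=trace.metadata.trace_id,
        peaks=events,
        detachment_force=events[-1].peak_force,
        initial_Lc=events[0].fitted_Lc,
        construct_name=trace.metadata.construct_name,
    )
    if _flag_unclean_start(trace, detection, criteria.max_proximal_artifact):
        analysis.flags.append("unclean_start")
    return select_trace(analysis, criteria)
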