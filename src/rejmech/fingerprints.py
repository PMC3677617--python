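"""Mechanical-fingerprint classification of fitted unfolding peaks.

Each well-characterised domain class carries a mechanical fingerprint — an
(unfolding force, ΔLc) signature: titin I27 unfolds at ~200 pN releasing
~29 ± 8 nm of contour; MBP unfolds at ~70 pN releasing ~100 nm in total,
optionally through a mechanical intermediate that splits the release into
two ~50 nm steps. Peaks that match neither fingerprint, given the
construct's composition, are REJ-domain candidates — attribution by
elimination, which is how unknown domains acquire unfolding forces in
polyprotein experiments.

Identity limits are preserved rather than resolved: when a REJ candidate
and an I27 fall in the same force window (the REJd1 case, where the
recorded pair at ~148 and ~204 pN cannot be told apart), both events are
marked unresolved and downstream statistics pool them jointly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .constructs import ConstructSpec
from .peaks import TraceAnalysis

logger = logging.getLogger(__name__)

__all__ = [
    "DomainFingerprint",
    "DEFAULT_FINGERPRINTS",
    "load_fingerprint_registry",
    "classify_peaks",
    "infer_rej_forces",
    "count_fingerprint_peaks",
    "mbp_total_delta_lc",
    "mbp_intermediate_delta_lc",
    "LABEL_MBP",
    "LABEL_MBP_INTERMEDIATE",
    "LABEL_I27",
    "LABEL_REJ",
    "LABEL_DETACH",
    "LABEL_UNASSIGNED",
]

LABEL_MBP = "MBP"
LABEL_MBP_INTERMEDIATE = "MBP-intermediate"
LABEL_I27 = "I27"
LABEL_REJ = "REJ"
LABEL_DETACH = "detach"
LABEL_UNASSIGNED = "unassigned"

KNOWN_LABELS = {LABEL_MBP, LABEL_MBP_INTERMEDIATE, LABEL_I27, LABEL_REJ,
                LABEL_DETACH, LABEL_UNASSIGNED}

FINGERPRINT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class DomainFingerprint:
    """Expected (force, ΔLc) signature of a domain class.

    Matching windows are mean ± 2 SD. ``is_total_Lc`` marks classes (MBP)
    whose ΔLc entry is the *total* released contour rather than per event.
    """

    label: str
    force_mean: float
    force_sd: float
    delta_Lc_mean: float
    delta_Lc_sd: float
    is_total_Lc: bool = False

    def __post_init__(self) -> None:
        if self.force_sd <= 0 or self.delta_Lc_sd <= 0:
            raise ValueError(f"fingerprint {self.label!r}: SDs must be positive")

    def force_window(self) -> tuple[float, float]:
        return (self.force_mean - 2 * self.force_sd, self.force_mean + 2 * self.force_sd)

    def delta_window(self) -> tuple[float, float]:
        return (
            self.delta_Lc_mean - 2 * self.delta_Lc_sd,
            self.delta_Lc_mean + 2 * self.delta_Lc_sd,
        )


#: Registry defaults seeded from the published fingerprint values:
#: I27 200 pN / 29±8 nm; MBP ~70 pN, total ΔLc 100 nm (matched ±20 nm),
#: intermediate step ~50 nm.
DEFAULT_FINGERPRINTS: dict[str, DomainFingerprint] = {
    LABEL_I27: DomainFingerprint(LABEL_I27, force_mean=200.0, force_sd=30.0,
                                 delta_Lc_mean=29.0, delta_Lc_sd=8.0),
    LABEL_MBP: DomainFingerprint(LABEL_MBP, force_mean=70.0, force_sd=25.0,
                                 delta_Lc_mean=100.0, delta_Lc_sd=10.0,
                                 is_total_Lc=True),
    LABEL_MBP_INTERMEDIATE: DomainFingerprint(
        LABEL_MBP_INTERMEDIATE, force_mean=100.0, force_sd=25.0,
        delta_Lc_mean=50.0, delta_Lc_sd=10.0,
    ),
}

#: Peaks above this force are never MBP events.
MBP_FORCE_MAX = 120.0


def load_fingerprint_registry(path: str | Path) -> dict[str, DomainFingerprint]:
    """Load a fingerprint registry from its JSON config format."""
    data = json.loads(Path(path).read_text())
    version = data.get("schema_version")
    if version != FINGERPRINT_SCHEMA_VERSION:
        logger.warning("fingerprint registry schema version %r != %r",
                       version, FINGERPRINT_SCHEMA_VERSION)
    out: dict[str, DomainFingerprint] = {}
    for label, entry in data["fingerprints"].items():
        out[label] = DomainFingerprint(label=label, **entry)
    return out


def _assign_mbp(
    analysis: TraceAnalysis,
    registry: dict[str, DomainFingerprint],
) -> None:
    """Label the MBP release: one ~100 nm event or two ~50 nm events.

    Candidates are low-force unfolding peaks; the accepted subset (size 1
    or 2, in extension order) is the one whose released gains sum closest
    to the MBP total within its ±2 SD window, each component lying in its
    own window. Works regardless of whether another low-force domain
    unfolds before, between, or after the MBP events.
    """
    total_fp = registry[LABEL_MBP]
    inter_fp = registry.get(LABEL_MBP_INTERMEDIATE)
    lo_tot, hi_tot = total_fp.delta_window()
    events = analysis.unfolding_peaks
    cand = [
        i for i, ev in enumerate(events)
        if ev.peak_force < MBP_FORCE_MAX and ev.released_gain is not None
    ]
    best: tuple[float, tuple[int, ...]] | None = None

    def consider(subset: tuple[int, ...]) -> None:
        nonlocal best
        gains = [events[i].released_gain for i in subset]
        total = sum(gains)
        if not (lo_tot <= total <= hi_tot):
            return
        if len(subset) == 2:
            if inter_fp is None:
                return
            lo_i, hi_i = inter_fp.delta_window()
            if not all(lo_i <= g <= hi_i for g in gains):
                return
        score = abs(total - total_fp.delta_Lc_mean)
        key = (score, subset)
        if best is None or key < (best[0], best[1]):
            best = (score, subset)

    for i in cand:
        consider((i,))
    for pair in combinations(cand, 2):
        consider(pair)

    if best is None:
        analysis.flags.append("mbp_unassigned")
        return
    subset = best[1]
    events[subset[0]].label = LABEL_MBP
    if len(subset) == 2:
        events[subset[1]].label = LABEL_MBP_INTERMEDIATE


def classify_peaks(
    analysis: TraceAnalysis,
    construct: ConstructSpec,
    registry: dict[str, DomainFingerprint] | None = None,
) -> TraceAnalysis:
    """Greedy construct-aware peak labelling (in place; analysis returned).

    1. The final peak is the detachment event.
    2. If the construct contains MBP, the low-force peak(s) whose released
       gains reconstruct the MBP total (~100 ± 20 nm) are labelled MBP /
       MBP-intermediate.
    3. Remaining peaks with ΔLc inside the I27 window are I27 candidates;
       up to the construct's I27 count are labelled I27, preferring forces
       nearest the I27 force mean.
    4. Leftover unfolding peaks are REJ candidates.

    When a REJ candidate and an I27 sit in the same force window the pair
    is marked unresolved (``resolved=False``) rather than force-ranked.
    More in-window peaks than the construct has slots raises an ambiguity
    flag on the trace, never a silent drop.
    """
    if registry is None:
        registry = DEFAULT_FINGERPRINTS
    if not analysis.peaks:
        return analysis
    for ev in analysis.peaks:
        ev.label = None
        ev.resolved = True
    analysis.flags = [f for f in analysis.flags
                      if f not in ("mbp_unassigned", "excess_peaks", "unassigned_peaks")]
    analysis.peaks[-1].label = LABEL_DETACH

    if construct.has_mbp:
        _assign_mbp(analysis, registry)

    events = analysis.unfolding_peaks
    i27_fp = registry[LABEL_I27]
    lo_d, hi_d = i27_fp.delta_window()
    unlabeled = [i for i, ev in enumerate(events) if ev.label is None]

    def single_domain_plausible(i: int) -> bool:
        # a single-domain (I27/FNIII-sized) event must show an in-window
        # increment on at least one side; peaks carrying only a fused
        # multi-event increment (e.g. after a sub-threshold neighbour) are
        # not attributable to one domain
        ev = events[i]
        cands = [d for d in (ev.delta_Lc, ev.released_gain) if d is not None]
        return any(lo_d <= d <= hi_d for d in cands)

    in_window = [i for i in unlabeled if single_domain_plausible(i)]
    if len(in_window) > construct.n_i27_slots + construct.n_rej_slots:
        analysis.flags.append("excess_peaks")
    # I27 slots filled by force proximity; stable order for ties.
    by_force = sorted(in_window, key=lambda i: (abs(events[i].peak_force - i27_fp.force_mean), i))
    for i in by_force[: construct.n_i27_slots]:
        events[i].label = LABEL_I27
    for i in unlabeled:
        if events[i].label is None:
            if single_domain_plausible(i):
                events[i].label = LABEL_REJ
            else:
                events[i].label = LABEL_UNASSIGNED
                if "unassigned_peaks" not in analysis.flags:
                    analysis.flags.append("unassigned_peaks")

    # Mark force-window-overlapping REJ/I27 pairs as unresolved.
    lo_f, hi_f = i27_fp.force_window()
    rej_in = [i for i in unlabeled if events[i].label == LABEL_REJ
              and lo_f <= events[i].peak_force <= hi_f]
    i27_in = [i for i in unlabeled if events[i].label == LABEL_I27
              and lo_f <= events[i].peak_force <= hi_f]
    if rej_in and i27_in:
        for i in rej_in + i27_in:
            events[i].resolved = False
    return analysis


def count_fingerprint_peaks(analysis: TraceAnalysis, label: str) -> int:
    """Exact count of events carrying ``label`` (detachment included when
    asked for explicitly)."""
    if label not in KNOWN_LABELS:
        raise KeyError(f"unknown label {label!r}; known: {sorted(KNOWN_LABELS)}")
    return sum(1 for p in analysis.peaks if p.label == label)


def infer_rej_forces(
    batch: list[TraceAnalysis],
    construct: ConstructSpec,
    accepted_only: bool = True,
) -> tuple[np.ndarray, list[tuple[str, int, str]]]:
    """Pool the unfolding forces attributable to REJ domains.

    For constructs with two or more REJ slots this is the REJ-labelled
    events. With exactly one REJ slot the REJ/I27 identity is unresolvable,
    so the unresolved pair is pooled jointly (REJ and I27 labels together),
    mirroring the single-population histogram such constructs produce.

    Returns the force samples and a provenance list of
    (trace_id, peak index, label).
    """
    labels = {LABEL_REJ}
    if construct.n_rej_slots == 1:
        labels.add(LABEL_I27)
    samples: list[float] = []
    provenance: list[tuple[str, int, str]] = []
    for analysis in batch:
        if accepted_only and not analysis.accepted:
            continue
        for i, ev in enumerate(analysis.unfolding_peaks):
            if ev.label in labels:
                samples.append(ev.peak_force)
                provenance.append((analysis.trace_id, i, ev.label))
    if not samples:
        logger.warning("no REJ-candidate events found in batch of %d traces", len(batch))
    return np.asarray(samples, dtype=float), provenance


def mbp_total_delta_lc(analysis: TraceAnalysis) -> float | None:
    """Total contour released by the MBP events of one trace (nm).

    Sum of the released gains of the MBP and MBP-intermediate events — the
    span of the '~100 nm' double-headed arrow on an annotated recording.
    None when the trace has no labelled MBP event.
    """
    gains = [
        ev.released_gain
        for ev in analysis.unfolding_peaks
        if ev.label in (LABEL_MBP, LABEL_MBP_INTERMEDIATE) and ev.released_gain is not None
    ]
    return float(sum(gains)) if gains else None


def mbp_intermediate_delta_lc(analysis: TraceAnalysis) -> float | None:
    """ΔLc of the MBP unfolding intermediate for one trace (nm).

    Measured as the contour-length increment between the MBP main peak and
    the immediately following MBP-intermediate peak — the way the ~50 nm
    step is read off an annotated recording. Returns None when the trace
    has no intermediate or another event interleaves the pair (the
    increment would then conflate two releases).
    """
    events = analysis.unfolding_peaks
    for prev, cur in zip(events, events[1:]):
        if (
            prev.label == LABEL_MBP
            and cur.label == LABEL_MBP_INTERMEDIATE
            and cur.delta_Lc is not None
        ):
            return float(cur.delta_Lc)
    return None
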