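"""Unfolding-force population statistics.

Pools peak forces across accepted traces, builds the reporting histogram,
and decomposes the pooled sample into one or two Gaussian populations by
maximum likelihood, choosing the component count with the Bayesian
information criterion. The published analyses choose 1 vs 2 components
visually; BIC makes that choice explicit and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .fingerprints import LABEL_I27, LABEL_REJ
from .peaks import TraceAnalysis

logger = logging.getLogger(__name__)

__all__ = ["PopulationFit", "pool_unfolding_events", "fit_force_populations"]

#: Minimum SD (pN) reported for a degenerate (zero-variance) sample.
SD_FLOOR = 1.0

#: A candidate mixture component only counts as a force population when it
#: explains at least this fraction of the pooled events ...
MIN_COMPONENT_WEIGHT = 0.10
#: ... and at least this many events outright.
MIN_COMPONENT_EVENTS = 5.0

DEFAULT_BIN_WIDTH = 20.0  # pN
DEFAULT_POOL_LABELS = (LABEL_REJ, LABEL_I27)


@dataclass(frozen=True)
class PopulationFit:
    """Gaussian decomposition of pooled unfolding forces.

    Components are ordered by ascending mean; weights sum to 1. ``bic`` maps
    candidate component counts to their model-selection score (lower wins).
    """

    n_components: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    n_events_per_component: tuple[float, ...]
    n_events: int
    n_traces: int | None
    bic: dict[int, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("component SDs must be positive")
        if list(self.means) != sorted(self.means):
            raise ValueError("component means must be ascending")

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "means": list(self.means),
            "sds": list(self.sds),
            "weights": list(self.weights),
            "n_events_per_component": list(self.n_events_per_component),
            "n_events": self.n_events,
            "n_traces": self.n_traces,
            "bic": {str(k): v for k, v in self.bic.items()},
            "seed": self.seed,
        }


def pool_unfolding_events(
    batch: list[TraceAnalysis],
    include_labels: tuple[str, ...] = DEFAULT_POOL_LABELS,
    accepted_only: bool = True,
) -> np.ndarray:
    """Concatenated peak forces of the requested labels across a batch.

    MBP and detachment events are excluded by the default label set — the
    published force histograms pool only REJ and I27 unfolding events.
    """
    forces = [
        ev.peak_force
        for analysis in batch
        if analysis.accepted or not accepted_only
        for ev in analysis.unfolding_peaks
        if ev.label in include_labels
    ]
    if not forces:
        logger.warning(
            "empty force pool (labels %s over %d traces)", include_labels, len(batch)
        )
    return np.asarray(forces, dtype=float)


def _fit_k(forces: np.ndarray, k: int, seed: int) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=20,
        init_params="k-means++",
        random_state=seed,
        reg_covar=1e-6,
    )
    gm.fit(forces.reshape(-1, 1))
    return gm


def _population_from(
    gm: GaussianMixture, forces: np.ndarray, bic: dict[int, float],
    n_traces: int | None, seed: int,
) -> PopulationFit:
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(-1))
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    resp = gm.predict_proba(forces.reshape(-1, 1)).sum(axis=0)
    return PopulationFit(
        n_components=int(gm.n_components),
        means=tuple(float(m) for m in means[order]),
        sds=tuple(max(float(s), SD_FLOOR if s < SD_FLOOR / 10 else float(s)) for s in sds[order]),
        weights=tuple(float(w) for w in weights[order]),
        n_events_per_component=tuple(float(r) for r in resp[order]),
        n_events=int(forces.size),
        n_traces=n_traces,
        bic=bic,
        seed=seed,
    )


def fit_force_populations(
    forces: np.ndarray,
    max_components: int = 2,
    bin_width: float = DEFAULT_BIN_WIDTH,
    seed: int = 0,
    n_traces: int | None = None,
    force_components: int | None = None,
) -> tuple[PopulationFit, dict]:
    """Gaussian-mixture decomposition of a pooled force sample.

    Fits every candidate component count from 1 to ``max_components`` by
    maximum likelihood (k-means++ initialisation, 20 restarts, fixed seed)
    and selects the count with the lowest BIC among admissible models —
    a component must hold at least 10% of the events (and 5 events) to
    count as a population rather than a tail artifact. Returns the selected
    :class:`PopulationFit` together with a reporting histogram
    (``counts``, ``bin_edges`` at the configured bin width).
    ``force_components`` bypasses model selection and returns the fit with
    exactly that component count.

    Requires at least 10 events; a degenerate sample (zero spread) is
    reported as a single component with a floor SD instead of crashing.
    """
    forces = np.asarray(forces, dtype=float).ravel()
    if forces.size < 10:
        raise ValueError(
            f"need at least 10 unfolding events to fit populations, got {forces.size}"
        )
    edges = np.arange(0.0, forces.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(forces, bins=edges)
    histogram = {"counts": counts, "bin_edges": edges, "bin_width": bin_width}
    assert int(counts.sum()) == forces.size  # conservation

    if float(np.ptp(forces)) < 1e-12:
        fit = PopulationFit(
            n_components=1,
            means=(float(forces[0]),),
            sds=(SD_FLOOR,),
            weights=(1.0,),
            n_events_per_component=(float(forces.size),),
            n_events=int(forces.size),
            n_traces=n_traces,
            bic={},
            seed=seed,
        )
        return fit, histogram

    models: dict[int, GaussianMixture] = {}
    bic: dict[int, float] = {}
    admissible: dict[int, bool] = {}
    for k in range(1, max_components + 1):
        if forces.size < 5 * k:
            break
        models[k] = _fit_k(forces, k, seed)
        bic[k] = float(models[k].bic(forces.reshape(-1, 1)))
        # a force population is a substantial fraction of events, not a few
        # skew-tail outliers: every component must hold >= 10% of the sample
        # and at least MIN_COMPONENT_EVENTS events to be admissible
        resp = models[k].predict_proba(forces.reshape(-1, 1)).sum(axis=0)
        admissible[k] = bool(
            np.all(models[k].weights_ >= MIN_COMPONENT_WEIGHT)
            and np.all(resp >= MIN_COMPONENT_EVENTS)
        )
    if force_components is not None:
        if force_components not in models:
            raise ValueError(
                f"cannot force {force_components} components with {forces.size} events"
            )
        return _population_from(models[force_components], forces, bic, n_traces, seed), histogram
    candidates = [k for k in bic if admissible[k]] or list(bic)
    best_k = min(candidates, key=lambda k: (bic[k], k))
    # by construction of the BIC choice, the selected model's log-likelihood
    # can fall short of an admissible rival's only by less than the penalty gap
    for k in candidates:
        if k != best_k:
            assert bic[best_k] <= bic[k]
    fit = _population_from(models[best_k], forces, bic, n_traces, seed)
    return fit, histogram
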