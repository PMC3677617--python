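"""Engineered polyprotein constructs and their unfolding kinetics.

The experimental strategy flanks putative REJ-module segments of human
polycystin-1 with domains whose mechanical behaviour is known — titin I27
(~200 pN, ~29 nm released contour) and maltose-binding protein
(~70 pN, ~100 nm total, with an optional ~50 nm intermediate) — so that
every recording carries internal fingerprints. This module holds the
construct registry (ordered segments with residue counts from the human PC1
sequence), and the Bell-model kinetic parameters used by the simulator.

Residue accounting
------------------
REJd1 spans residues 2151-2256 (106 aa) and REJd2 2257-2375 (119 aa, implied
by subtraction of the published construct ranges). Their observed released
contour length is ~29 nm, which corresponds to an ~89-residue structured
core; the remaining residues are modelled as coil tails that extend from the
start. MBP's mechanically relevant stretch is modelled with an effective
unfolded length of 103.5 nm so that its released total is the observed
~100 nm. REJd3 (2380-2467) and REJd4 (2468-2575) are modelled as
unstructured coils, which is the experimental conclusion for them.

All kinetic constants (k0, delta_x) are calibration products of
:func:`rejmech.simulate.calibrate_bell` / ``calibrate_to_detected`` — no
measured unfolding kinetics exist for these domains. They reproduce the
fingerprint force populations at the default 0.6 nm/ms pulling speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .config import DEFAULT_GEOMETRY, ChainGeometry

__all__ = [
    "Segment",
    "ConstructSpec",
    "KineticParams",
    "IntermediatePath",
    "CONSTRUCTS",
    "DEFAULT_KINETICS",
    "get_construct",
    "kinetics_for",
]


@dataclass(frozen=True)
class Segment:
    """One contiguous stretch of polypeptide in a construct."""

    name: str
    domain_class: str  # "I27", "FNIII", "MBP", or "coil"
    n_residues: int
    folded: bool
    kinetics_ref: str | None = None  # key into the kinetics registry
    residue_range: tuple[int, int] | None = None  # human PC1 numbering
    unfolded_length_override_nm: float | None = None

    def __post_init__(self) -> None:
        if self.n_residues <= 0:
            raise ValueError(f"segment {self.name!r} has no residues")
        if self.folded and self.kinetics_ref is None:
            raise ValueError(f"folded segment {self.name!r} needs a kinetics_ref")
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if hi < lo:
                raise ValueError(f"segment {self.name!r} residue range is reversed")

    def unfolded_length(self, geometry: ChainGeometry = DEFAULT_GEOMETRY) -> float:
        if self.unfolded_length_override_nm is not None:
            return self.unfolded_length_override_nm
        return self.n_residues * geometry.nm_per_residue

    def released_gain(self, geometry: ChainGeometry = DEFAULT_GEOMETRY) -> float:
        """Contour length (nm) released when this folded segment unfolds."""
        if not self.folded:
            return 0.0
        return self.unfolded_length(geometry) - geometry.folded_distance(self.domain_class)


@dataclass(frozen=True)
class ConstructSpec:
    """Ordered segments of an engineered polyprotein."""

    name: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        ranges = [s.residue_range for s in self.segments if s.residue_range]
        for a, b in zip(ranges, ranges[1:]):
            if b[0] <= a[1]:
                raise ValueError(
                    f"construct {self.name!r}: residue ranges overlap or are unordered"
                )

    @property
    def n_i27_slots(self) -> int:
        return sum(1 for s in self.segments if s.folded and s.domain_class == "I27")

    @property
    def n_rej_slots(self) -> int:
        """Folded REJ (FNIII-class) segments — the candidate unfolding events."""
        return sum(1 for s in self.segments if s.folded and s.domain_class == "FNIII")

    @property
    def has_mbp(self) -> bool:
        return any(s.folded and s.domain_class == "MBP" for s in self.segments)

    def expected_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.segments:
            if s.folded:
                counts[s.domain_class] = counts.get(s.domain_class, 0) + 1
        return counts


@dataclass(frozen=True)
class IntermediatePath:
    """Optional two-step unfolding (MBP-style mechanical intermediate).

    ``probability`` is the per-molecule chance that unfolding proceeds via
    the intermediate; ``partial_delta_lc`` is the contour released by the
    first step (the remainder is released by the second step, whose own Bell
    kinetics are k0/delta_x below).
    """

    probability: float
    partial_delta_lc: float
    k0: float
    delta_x: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"intermediate probability must be in [0,1], got {self.probability}")
        if self.partial_delta_lc <= 0 or self.k0 <= 0 or self.delta_x <= 0:
            raise ValueError("intermediate partial ΔLc, k0 and delta_x must be positive")


@dataclass(frozen=True)
class KineticParams:
    """Bell-model unfolding kinetics: k(F) = k0 * exp(F * delta_x / kBT)."""

    k0: float  # zero-force unfolding rate, 1/s
    delta_x: float  # distance to the transition state, nm
    unfolded_contour_gain: float  # nm released on (complete) unfolding
    intermediate: IntermediatePath | None = None

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError(f"k0 must be positive, got {self.k0}")
        if self.delta_x <= 0:
            raise ValueError(f"delta_x must be positive, got {self.delta_x}")
        if self.unfolded_contour_gain <= 0:
            raise ValueError(
                f"unfolded contour gain must be positive, got {self.unfolded_contour_gain}"
            )
        if self.intermediate is not None:
            if self.intermediate.partial_delta_lc >= self.unfolded_contour_gain:
                raise ValueError("intermediate ΔLc must be smaller than the total gain")


def _i27(i: int) -> Segment:
    return Segment(name=f"I27-{i}", domain_class="I27", n_residues=89, folded=True,
                   kinetics_ref="I27")


# Expression tags, protease sites and cloning scars of the MBP fusions,
# pooled as one terminal coil; keeps the first unfolding peak clear of the
# 10-30 nm proximal-adhesion window, as in the published recordings.
_LINKER = Segment(name="linker", domain_class="coil", n_residues=90, folded=False)

_MBP = Segment(
    name="MBP", domain_class="MBP", n_residues=370, folded=True, kinetics_ref="MBP",
    # effective stretch between attachment points; released total = 100 nm
    unfolded_length_override_nm=103.5,
)

_REJD1_CORE = Segment(
    name="REJd1", domain_class="FNIII", n_residues=89, folded=True,
    kinetics_ref="REJd1", residue_range=(2151, 2239),
)
_REJD1_TAIL = Segment(
    name="REJd1-tail", domain_class="coil", n_residues=17, folded=False,
    residue_range=(2240, 2256),
)
_REJD2_CORE = Segment(
    name="REJd2", domain_class="FNIII", n_residues=89, folded=True,
    kinetics_ref="REJd2", residue_range=(2257, 2345),
)
_REJD2_TAIL = Segment(
    name="REJd2-tail", domain_class="coil", n_residues=30, folded=False,
    residue_range=(2346, 2375),
)
_REJD4_COIL = Segment(
    name="REJd4", domain_class="coil", n_residues=108, folded=False,
    residue_range=(2468, 2575),
)
_REJD34_COIL = Segment(
    name="REJd3,4", domain_class="coil", n_residues=196, folded=False,
    residue_range=(2380, 2575),
)

CONSTRUCTS: dict[str, ConstructSpec] = {
    c.name: c
    for c in (
        ConstructSpec(
            name="MBP-REJd1-I27",
            segments=(_LINKER, _MBP, _REJD1_CORE, _REJD1_TAIL, _i27(1)),
        ),
        ConstructSpec(
            name="MBP-REJd1,2-I27",
            segments=(_LINKER, _MBP, _REJD1_CORE, _REJD1_TAIL,
                      _REJD2_CORE, _REJD2_TAIL, _i27(1)),
        ),
        ConstructSpec(
            name="(I27)3-REJd4-(I27)2",
            segments=(_i27(1), _i27(2), _i27(3), _REJD4_COIL, _i27(4), _i27(5)),
        ),
        ConstructSpec(
            name="(I27)3-REJd3,4-(I27)2",
            segments=(_i27(1), _i27(2), _i27(3), _REJD34_COIL, _i27(4), _i27(5)),
        ),
    )
}


def get_construct(name: str) -> ConstructSpec:
    try:
        return CONSTRUCTS[name]
    except KeyError:
        raise KeyError(
            f"unknown construct {name!r}; available: {sorted(CONSTRUCTS)}"
        ) from None


# Calibration products (see module docstring): tuned so the detected-event
# force populations at 0.6 nm/ms match the fingerprint registry.
DEFAULT_KINETICS: dict[str, KineticParams] = {
    "I27": KineticParams(k0=7.54e-4, delta_x=0.2932, unfolded_contour_gain=28.085),
    "REJd1": KineticParams(k0=7.70e-3, delta_x=0.20, unfolded_contour_gain=28.985),
    "REJd2": KineticParams(k0=2.34, delta_x=0.20, unfolded_contour_gain=28.985),
    "MBP": KineticParams(
        k0=0.126, delta_x=0.40, unfolded_contour_gain=100.0,
        intermediate=IntermediatePath(
            probability=0.5, partial_delta_lc=50.0, k0=5.92e-3, delta_x=0.40,
        ),
    ),
}


def kinetics_for(
    construct: ConstructSpec,
    registry: dict[str, KineticParams] | None = None,
    geometry: ChainGeometry = DEFAULT_GEOMETRY,
    mbp_intermediate_probability: float | None = None,
) -> dict[str, KineticParams]:
    """Kinetics registry restricted to a construct, gains checked vs geometry.

    The contour gain carried by each :class:`KineticParams` must agree with
    the construct's segment geometry to < 0.1 nm — the simulator and the
    contour-length accounting must never disagree.
    """
    registry = dict(registry if registry is not None else DEFAULT_KINETICS)
    out: dict[str, KineticParams] = {}
    for seg in construct.segments:
        if not seg.folded:
            continue
        if seg.kinetics_ref not in registry:
            raise KeyError(
                f"no kinetics for segment {seg.name!r} (ref {seg.kinetics_ref!r})"
            )
        params = registry[seg.kinetics_ref]
        gain = seg.released_gain(geometry)
        if abs(gain - params.unfolded_contour_gain) > 0.1:
            params = replace(params, unfolded_contour_gain=gain)
        if (
            mbp_intermediate_probability is not None
            and seg.domain_class == "MBP"
            and params.intermediate is not None
        ):
            params = replace(
                params,
                intermediate=replace(
                    params.intermediate, probability=mbp_intermediate_probability
                ),
            )
        out[seg.kinetics_ref] = params
    return out
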