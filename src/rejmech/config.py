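"""Versioned physical constants and ledger defaults.

Every number that enters an analysis but is not carried by the data itself
lives here: the Boltzmann constant in AFM-friendly units, the default
persistence length used for per-peak worm-like-chain fits, and the
residue-count accounting used to convert construct composition into contour
length. All of them can be overridden per call; this module only fixes the
defaults and documents their provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CONFIG_VERSION = "1"

#: Boltzmann constant in pN nm / K.
KB = 0.0138065

#: Default absolute temperature (K) for fits and simulations.
DEFAULT_TEMPERATURE = 298.0

#: Default polypeptide persistence length (nm), held fixed during per-peak
#: WLC fits. Standard value for unfolded polypeptide in the SMFS literature.
DEFAULT_PERSISTENCE_LENGTH = 0.4

#: Contour length gained per unfolded residue (nm/aa).
DEFAULT_NM_PER_RESIDUE = 0.365

#: Folded N-to-C terminal distance by domain class (nm). A folded domain
#: contributes this distance to the stretched contour; once unfolded it
#: contributes residues x nm_per_residue instead. Coil segments are always
#: fully extended and contribute residues x nm_per_residue from the start.
DEFAULT_FOLDED_NC_DISTANCE = {
    "I27": 4.4,
    "FNIII": 3.5,
    "MBP": 3.5,
}


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kB*T in pN nm."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature


@dataclass(frozen=True)
class ChainGeometry:
    """Residue-count to contour-length accounting.

    Parameters
    ----------
    nm_per_residue:
        Contour length per unfolded residue, nm/aa. Must lie in the
        physically sensible band (0.3, 0.42).
    folded_nc_distance:
        Map from domain-class label to the folded N-C distance in nm.
    """

    nm_per_residue: float = DEFAULT_NM_PER_RESIDUE
    folded_nc_distance: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOLDED_NC_DISTANCE)
    )

    def __post_init__(self) -> None:
        if not (0.3 < self.nm_per_residue < 0.42):
            raise ValueError(
                f"nm_per_residue must be in (0.3, 0.42), got {self.nm_per_residue}"
            )
        for label, d in self.folded_nc_distance.items():
            if d < 0:
                raise ValueError(f"folded N-C distance for {label!r} is negative: {d}")

    def folded_distance(self, label: str) -> float:
        try:
            return self.folded_nc_distance[label]
        except KeyError:
            raise KeyError(
                f"no folded N-C distance configured for domain class {label!r}; "
                f"known classes: {sorted(self.folded_nc_distance)}"
            ) from None


DEFAULT_GEOMETRY = ChainGeometry()
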