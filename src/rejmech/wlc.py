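"""Worm-like-chain polymer mechanics and cantilever calibration.

The entropic elasticity of unfolded polypeptide is described by the
Marko-Siggia interpolation of the worm-like chain (WLC):

    F(x) = (kB T / p) * [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

with persistence length ``p``, contour length ``Lc``, and extension ``x``.
This module provides the forward force law, its numerical inverse, a
least-squares segment fitter (the workhorse behind per-peak contour-length
measurement), equipartition cantilever calibration, and the residue-count
bookkeeping that converts a construct's fold state into total contour length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import DEFAULT_GEOMETRY, DEFAULT_PERSISTENCE_LENGTH, DEFAULT_TEMPERATURE, ChainGeometry, kbt

if TYPE_CHECKING:  # pragma: no cover
    from .constructs import ConstructSpec

__all__ = [
    "WLCParams",
    "wlc_force",
    "invert_wlc",
    "fit_wlc_segment",
    "WLCFitResult",
    "FitError",
    "spring_constant_equipartition",
    "chain_contour_length",
]


class FitError(RuntimeError):
    """Raised when a WLC segment fit cannot be performed or fails."""


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain parameters.

    Attributes
    ----------
    persistence_length_p : persistence length p in nm (> 0)
    contour_length_Lc : contour length Lc in nm (> 0)
    temperature_T : absolute temperature in K (> 0)
    """

    persistence_length_p: float
    contour_length_Lc: float
    temperature_T: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.persistence_length_p <= 0:
            raise ValueError(f"persistence length must be > 0, got {self.persistence_length_p}")
        if self.contour_length_Lc <= 0:
            raise ValueError(f"contour length must be > 0, got {self.contour_length_Lc}")
        if self.temperature_T <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature_T}")

    @property
    def kbt(self) -> float:
        return kbt(self.temperature_T)


def _ms_force(x, p: float, lc: float, kt: float):
    t = np.asarray(x, dtype=float) / lc
    return (kt / p) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)


def wlc_force(x, params: WLCParams):
    """Marko-Siggia WLC force (pN) at extension ``x`` (nm).

    Accepts a scalar or array extension; every element must satisfy
    0 <= x < Lc, otherwise a ``ValueError`` naming the offending value is
    raised. Returns a scalar for scalar input.
    """
    arr = np.asarray(x, dtype=float)
    lc = params.contour_length_Lc
    if np.any(arr < 0):
        bad = float(arr[arr < 0].flat[0]) if arr.ndim else float(arr)
        raise ValueError(f"extension must be non-negative, got {bad} nm")
    if np.any(arr >= lc):
        bad = float(arr[arr >= lc].flat[0]) if arr.ndim else float(arr)
        raise ValueError(f"extension {bad} nm is not below the contour length {lc} nm")
    out = _ms_force(arr, params.persistence_length_p, lc, params.kbt)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def invert_wlc(force: float, params: WLCParams, tol: float = 1e-9, max_iter: int = 200) -> float:
    """Extension x (nm) at which the WLC produces ``force`` (pN).

    Bracketed bisection on [0, Lc*(1 - 1e-9)]; unconditionally convergent
    because the force law is strictly monotone. ``tol`` is the bracket width
    in nm at which iteration stops.
    """
    if force < 0:
        raise ValueError(f"force must be non-negative, got {force} pN")
    if force == 0.0:
        return 0.0
    lc = params.contour_length_Lc
    lo, hi = 0.0, lc * (1.0 - 1e-9)
    p, kt = params.persistence_length_p, params.kbt
    if _ms_force(hi, p, lc, kt) < force:
        raise ValueError(
            f"force {force} pN is not reachable below the bracket end at Lc={lc} nm"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if _ms_force(mid, p, lc, kt) < force:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            return 0.5 * (lo + hi)
    raise RuntimeError(
        f"WLC inversion did not converge within {max_iter} iterations for F={force} pN"
    )


@dataclass(frozen=True)
class WLCFitResult:
    """Outcome of a WLC segment fit."""

    params: WLCParams
    residual_norm: float
    n_points: int
    p_was_free: bool


def fit_wlc_segment(
    points: Sequence[tuple[float, float]] | np.ndarray,
    p_fixed: float | None = DEFAULT_PERSISTENCE_LENGTH,
    temperature: float = DEFAULT_TEMPERATURE,
) -> WLCFitResult:
    """Least-squares WLC fit of an (extension, force) segment.

    Parameters
    ----------
    points:
        Sequence of (extension_nm, force_pN) pairs; at least 4 required.
    p_fixed:
        Persistence length held fixed during the fit (nm). Pass ``None`` to
        fit p jointly with Lc.
    temperature:
        Temperature (K) entering kB*T.

    Returns the fitted :class:`WLCParams` together with the residual 2-norm.
    The optimisation is deterministic for identical inputs.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (extension, force)")
    if pts.shape[0] < 4:
        raise FitError(f"need at least 4 points for a WLC fit, got {pts.shape[0]}")
    x, f = pts[:, 0], pts[:, 1]
    if np.any(x < 0):
        raise ValueError("extensions must be non-negative")
    fmax = float(np.max(f))
    if fmax < 1e-6:
        raise FitError("degenerate segment: all forces are ~0, nothing to fit")
    kt = kbt(temperature)
    xmax = float(np.max(x))

    def lc_guess(p: float) -> float:
        # Invert the dominant 1/(4(1-t)^2) term at the highest-force point.
        t = 1.0 - 0.5 * np.sqrt(kt / (p * max(fmax, 1.0)))
        t = min(max(t, 0.5), 1.0 - 1e-3)
        return max(xmax / t, xmax + 1.0)

    lo_lc = xmax * (1.0 + 1e-6)

    if p_fixed is not None:
        p0 = float(p_fixed)

        def resid(theta):
            return _ms_force(x, p0, theta[0], kt) - f

        sol = least_squares(
            resid, x0=[lc_guess(p0)], bounds=([lo_lc], [np.inf]), method="trf"
        )
        params = WLCParams(p0, float(sol.x[0]), temperature)
    else:
        p0 = DEFAULT_PERSISTENCE_LENGTH

        def resid(theta):
            return _ms_force(x, theta[1], theta[0], kt) - f

        sol = least_squares(
            resid,
            x0=[lc_guess(p0), p0],
            bounds=([lo_lc, 0.05], [np.inf, 5.0]),
            method="trf",
        )
        params = WLCParams(float(sol.x[1]), float(sol.x[0]), temperature)
    if not sol.success:
        raise FitError(f"WLC fit failed: {sol.message}")
    return WLCFitResult(
        params=params,
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_points=int(pts.shape[0]),
        p_was_free=p_fixed is None,
    )


def spring_constant_equipartition(
    deflection_variance: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Cantilever stiffness (pN/nm) from the equipartition theorem.

    k = kB T / <dx^2>, with the thermal deflection variance in nm^2.
    """
    if deflection_variance <= 0:
        raise ValueError(
            f"deflection variance must be positive, got {deflection_variance} nm^2"
        )
    return kbt(temperature) / deflection_variance


def chain_contour_length(
    construct: "ConstructSpec",
    geometry: ChainGeometry = DEFAULT_GEOMETRY,
    state: Sequence[bool] | None = None,
) -> float:
    """Total stretched contour length (nm) of a construct in a fold state.

    ``state[i]`` is True while segment i is still folded. Folded segments
    contribute their class's folded N-C distance; unfolded (and coil)
    segments contribute residues x nm_per_residue, unless the segment
    carries an explicit unfolded-length override. Unfolding any segment
    strictly increases the total.
    """
    segments = construct.segments
    if state is None:
        state = [seg.folded for seg in segments]
    if len(state) != len(segments):
        raise ValueError(
            f"state covers {len(state)} segments but construct has {len(segments)}"
        )
    total = 0.0
    for seg, folded in zip(segments, state):
        if folded:
            if not seg.folded:
                raise ValueError(
                    f"segment {seg.name!r} is a coil and cannot be in a folded state"
                )
            total += geometry.folded_distance(seg.domain_class)
        else:
            total += seg.unfolded_length(geometry)
    return total
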