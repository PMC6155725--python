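"""Closed-form small-angle scattering model functions.

The central object is the generalized Guinier-Porod (GGP) model, an empirical
form factor that joins a Guinier-like low-q branch

    I(q) = I(0) * q^(-s) * exp(-q^2 Rg^2 / (3 - s)),   q <= q1

to a Porod power law

    I(q) = D * q^(-d),                                  q >= q1

at the crossover

    q1 = (1/Rg) * sqrt((d - s)(3 - s) / 2),

the unique point at which the two branches agree in both value and
logarithmic slope.  The dimensionality parameter s encodes the scatterer
shape (0 globular, 1 rod-like, 2 lamellar); d is the Porod exponent
(d ~ 4 for sharp interfaces).  The Porod prefactor D is not free: it is
fixed by value continuity at q1.

Also provided: the pure Porod power law (used for scatterers whose Guinier
rollover lies below the instrument window), the Debye-Bueche and
Ornstein-Zernike correlation-length models for gel-like systems, additive
composites of these, and analytic helpers (Kratky peak position,
equivalent-sphere diameter from Rg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import NoPeakError

__all__ = [
    "GuinierPorodParams",
    "PorodParams",
    "DebyeBuecheParams",
    "OrnsteinZernikeParams",
    "CompositeModel",
    "GelModel",
    "ggp_crossover",
    "ggp_porod_prefactor",
    "ggp_intensity",
    "porod_intensity",
    "debye_bueche_intensity",
    "ornstein_zernike_intensity",
    "gel_intensity",
    "composite_intensity",
    "sphere_diameter",
    "rg_from_sphere_diameter",
    "kratky_peak_q",
]


@dataclass(frozen=True)
class GuinierPorodParams:
    """One GGP scatterer component.

    Parameters
    ----------
    i0 : forward intensity I(0), arbitrary units (> 0).
    rg : radius of gyration, nm (> 0).
    d : Porod exponent (must exceed ``s``).
    s : dimensionality parameter, 0 <= s < 3 (0 = globular, 1 = rod,
        2 = lamella).
    """

    i0: float
    rg: float
    d: float
    s: float = 0.0

    def __post_init__(self) -> None:
        if not self.i0 > 0:
            raise ValueError(f"i0 must be positive, got {self.i0}")
        if not self.rg > 0:
            raise ValueError(f"rg must be positive, got {self.rg}")
        if not 0 <= self.s < 3:
            raise ValueError(f"s must lie in [0, 3), got {self.s}")
        if not self.d > self.s:
            raise ValueError(f"d must exceed s, got d={self.d}, s={self.s}")

    @property
    def q1(self) -> float:
        """Guinier/Porod crossover, nm^-1."""
        return ggp_crossover(self)

    @property
    def porod_prefactor(self) -> float:
        """Continuity-derived Porod prefactor D, a.u. * nm^-d."""
        return ggp_porod_prefactor(self)


@dataclass(frozen=True)
class PorodParams:
    """A pure power law I(q) = D * q^(-d), no Guinier rollover.

    Used for scatterers larger than the instrument window, whose Kratky
    signature is a shoulder rather than a peak.
    """

    prefactor: float
    d: float
    d_max: float = 4.0

    def __post_init__(self) -> None:
        if not self.prefactor > 0:
            raise ValueError(f"prefactor must be positive, got {self.prefactor}")
        if not 0 < self.d <= self.d_max:
            raise ValueError(f"d must lie in (0, {self.d_max}], got {self.d}")


@dataclass(frozen=True)
class DebyeBuecheParams:
    """Debye-Bueche long-range inhomogeneity model I = A / (1 + xi^2 q^2)^2."""

    amplitude: float
    xi: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if not self.xi > 0:
            raise ValueError(f"xi must be positive, got {self.xi}")


@dataclass(frozen=True)
class OrnsteinZernikeParams:
    """Ornstein-Zernike chain-fluctuation model I = A / (1 + xi^2 q^2)."""

    amplitude: float
    xi: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if not self.xi > 0:
            raise ValueError(f"xi must be positive, got {self.xi}")


@dataclass(frozen=True)
class CompositeModel:
    """Additive mixture of GGP components, an optional Porod shoulder, and an
    optional flat background.

    Component intensities sum; at least one component must be present.
    """

    ggp_components: tuple[GuinierPorodParams, ...] = ()
    porod_shoulder: PorodParams | None = None
    flat_background: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ggp_components", tuple(self.ggp_components))
        if (
            not self.ggp_components
            and self.porod_shoulder is None
            and self.flat_background is None
        ):
            raise ValueError("CompositeModel needs at least one component")
        if self.flat_background is not None and self.flat_background < 0:
            raise ValueError("flat_background must be >= 0")

    def sorted_by_rg(self) -> "CompositeModel":
        """Return a copy with GGP components ordered by descending rg
        (subscript 1 = larger aggregate)."""
        comps = tuple(sorted(self.ggp_components, key=lambda c: -c.rg))
        return replace(self, ggp_components=comps)


@dataclass(frozen=True)
class GelModel:
    """Debye-Bueche term plus optional Ornstein-Zernike term (additive)."""

    db: DebyeBuecheParams
    oz: OrnsteinZernikeParams | None = None


def ggp_crossover(params: GuinierPorodParams) -> float:
    """Crossover momentum transfer q1 = (1/Rg) sqrt((d-s)(3-s)/2), nm^-1."""
    return math.sqrt((params.d - params.s) * (3.0 - params.s) / 2.0) / params.rg


def ggp_porod_prefactor(params: GuinierPorodParams) -> float:
    """Porod prefactor guaranteeing value continuity of the two branches at q1."""
    q1 = ggp_crossover(params)
    return (
        params.i0
        * q1 ** (params.d - params.s)
        * math.exp(-(q1**2) * params.rg**2 / (3.0 - params.s))
    )


def ggp_intensity(params: GuinierPorodParams, q: np.ndarray) -> np.ndarray:
    """Evaluate the piecewise GGP model on q > 0 (nm^-1)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("GGP intensity requires q > 0")
    q1 = ggp_crossover(params)
    big_d = ggp_porod_prefactor(params)
    guinier = params.i0 * q ** (-params.s) * np.exp(
        -(q**2) * params.rg**2 / (3.0 - params.s)
    )
    porod = big_d * q ** (-params.d)
    return np.where(q <= q1, guinier, porod)


def porod_intensity(params: PorodParams, q: np.ndarray) -> np.ndarray:
    """I(q) = D q^(-d)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("Porod intensity requires q > 0")
    return params.prefactor * q ** (-params.d)


def debye_bueche_intensity(params: DebyeBuecheParams, q: np.ndarray) -> np.ndarray:
    """I(q) = A / (1 + xi^2 q^2)^2."""
    q = np.asarray(q, dtype=float)
    return params.amplitude / (1.0 + params.xi**2 * q**2) ** 2


def ornstein_zernike_intensity(
    params: OrnsteinZernikeParams, q: np.ndarray
) -> np.ndarray:
    """I(q) = A / (1 + xi^2 q^2)."""
    q = np.asarray(q, dtype=float)
    return params.amplitude / (1.0 + params.xi**2 * q**2)


def gel_intensity(model: GelModel, q: np.ndarray) -> np.ndarray:
    out = debye_bueche_intensity(model.db, q)
    if model.oz is not None:
        out = out + ornstein_zernike_intensity(model.oz, q)
    return out


def composite_intensity(model: CompositeModel, q: np.ndarray) -> np.ndarray:
    """Elementwise sum of all component intensities plus the flat background."""
    q = np.asarray(q, dtype=float)
    out = np.zeros_like(q)
    for comp in model.ggp_components:
        out = out + ggp_intensity(comp, q)
    if model.porod_shoulder is not None:
        out = out + porod_intensity(model.porod_shoulder, q)
    if model.flat_background is not None:
        out = out + model.flat_background
    return out


def sphere_diameter(rg: float) -> float:
    """Equivalent-sphere diameter 2R from Rg via R^2 = (5/3) Rg^2, nm."""
    if rg < 0:
        raise ValueError(f"rg must be non-negative, got {rg}")
    return 2.0 * math.sqrt(5.0 / 3.0) * rg


def rg_from_sphere_diameter(diameter: float) -> float:
    """Inverse of :func:`sphere_diameter`."""
    if diameter < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter}")
    return diameter / (2.0 * math.sqrt(5.0 / 3.0))


def kratky_peak_q(
    params: GuinierPorodParams, q_range: tuple[float, float] | None = None
) -> float:
    """Position of the Kratky-plot maximum (argmax of q^2 I(q)), nm^-1.

    On the Guinier branch q^2 I = I(0) q^(2-s) exp(-q^2 Rg^2/(3-s)), whose
    stationary point is q* = sqrt((2-s)(3-s)/2)/Rg (for s=0: sqrt(3)/Rg).
    The closed form applies whenever q* falls below the crossover q1, i.e.
    whenever d > 2; otherwise a dense-grid argmax is used.
    """
    if params.s >= 2:
        raise NoPeakError(
            f"no Kratky peak in the Guinier branch for s={params.s} (needs s < 2)"
        )
    q_star = math.sqrt((2.0 - params.s) * (3.0 - params.s) / 2.0) / params.rg
    q1 = ggp_crossover(params)
    if q_star <= q1:  # equivalent to d >= 2
        return q_star
    # d < 2: the Porod branch Kratky curve q^(2-d) keeps rising past q1, so
    # search a dense log grid and demand an interior maximum.
    lo, hi = q_range if q_range is not None else (1e-3 / params.rg, 1e3 / params.rg)
    grid = np.geomspace(lo, hi, 100_000)
    kratky = grid**2 * ggp_intensity(params, grid)
    idx = int(np.argmax(kratky))
    if idx in (0, grid.size - 1):
        raise NoPeakError("no interior Kratky maximum on the evaluated q range")
    return float(grid[idx])
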