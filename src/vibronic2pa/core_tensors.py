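"""Two-photon strength algebra.

Rotational (orientational) averaging of second-order transition moment
tensors ``S_ab``, Gaussian lineshapes parameterized by HWHM, and conversion
of rotationally averaged two-photon strengths ``delta`` (a.u.) to macroscopic
cross sections in Goeppert-Mayer units.

For a single source of linearly polarized photons the isotropic average of
the two-photon transition probability is

    delta_2PA = (F*delta_F + G*delta_G + H*delta_H) / 30

with the Monson-McClain invariants

    delta_F = sum_ab S^L_aa S^R_bb   (= tr L * tr R)
    delta_G = sum_ab S^L_ab S^R_ab
    delta_H = sum_ab S^L_ab S^R_ba

and F = G = H = 2 for one linearly polarized beam.  ``L`` and ``R`` are the
left and right second-order transition moments; for Hermitian electronic
structure theories (e.g. TD-DFT response) a single tensor serves as both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    BOHR_RADIUS_CM,
    DEFAULT_PREFACTOR,
    FINE_STRUCTURE,
    GM_IN_CM4_S,
    SPEED_OF_LIGHT_CM_S,
    ev_to_hartree,
)

__all__ = [
    "Rank2TransitionTensor",
    "PolarizationWeights",
    "TwoPhotonStrength",
    "LineshapeSpec",
    "CrossSectionConvention",
    "rotational_average",
    "to_cross_section",
    "gaussian_profile",
]


@dataclass(frozen=True)
class Rank2TransitionTensor:
    """A 3x3 second-order transition moment tensor in atomic units.

    ``hermitian`` indicates that the same tensor acts as both the left and
    the right factor in the rotational average (the TD-DFT case); for
    non-Hermitian theories carry a distinct left/right pair.
    """

    components: np.ndarray
    hermitian: bool = True
    state_labels: str = ""

    def __post_init__(self):
        arr = np.asarray(self.components, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError(f"expected a 3x3 tensor, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("tensor components must be finite")
        object.__setattr__(self, "components", arr)

    @classmethod
    def zero(cls) -> "Rank2TransitionTensor":
        return cls(np.zeros((3, 3)))

    def rotated(self, rotation: np.ndarray) -> "Rank2TransitionTensor":
        """Return the tensor transformed as S -> R S R^T."""
        r = np.asarray(rotation, dtype=float)
        return Rank2TransitionTensor(
            r @ self.components @ r.T, self.hermitian, self.state_labels
        )


@dataclass(frozen=True)
class PolarizationWeights:
    """Polarization variables F, G, H.

    The default (2, 2, 2) corresponds to a single source of linearly
    polarized photons.
    """

    F: float = 2.0
    G: float = 2.0
    H: float = 2.0


@dataclass(frozen=True)
class TwoPhotonStrength:
    """Rotationally averaged two-photon strength and its invariants (a.u.)."""

    delta_F: float
    delta_G: float
    delta_H: float
    delta_2PA: float
    weights: PolarizationWeights = field(default_factory=PolarizationWeights)


@dataclass(frozen=True)
class LineshapeSpec:
    """Broadening profile; ``hwhm`` is the half width at half maximum in eV."""

    shape: str = "gaussian"
    hwhm: float = 0.005

    def __post_init__(self):
        if self.shape != "gaussian":
            raise ValueError(f"unsupported lineshape {self.shape!r}")
        if not self.hwhm > 0:
            raise ValueError("hwhm must be positive")


@dataclass(frozen=True)
class CrossSectionConvention:
    """Constants and prefactor of the cross-section formula.

    sigma(2w) = prefactor * alpha * a0^5 * w^2 * g(2w) * delta / c

    with w, g and delta in atomic units, a0 in cm and c in cm/s, yielding
    sigma in cm^4 s (1 GM = 1e-50 cm^4 s).  Conventions for the dimensionless
    prefactor differ between codes; the default is the 4*pi^2 convention of
    FCclasses-style implementations, and the value used is recorded in all
    output metadata.
    """

    alpha: float = FINE_STRUCTURE
    a0_cm: float = BOHR_RADIUS_CM
    c_cm_s: float = SPEED_OF_LIGHT_CM_S
    prefactor_constant: float = DEFAULT_PREFACTOR

    def prefactor_au(self, photon_energy_au: float) -> float:
        """Everything in front of g(2w)*delta, for sigma in GM."""
        return (
            self.prefactor_constant
            * self.alpha
            * self.a0_cm**5
            * photon_energy_au**2
            / self.c_cm_s
            / GM_IN_CM4_S
        )


def rotational_average(
    left: Rank2TransitionTensor,
    right: Rank2TransitionTensor | None = None,
    weights: PolarizationWeights = PolarizationWeights(),
) -> TwoPhotonStrength:
    """Orientationally average a pair of second-order transition tensors.

    When ``right`` is omitted the left tensor is used on both sides (the
    Hermitian case).
    """
    if right is None:
        right = left
    sl = left.components
    sr = right.components
    delta_f = float(np.trace(sl) * np.trace(sr))
    delta_g = float(np.sum(sl * sr))
    delta_h = float(np.sum(sl * sr.T))
    delta = (weights.F * delta_f + weights.G * delta_g + weights.H * delta_h) / 30.0
    return TwoPhotonStrength(delta_f, delta_g, delta_h, delta, weights)


def to_cross_section(
    delta: TwoPhotonStrength | float,
    photon_energy_ev: float,
    lineshape_value_au: float,
    convention: CrossSectionConvention = CrossSectionConvention(),
) -> float:
    """Convert a two-photon strength to a cross section in GM.

    ``lineshape_value_au`` is the value of the unit-area broadening function
    g(2w) at the evaluation point, in 1/hartree.
    """
    if photon_energy_ev <= 0:
        raise ValueError("photon energy must be positive")
    if lineshape_value_au < 0:
        raise ValueError("lineshape value must be non-negative")
    d = delta.delta_2PA if isinstance(delta, TwoPhotonStrength) else float(delta)
    if d < 0:
        warnings.warn(
            "negative delta_2PA encountered; value propagated", RuntimeWarning
        )
    w_au = float(ev_to_hartree(photon_energy_ev))
    return convention.prefactor_au(w_au) * lineshape_value_au * d


def gaussian_profile(center, hwhm, energy_grid):
    """Unit-area Gaussian parameterized by its HWHM.

    Both ``center``/``hwhm`` and the grid may be in any single consistent
    energy unit; the returned densities are per that unit.
    """
    if hwhm <= 0:
        raise ValueError("hwhm must be positive")
    grid = np.asarray(energy_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("energy grid must be strictly increasing")
    sigma = hwhm / np.sqrt(2.0 * np.log(2.0))
    vals = np.exp(-0.5 * ((grid - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    if grid[0] > center - 4 * sigma or grid[-1] < center + 4 * sigma:
        warnings.warn(
            "energy grid does not cover 99.99% of the Gaussian mass", RuntimeWarning
        )
    return vals
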