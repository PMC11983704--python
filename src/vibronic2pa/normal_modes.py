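"""Harmonic analysis of molecular systems.

Mass-weighted Hessian diagonalization with Eckart projection of the rigid
translations and rotations, and generation of Cartesian geometries displaced
along normal modes for numerical differentiation.

Conventions
-----------
* Masses are stored in amu and converted to electron masses internally, so
  mass-weighted coordinates, frequencies and mode vectors are in pure Hartree
  atomic units.
* Mode vectors L are columns of an orthonormal matrix in mass-weighted
  Cartesian space; the Cartesian displacement pattern of mode v is
  M^(-1/2) L_v.
* Each mode's sign is fixed so that its largest-magnitude Cartesian component
  is positive (quantum-chemistry codes return arbitrary phases; derivative
  comparison across codes needs a deterministic gauge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .constants import AMU_TO_ME, HARTREE_TO_CM1

__all__ = [
    "MolecularSystem",
    "NormalModeBasis",
    "compute_normal_modes",
    "displace_along_coordinate",
    "displacement_steps",
]

#: tolerance on the moment-of-inertia rank test for linear molecules (amu*Bohr^2)
LINEAR_TOL_AMU_BOHR2 = 1e-6


@dataclass(frozen=True)
class MolecularSystem:
    """A molecular system: masses, geometry, Hessian and optional gradient.

    Units: masses in amu, coordinates in Bohr, Hessian and gradient in
    Hartree atomic units (per Cartesian displacement in Bohr), energy in
    hartree.
    """

    masses: np.ndarray
    coordinates: np.ndarray
    hessian: np.ndarray | None = None
    gradient: np.ndarray | None = None
    energy: float = 0.0
    label: str = ""

    def __post_init__(self):
        m = np.asarray(self.masses, dtype=float)
        x = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if m.ndim != 1 or m.size != x.shape[0]:
            raise ValueError("masses and coordinates are inconsistent")
        if not np.all(m > 0):
            raise ValueError("masses must be positive")
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "coordinates", x)
        n3 = 3 * m.size
        if self.hessian is not None:
            h = np.asarray(self.hessian, dtype=float)
            if h.shape != (n3, n3):
                raise ValueError(f"hessian must be {n3}x{n3}")
            if not np.allclose(h, h.T, atol=1e-8):
                raise ValueError("hessian must be symmetric within 1e-8")
            object.__setattr__(self, "hessian", h)
        if self.gradient is not None:
            g = np.asarray(self.gradient, dtype=float).reshape(-1)
            if g.size != n3:
                raise ValueError(f"gradient must have length {n3}")
            object.__setattr__(self, "gradient", g)

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    @property
    def masses_au(self) -> np.ndarray:
        """Per-Cartesian-coordinate masses in electron masses (length 3N)."""
        return np.repeat(self.masses * AMU_TO_ME, 3)

    def is_linear(self) -> bool:
        com = np.average(self.coordinates, axis=0, weights=self.masses)
        x = self.coordinates - com
        inertia = np.zeros((3, 3))
        for mi, xi in zip(self.masses, x):
            inertia += mi * (np.dot(xi, xi) * np.eye(3) - np.outer(xi, xi))
        evals = np.linalg.eigvalsh(inertia)
        return bool(evals[0] < LINEAR_TOL_AMU_BOHR2)


@dataclass(frozen=True)
class NormalModeBasis:
    """Orthonormal mass-weighted normal modes with ascending frequencies.

    ``frequencies`` are in a.u.; an imaginary mode is reported as a negative
    value.  ``mode_vectors`` has shape (3N, n_modes).
    """

    frequencies: np.ndarray
    mode_vectors: np.ndarray
    n_modes: int = field(init=False)

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        lv = np.asarray(self.mode_vectors, dtype=float)
        if lv.ndim != 2 or lv.shape[1] != f.size:
            raise ValueError("mode_vectors shape inconsistent with frequencies")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "mode_vectors", lv)
        object.__setattr__(self, "n_modes", f.size)

    @property
    def frequencies_cm1(self) -> np.ndarray:
        return self.frequencies * HARTREE_TO_CM1


def _rigid_body_vectors(system: MolecularSystem) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (3N, 5 or 6)."""
    n = system.n_atoms
    sqm = np.sqrt(system.masses * AMU_TO_ME)
    com = np.average(system.coordinates, axis=0, weights=system.masses)
    x = system.coordinates - com
    vecs = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = sqm
        vecs.append(t.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        r = np.cross(x, e) * sqm[:, None]
        vecs.append(r.ravel())
    q, rmat = np.linalg.qr(np.column_stack(vecs))
    keep = np.abs(np.diag(rmat)) > 1e-10 * np.max(np.abs(np.diag(rmat)))
    return q[:, keep]


def _fix_mode_signs(cart_pattern: np.ndarray, modes: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|.| Cartesian component is positive."""
    out = modes.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(cart_pattern[:, j])))
        if cart_pattern[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def compute_normal_modes(
    system: MolecularSystem,
    projector_reference: MolecularSystem | None = None,
) -> NormalModeBasis:
    """Diagonalize the mass-weighted Hessian in the vibrational subspace.

    Translations and rotations are projected out exactly (the Hessian is
    diagonalized in an orthonormal basis of their complement), so no
    near-zero rigid-body eigenvalues appear among the returned modes.
    Negative vibrational eigenvalues are kept and reported as negative
    frequencies.

    ``projector_reference`` optionally supplies the geometry whose Eckart
    frame defines the vibrational subspace (used by vertical and adiabatic
    vibronic models so that both electronic surfaces share one frame).
    """
    if system.hessian is None:
        raise ValueError("system carries no Hessian")
    ref = projector_reference if projector_reference is not None else system
    rigid = _rigid_body_vectors(ref)
    n3 = 3 * system.n_atoms
    expected = n3 - rigid.shape[1]
    sqm = np.sqrt(system.masses_au)
    h_mw = system.hessian / np.outer(sqm, sqm)
    basis = scipy.linalg.null_space(rigid.T)
    if basis.shape[1] != expected:  # pragma: no cover - defensive
        raise ValueError("unexpected rigid-body space dimension")
    h_int = basis.T @ h_mw @ basis
    h_int = 0.5 * (h_int + h_int.T)
    evals, evecs = np.linalg.eigh(h_int)
    scale = max(np.max(np.abs(evals)), 1e-30)
    if np.count_nonzero(np.abs(evals) < 1e-10 * scale) > 0:
        raise ValueError(
            "degenerate geometry: vibrational eigenvalues numerically zero "
            "beyond the expected rigid-body count"
        )
    freqs = np.sign(evals) * np.sqrt(np.abs(evals))
    order = np.argsort(freqs)
    freqs = freqs[order]
    modes = basis @ evecs[:, order]
    cart = modes / sqm[:, None]
    modes = _fix_mode_signs(cart, modes)
    return NormalModeBasis(freqs, modes)


def displace_along_coordinate(
    system: MolecularSystem,
    basis: NormalModeBasis,
    mode_index: int,
    step: float,
) -> MolecularSystem:
    """Displace the Cartesian geometry by ``step`` along one normal mode.

    ``step`` is in mass-weighted atomic units: the normal coordinate Q_v of
    the displaced geometry changes by exactly ``step``; the Cartesian
    displacement is step * M^(-1/2) L_v.
    """
    if not np.isfinite(step):
        raise ValueError("step must be finite")
    if not 0 <= mode_index < basis.n_modes:
        raise IndexError(f"mode index {mode_index} out of range")
    sqm = np.sqrt(system.masses_au)
    dx = step * (basis.mode_vectors[:, mode_index] / sqm)
    new_coords = system.coordinates + dx.reshape(-1, 3)
    return replace(
        system,
        coordinates=new_coords,
        label=f"{system.label}+Q{mode_index}*{step:g}",
    )


def displacement_steps(base_step: float, levels: int = 4) -> np.ndarray:
    """Signed steps of the geometric mesh +-2^k * Delta, k = 0..levels.

    The default levels = 4 gives the 10-point mesh (5 positive, 5 negative)
    used for Romberg differentiation.
    """
    k = np.arange(levels + 1)
    pos = base_step * 2.0**k
    return np.concatenate([-pos[::-1], pos])
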