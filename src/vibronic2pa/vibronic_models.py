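"""Excited-state harmonic surface models: AH, VH and VG.

All three models express the final-state (excited) normal coordinates in
terms of the initial-state (ground) ones through the Duschinsky relation

    Q' = J Q + K

with J orthogonal and K the mass-weighted shift vector, so that Q' = 0 at
the excited-state minimum implied by the model.  The adiabatic Hessian (AH)
uses the true excited-state minimum and Hessian; the vertical Hessian (VH)
and vertical gradient (VG) extrapolate the excited surface from its Hessian
or gradient at the ground-state equilibrium geometry.

Both surfaces are expanded in the vibrational subspace of the *ground-state*
geometry's Eckart frame (also for AH, unless a caller supplies its own
excited basis); with per-geometry frames J would not be exactly orthogonal
and exactly harmonic surface pairs would not give AH == VH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import AMU_TO_ME, BOHR_TO_ANGSTROM
from .normal_modes import MolecularSystem, NormalModeBasis, compute_normal_modes

__all__ = [
    "VibronicModel",
    "build_VG",
    "build_VH",
    "build_AH",
    "rmsd_geometries",
]

logger = logging.getLogger(__name__)

#: gradient-norm tolerance (a.u.) below which a geometry counts as a minimum
MINIMUM_GRADIENT_TOL = 1e-6


@dataclass(frozen=True)
class VibronicModel:
    """Two harmonic surfaces linked by a Duschinsky rotation and shift.

    ``energy_gap`` is the electronic gap as supplied (adiabatic for AH,
    vertical for VH/VG, per ``gap_kind``); ``adiabatic_gap`` always holds the
    minimum-to-minimum gap implied by the model.  Frequencies are in a.u.,
    K in mass-weighted a.u.
    """

    model_kind: str
    initial_frequencies: np.ndarray
    final_frequencies: np.ndarray
    duschinsky_J: np.ndarray
    shift_K: np.ndarray
    energy_gap: float
    gap_kind: str
    adiabatic_gap: float = 0.0
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self):
        wi = np.asarray(self.initial_frequencies, dtype=float)
        wf = np.asarray(self.final_frequencies, dtype=float)
        j = np.asarray(self.duschinsky_J, dtype=float)
        k = np.asarray(self.shift_K, dtype=float)
        n = wi.size
        if wf.size != n or j.shape != (n, n) or k.size != n:
            raise ValueError("model dimensions inconsistent")
        if np.any(wf <= 0):
            raise ValueError("all final frequencies must be positive")
        if not np.allclose(j.T @ j, np.eye(n), atol=1e-8):
            raise ValueError("Duschinsky matrix is not orthogonal within 1e-8")
        object.__setattr__(self, "initial_frequencies", wi)
        object.__setattr__(self, "final_frequencies", wf)
        object.__setattr__(self, "duschinsky_J", j)
        object.__setattr__(self, "shift_K", k)

    @property
    def n_modes(self) -> int:
        return self.initial_frequencies.size

    @property
    def reorganization_energy(self) -> float:
        """Relaxation energy on the final surface, 1/2 K^T Omega'^2 K."""
        return 0.5 * float(np.sum(self.final_frequencies**2 * self.shift_K**2))


def _mw_gradient_on_modes(
    system: MolecularSystem, mode_vectors: np.ndarray, gradient: np.ndarray
) -> np.ndarray:
    sqm = np.sqrt(system.masses_au)
    return mode_vectors.T @ (np.asarray(gradient, float).reshape(-1) / sqm)


def build_VG(
    gs_system: MolecularSystem,
    gs_basis: NormalModeBasis,
    es_gradient_at_gs: np.ndarray,
    vertical_gap: float,
) -> VibronicModel:
    """Vertical gradient model: ES minimum from the gradient alone.

    The excited surface inherits the ground-state modes and frequencies;
    with the excited energy expanded as E + g.Q + 1/2 Q^T Omega^2 Q its
    minimum sits at Q = -Omega^-2 g, hence K = Omega^-2 g (so that
    Q' = Q + K vanishes there) and the adiabatic gap estimate is
    vertical_gap - 1/2 sum_v g_v^2 / omega_v^2.
    """
    w = gs_basis.frequencies
    if np.any(np.abs(w) < 1e-8):
        raise ValueError("near-zero ground-state frequency: shift ill-conditioned")
    if np.any(w < 0):
        raise ValueError("ground state has imaginary frequencies")
    g = _mw_gradient_on_modes(gs_system, gs_basis.mode_vectors, es_gradient_at_gs)
    k = g / w**2
    reorg = 0.5 * float(np.sum(g**2 / w**2))
    return VibronicModel(
        model_kind="VG",
        initial_frequencies=w,
        final_frequencies=w.copy(),
        duschinsky_J=np.eye(w.size),
        shift_K=k,
        energy_gap=vertical_gap,
        gap_kind="vertical",
        adiabatic_gap=vertical_gap - reorg,
    )


def build_VH(
    gs_system: MolecularSystem,
    gs_basis: NormalModeBasis,
    es_hessian_at_gs: np.ndarray,
    es_gradient_at_gs: np.ndarray,
    vertical_gap: float,
) -> VibronicModel:
    """Vertical Hessian model: ES surface from Hessian + gradient at the GS
    geometry.

    Imaginary excited-state frequencies (negative eigenvalues -omega^2 of the
    projected ES Hessian) are considered real and positive, with a logged
    warning; the energy gap is kept as supplied.
    """
    es_at_gs = MolecularSystem(
        masses=gs_system.masses,
        coordinates=gs_system.coordinates,
        hessian=es_hessian_at_gs,
        label=f"{gs_system.label}:ES@GS",
    )
    es_basis = compute_normal_modes(es_at_gs, projector_reference=gs_system)
    wf = es_basis.frequencies.copy()
    notes: list[str] = []
    n_imag = int(np.sum(wf < 0))
    if n_imag:
        msg = (
            f"{n_imag} imaginary excited-state frequencies considered real "
            "(positive)"
        )
        logger.warning(msg)
        notes.append(msg)
        wf = np.abs(wf)
        order = np.argsort(wf)
        wf = wf[order]
        es_basis = NormalModeBasis(wf, es_basis.mode_vectors[:, order])
    j = es_basis.mode_vectors.T @ gs_basis.mode_vectors
    g_final = _mw_gradient_on_modes(
        gs_system, es_basis.mode_vectors, es_gradient_at_gs
    )
    k = g_final / wf**2
    reorg = 0.5 * float(np.sum(g_final**2 / wf**2))
    return VibronicModel(
        model_kind="VH",
        initial_frequencies=gs_basis.frequencies,
        final_frequencies=wf,
        duschinsky_J=j,
        shift_K=k,
        energy_gap=vertical_gap,
        gap_kind="vertical",
        adiabatic_gap=vertical_gap - reorg,
        warnings=tuple(notes),
    )


def build_AH(
    gs_system: MolecularSystem,
    gs_basis: NormalModeBasis,
    es_system: MolecularSystem,
    adiabatic_gap: float,
    es_basis: NormalModeBasis | None = None,
    gradient_tol: float = MINIMUM_GRADIENT_TOL,
) -> VibronicModel:
    """Adiabatic Hessian model from both optimized minima.

    J = L_e^T L_g and K = L_e^T M^(1/2) (x_g - x_e) in mass-weighted
    Cartesian coordinates.  Unless ``es_basis`` is given, the excited modes
    are computed with the ground-state geometry's Eckart projectors (see the
    module docstring).
    """
    for sys_, name in ((gs_system, "ground"), (es_system, "excited")):
        if sys_.gradient is not None:
            gnorm = float(np.linalg.norm(sys_.gradient))
            if gnorm > gradient_tol:
                raise ValueError(
                    f"{name}-state geometry is not a minimum "
                    f"(|gradient| = {gnorm:.2e} a.u.)"
                )
    if es_basis is None:
        es_basis = compute_normal_modes(es_system, projector_reference=gs_system)
    if np.any(es_basis.frequencies <= 0):
        raise ValueError("excited-state minimum has non-positive frequencies")
    j = es_basis.mode_vectors.T @ gs_basis.mode_vectors
    sqm = np.sqrt(gs_system.masses_au)
    dx = (gs_system.coordinates - es_system.coordinates).ravel()
    k = es_basis.mode_vectors.T @ (sqm * dx)
    return VibronicModel(
        model_kind="AH",
        initial_frequencies=gs_basis.frequencies,
        final_frequencies=es_basis.frequencies,
        duschinsky_J=j,
        shift_K=k,
        energy_gap=adiabatic_gap,
        gap_kind="adiabatic",
        adiabatic_gap=adiabatic_gap,
    )


def rmsd_geometries(a: MolecularSystem, b: MolecularSystem) -> float:
    """Minimum RMSD (Angstrom) after optimal superposition (Kabsch).

    Translation and proper rotation are removed; atoms must correspond
    one-to-one in order.
    """
    if a.n_atoms != b.n_atoms:
        raise ValueError("atom counts differ")
    p = a.coordinates - a.coordinates.mean(axis=0)
    q = b.coordinates - b.coordinates.mean(axis=0)
    cov = p.T @ q
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rot = u @ diag @ vt
    diff = p - q @ rot.T
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1)))) * BOHR_TO_ANGSTROM
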