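"""Synthetic harmonic model systems with known ground truth.

Stand-in for quantum-chemistry outputs: a ground-state surface (random
non-linear geometry, orthonormal modes, frequencies in the mid-IR window),
an excited surface built *by construction* from chosen shifts, frequency
changes and small-angle Duschinsky mixing (so AH/VH/VG inputs are exactly
consistent and the model-equivalence properties are exact), and a polynomial
transition-tensor field S(Q) = S0 + sum_v B_v Q_v + 1/2 sum_v C_v Q_v^2
whose derivatives are the generator's ground truth.

The statistical structure emulates benchmarked quantum-chemistry data: the
longitudinal xx component dominates every tensor by about an order of
magnitude on average, and per-mode derivative magnitudes are heavy-tailed
(log-normal) so that the median is far below the mean -- most modes couple
weakly, a few dominate.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import scipy.linalg

from .benchmark_stats import DerivativeSet
from .constants import cm1_to_hartree
from .core_tensors import Rank2TransitionTensor
from .normal_modes import (
    MolecularSystem,
    NormalModeBasis,
    _fix_mode_signs,
    _rigid_body_vectors,
)
from .romberg import ModeDerivative
from .vibronic_models import VibronicModel
from .vibronic_spectrum import HTExpansion

__all__ = [
    "SyntheticSpec",
    "GeneratedSystem",
    "generate_model_system",
    "perturb_derivatives",
    "PerturbedDerivativeSet",
    "write_fixture",
    "read_fixture",
    "random_vibronic_model",
    "random_expansion",
    "derivative_set_from_mode_derivatives",
    "derivative_set_from_expansion",
]

_ATOM_MASSES = np.array([1.008, 12.011, 14.007, 15.999])


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the stated synthetic world.

    Defaults: vibrational frequencies span the generic mid-IR window
    200-3500 cm^-1; dimensionless shifts of scale 0.4 give Huang-Rhys
    factors up to ~0.3 (typical rigid fluorophores); Duschinsky angles of
    ~0.15 rad are "small mixing"; S0_xx = 50 a.u. with ~2 a.u. off
    components and heavy-tailed first derivatives of median 0.02 a.u.
    (log-normal sigma 1.8, median/mean ~ 0.2) emulate the dominant
    longitudinal component and the few-strongly-coupled-modes signature of
    push-pull chromophores, and put the HT share of the total intensity at
    the few-percent scale.
    """

    n_modes: int = 6
    n_atoms: int | None = None
    frequency_range: tuple[float, float] = (200.0, 3500.0)  # cm^-1
    shift_scale: float = 0.4  # dimensionless displacement scale
    duschinsky_angle_scale: float = 0.15  # rad
    frequency_change_scale: float = 0.05  # relative ES frequency jitter
    s0_xx_scale: float = 50.0  # a.u.
    off_component_scale: float = 2.0  # a.u. (S0 off components)
    b_xx_median: float = 0.02  # a.u., median |dS_xx/dQ|
    b_off_ratio: float = 0.05  # off-component scale relative to xx
    c_xx_median: float = 0.01  # a.u., median |d2S_xx/dQ2|
    derivative_tail_exponent: float = 1.8  # log-normal sigma
    vertical_gap: float = 0.12  # hartree (~3.3 eV)
    seed: int = 0

    def resolved_n_atoms(self) -> int:
        n = self.n_atoms
        if n is None:
            n = max(3, math.ceil((self.n_modes + 6) / 3))
        if self.n_modes > 3 * n - 6:
            raise ValueError(
                f"n_modes={self.n_modes} exceeds 3*{n}-6 internal coordinates"
            )
        return n


@dataclass(frozen=True)
class GeneratedSystem:
    """A generated model system with all ground-truth parameters.

    ``active_modes`` lists the indices carrying shifts and tensor
    derivatives; any additional internal modes of the Cartesian Hessian are
    inert spectators (zero shift, zero derivative, unchanged frequency).
    ``truth_model`` is the exact final surface used in the construction.
    """

    spec: SyntheticSpec
    ground: MolecularSystem
    gs_basis: NormalModeBasis
    excited: MolecularSystem
    es_gradient_at_gs: np.ndarray
    vertical_gap: float
    adiabatic_gap: float
    truth_model: VibronicModel
    expansion: HTExpansion
    evaluator: Callable[[MolecularSystem], Rank2TransitionTensor]
    active_modes: tuple[int, ...]


def _symmetric_tensor(xx, yy, zz, xy, xz, yz) -> np.ndarray:
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])


def _draw_tensor(rng, xx_median, off_ratio, sigma) -> np.ndarray:
    """Symmetric tensor with heavy-tailed magnitudes, dominant xx."""
    def draw(scale):
        sign = rng.choice([-1.0, 1.0])
        mag = rng.lognormal(np.log(scale), sigma) if scale > 0 else 0.0
        return sign * mag

    xx = draw(xx_median)
    off = xx_median * off_ratio
    return _symmetric_tensor(
        xx, draw(off), draw(off), draw(off * 2), draw(off), draw(off)
    )


def _random_geometry(rng, n_atoms: int) -> tuple[np.ndarray, np.ndarray]:
    masses = rng.choice(_ATOM_MASSES, size=n_atoms)
    for _ in range(100):
        coords = rng.normal(scale=2.0, size=(n_atoms, 3))
        sys_probe = MolecularSystem(masses=masses, coordinates=coords)
        if not sys_probe.is_linear():
            return masses, coords
    raise RuntimeError("failed to draw a non-linear geometry")  # pragma: no cover


def _spaced_frequencies(rng, n: int, lo_cm: float, hi_cm: float) -> np.ndarray:
    """Ascending frequencies with guaranteed spacing (eigenvector stability)."""
    base = np.linspace(lo_cm, hi_cm, n + 2)[1:-1]
    gap = (hi_cm - lo_cm) / (n + 1)
    jitter = rng.uniform(-0.3, 0.3, size=n) * gap
    return np.asarray(cm1_to_hartree(np.sort(base + jitter)))


def generate_model_system(spec: SyntheticSpec) -> GeneratedSystem:
    """Build a self-consistent harmonic surface pair and tensor field."""
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.resolved_n_atoms()
    n_total = 3 * n_atoms - 6
    n_active = spec.n_modes

    masses, coords = _random_geometry(rng, n_atoms)
    probe = MolecularSystem(masses=masses, coordinates=coords, label="synthetic-gs")
    sqm = np.sqrt(probe.masses_au)

    freqs = _spaced_frequencies(rng, n_total, *spec.frequency_range)
    rigid = _rigid_body_vectors(probe)
    vib_basis = scipy.linalg.null_space(rigid.T)
    q_rand, _ = np.linalg.qr(rng.normal(size=(n_total, n_total)))
    modes = vib_basis @ q_rand
    modes = _fix_mode_signs(modes / sqm[:, None], modes)

    hessian = (sqm[:, None] * modes) @ np.diag(freqs**2) @ (modes.T * sqm[None, :])
    hessian = 0.5 * (hessian + hessian.T)
    ground = MolecularSystem(
        masses=masses,
        coordinates=coords,
        hessian=hessian,
        gradient=np.zeros(3 * n_atoms),
        energy=0.0,
        label="synthetic-gs",
    )
    gs_basis = NormalModeBasis(freqs, modes)

    # excited surface by construction: Q' = J Q + K in the initial modes
    active = tuple(range(n_active))
    j_full = np.eye(n_total)
    if n_active > 1 and spec.duschinsky_angle_scale > 0:
        skew = rng.normal(size=(n_active, n_active))
        skew = (skew - skew.T) / np.sqrt(2.0)
        norm = np.linalg.norm(skew, 2)
        if norm > 0:
            skew *= spec.duschinsky_angle_scale / norm
        j_full[:n_active, :n_active] = scipy.linalg.expm(skew)
    wf = freqs.copy()
    if spec.frequency_change_scale > 0:
        jit = np.clip(
            rng.normal(0.0, spec.frequency_change_scale, size=n_active), -0.2, 0.2
        )
        wf[:n_active] = freqs[:n_active] * (1.0 + jit)
    k_full = np.zeros(n_total)
    k_full[:n_active] = rng.normal(0.0, spec.shift_scale, size=n_active) / np.sqrt(
        freqs[:n_active]
    )

    # canonicalize the final-mode sign gauge to the package convention so
    # that AH/VH reconstruction reproduces J and K including signs
    l_e = modes @ j_full.T
    l_e_fixed = _fix_mode_signs(l_e / sqm[:, None], l_e)
    gauge = np.sign(np.sum(l_e_fixed * l_e, axis=0))
    j_full = gauge[:, None] * j_full
    k_full = gauge * k_full

    reorg = 0.5 * float(np.sum(wf**2 * k_full**2))
    adiabatic_gap = spec.vertical_gap - reorg
    truth_model = VibronicModel(
        model_kind="exact",
        initial_frequencies=freqs,
        final_frequencies=wf,
        duschinsky_J=j_full,
        shift_K=k_full,
        energy_gap=adiabatic_gap,
        gap_kind="adiabatic",
        adiabatic_gap=adiabatic_gap,
    )

    # quantum-chemistry-like views of the excited surface
    q_min = -j_full.T @ k_full
    x_e = coords + (modes @ q_min / sqm).reshape(-1, 3)
    h_es = (
        (sqm[:, None] * modes)
        @ j_full.T
        @ np.diag(wf**2)
        @ j_full
        @ (modes.T * sqm[None, :])
    )
    h_es = 0.5 * (h_es + h_es.T)
    grad_modes = j_full.T @ (wf**2 * k_full)
    es_gradient_at_gs = (sqm[:, None] * modes @ grad_modes).reshape(-1)
    excited = MolecularSystem(
        masses=masses,
        coordinates=x_e,
        hessian=h_es,
        gradient=np.zeros(3 * n_atoms),
        energy=adiabatic_gap,
        label="synthetic-es",
    )

    # transition tensor field
    sigma = spec.derivative_tail_exponent
    s0 = _symmetric_tensor(
        spec.s0_xx_scale * rng.uniform(0.8, 1.2),
        *(rng.normal(0.0, spec.off_component_scale) for _ in range(5)),
    )
    b_list = []
    c_list = []
    for v in range(n_total):
        if v in active:
            b_list.append(_draw_tensor(rng, spec.b_xx_median, spec.b_off_ratio, sigma))
            c_list.append(_draw_tensor(rng, spec.c_xx_median, spec.b_off_ratio, sigma))
        else:
            b_list.append(np.zeros((3, 3)))
            c_list.append(np.zeros((3, 3)))
    expansion = HTExpansion(
        S0=Rank2TransitionTensor(s0),
        B=tuple(Rank2TransitionTensor(b) for b in b_list),
        C=tuple(Rank2TransitionTensor(c) for c in c_list),
    )

    b_arr = np.array(b_list)
    c_arr = np.array(c_list)
    x0 = coords.copy()

    def evaluator(system: MolecularSystem) -> Rank2TransitionTensor:
        dx = (np.asarray(system.coordinates) - x0).ravel()
        q = modes.T @ (sqm * dx)
        tensor = (
            s0
            + np.tensordot(q, b_arr, axes=(0, 0))
            + 0.5 * np.tensordot(q**2, c_arr, axes=(0, 0))
        )
        return Rank2TransitionTensor(tensor)

    return GeneratedSystem(
        spec=spec,
        ground=ground,
        gs_basis=gs_basis,
        excited=excited,
        es_gradient_at_gs=es_gradient_at_gs,
        vertical_gap=spec.vertical_gap,
        adiabatic_gap=adiabatic_gap,
        truth_model=truth_model,
        expansion=expansion,
        evaluator=evaluator,
        active_modes=active,
    )


@dataclass(frozen=True)
class PerturbedDerivativeSet(DerivativeSet):
    """A derivative set with a record of which entries had sign flips."""

    flipped: tuple[tuple[int, str], ...] = ()


def perturb_derivatives(
    truth: DerivativeSet,
    scale: float = 1.0,
    sign_flip_prob: float = 0.0,
    relative_noise: float = 0.0,
    seed: int = 0,
    method_label: str | None = None,
) -> PerturbedDerivativeSet:
    """Emulate a method-like derivative set from ground truth.

    Each value is multiplied by scale * (1 + noise) with Gaussian relative
    noise, and its sign is flipped with probability ``sign_flip_prob`` (the
    wrong-sign pathology some methods exhibit); flips are recorded.
    """
    if not 0.0 <= sign_flip_prob <= 1.0:
        raise ValueError("sign_flip_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    values = {}
    flipped = []
    # iteration in sorted key order keeps the draw sequence reproducible
    for key in sorted(truth.values):
        v = truth.values[key] * scale
        if relative_noise > 0:
            v *= 1.0 + rng.normal(0.0, relative_noise)
        if sign_flip_prob > 0 and rng.random() < sign_flip_prob:
            v = -v
            flipped.append(key)
        values[key] = v
    return PerturbedDerivativeSet(
        method_label=method_label
        or f"{truth.method_label}*{scale:g}"
        + (f"+noise{relative_noise:g}" if relative_noise else ""),
        values=values,
        mode_vectors=None if truth.mode_vectors is None else truth.mode_vectors.copy(),
        flipped=tuple(flipped),
    )


def derivative_set_from_expansion(
    expansion: HTExpansion,
    method_label: str = "truth",
    components: tuple[str, ...] = ("xx",),
    modes: tuple[int, ...] | None = None,
    mode_vectors: np.ndarray | None = None,
    order: int = 1,
) -> DerivativeSet:
    """Ground-truth derivative set (B, or C for order 2) of an expansion."""
    comp_index = {"xx": (0, 0), "yy": (1, 1), "zz": (2, 2),
                  "xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}
    tensors = expansion.B if order == 1 else expansion.C
    if tensors is None:
        raise ValueError("expansion has no second derivatives")
    mode_list = modes if modes is not None else tuple(range(len(tensors)))
    values = {
        (v, c): float(tensors[v].components[comp_index[c]])
        for v in mode_list
        for c in components
    }
    return DerivativeSet(method_label, values, mode_vectors)


def derivative_set_from_mode_derivatives(
    derivs: dict[int, ModeDerivative],
    method_label: str,
    components: tuple[str, ...] = ("xx",),
    mode_vectors: np.ndarray | None = None,
    stable_only: bool = False,
) -> DerivativeSet:
    """Collect Romberg-selected derivatives into a DerivativeSet."""
    comp_index = {"xx": (0, 0), "yy": (1, 1), "zz": (2, 2),
                  "xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}
    values = {}
    for v, md in sorted(derivs.items()):
        for c in components:
            i, j = comp_index[c]
            if stable_only and not md.stable[i, j]:
                continue
            values[(v, c)] = float(md.tensor[i, j])
    return DerivativeSet(method_label, values, mode_vectors)


# -- fixture bundles --------------------------------------------------------

def write_fixture(generated: GeneratedSystem, path: str | Path) -> None:
    """Write a fixture bundle (one JSON per object + a seeded manifest)."""
    from . import interchange as io

    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    io.write_system(generated.ground, root / "ground.json")
    io.write_system(generated.excited, root / "excited.json")
    io.write_expansion(generated.expansion, root / "expansion.json")
    io.write_model(
        VibronicModel(
            model_kind="AH",
            initial_frequencies=generated.truth_model.initial_frequencies,
            final_frequencies=generated.truth_model.final_frequencies,
            duschinsky_J=generated.truth_model.duschinsky_J,
            shift_K=generated.truth_model.shift_K,
            energy_gap=generated.adiabatic_gap,
            gap_kind="adiabatic",
            adiabatic_gap=generated.adiabatic_gap,
        ),
        root / "model_truth.json",
    )
    spec_dict = asdict(generated.spec)
    spec_dict["frequency_range"] = list(generated.spec.frequency_range)
    manifest = {
        "spec": spec_dict,
        "seed": generated.spec.seed,
        "vertical_gap_hartree": generated.vertical_gap,
        "adiabatic_gap_hartree": generated.adiabatic_gap,
        "active_modes": list(generated.active_modes),
        "es_gradient_at_gs_au": generated.es_gradient_at_gs.tolist(),
        "files": ["ground.json", "excited.json", "expansion.json",
                  "model_truth.json"],
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_fixture(path: str | Path) -> GeneratedSystem:
    """Regenerate the bundle's system from its recorded spec and seed.

    The generator is deterministic in the seed, so the regenerated system is
    bit-identical to the one the bundle was written from; the stored files
    serve interchange with other tools.
    """
    root = Path(path)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    spec_dict = dict(manifest["spec"])
    spec_dict["frequency_range"] = tuple(spec_dict["frequency_range"])
    return generate_model_system(SyntheticSpec(**spec_dict))


# -- small direct-model helpers (oracle-scale tests) ------------------------

def random_vibronic_model(
    rng: np.random.Generator,
    n_modes: int = 2,
    shift_scale: float = 0.6,
    angle_scale: float = 0.35,
    frequency_change_scale: float = 0.1,
) -> VibronicModel:
    """A random 1-2 mode Duschinsky model (no Cartesian backing)."""
    w = np.sort(np.asarray(cm1_to_hartree(rng.uniform(600.0, 2000.0, size=n_modes))))
    wf = w * (1.0 + np.clip(rng.normal(0, frequency_change_scale, n_modes), -0.3, 0.3))
    if n_modes > 1 and angle_scale > 0:
        skew = rng.normal(size=(n_modes, n_modes))
        skew = skew - skew.T
        norm = np.linalg.norm(skew, 2)
        j = scipy.linalg.expm(skew * (angle_scale / norm))
    else:
        j = np.eye(n_modes)
    k = rng.normal(0.0, shift_scale, size=n_modes) / np.sqrt(w)
    gap = 0.12
    model = VibronicModel(
        model_kind="VH",
        initial_frequencies=w,
        final_frequencies=wf,
        duschinsky_J=j,
        shift_K=k,
        energy_gap=gap,
        gap_kind="vertical",
        adiabatic_gap=gap - 0.5 * float(np.sum(wf**2 * k**2)),
    )
    return model


def random_expansion(
    rng: np.random.Generator, n_modes: int, s0_scale: float = 5.0, b_scale: float = 0.5
) -> HTExpansion:
    """A random dense HT expansion for oracle-scale tests."""
    def sym(scale):
        m = rng.normal(0.0, scale, size=(3, 3))
        return Rank2TransitionTensor(0.5 * (m + m.T))

    return HTExpansion(
        S0=sym(s0_scale), B=tuple(sym(b_scale) for _ in range(n_modes))
    )
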