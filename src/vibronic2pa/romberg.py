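"""Rutishauser-Romberg numerical differentiation.

Central differences on a geometric mesh of displacements +-2^k * Delta
(k = 0..K, i.e. 10 displaced points for the default K = 4) are refined by
Richardson extrapolation into a Romberg triangle; the stable entry is the one
minimizing the difference between adjacent rows of a refinement column.
Tensor-valued properties are differentiated component by component, each with
its own triangle and error estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .core_tensors import Rank2TransitionTensor
from .normal_modes import (
    MolecularSystem,
    NormalModeBasis,
    displace_along_coordinate,
    displacement_steps,
)

__all__ = [
    "DisplacementMesh",
    "RombergTriangle",
    "ModeDerivative",
    "central_difference",
    "build_romberg_triangle",
    "differentiate_tensor_function",
]

#: default relative-error acceptance threshold for a derivative component
#: (second-derivative numerical quality screening)
DEFAULT_ACCEPT_THRESHOLD = 0.04


@dataclass(frozen=True)
class DisplacementMesh:
    """Scalar property values on the geometric mesh +-2^k * Delta."""

    base_step: float
    levels: int
    values: Mapping[float, float]
    value_at_zero: float = 0.0

    def at(self, step: float) -> float:
        try:
            return self.values[step]
        except KeyError:
            raise KeyError(f"mesh is missing the point at step {step:g}") from None

    @classmethod
    def from_function(
        cls, f: Callable[[float], float], base_step: float, levels: int = 4
    ) -> "DisplacementMesh":
        steps = displacement_steps(base_step, levels)
        return cls(base_step, levels, {s: f(s) for s in steps}, f(0.0))


@dataclass(frozen=True)
class RombergTriangle:
    """Lower-triangular table of refined difference estimates.

    ``estimates[k][l]``: row k uses step 2^k * Delta; column l has been
    refined l times, so column l holds one fewer row than column l-1.
    """

    estimates: list[list[float]]
    selected_value: float
    error_estimate: float
    stability_flag: bool
    selected_index: tuple[int, int] = (0, 0)


def central_difference(mesh: DisplacementMesh, order: int, level: int = 0) -> float:
    """Raw symmetric difference quotient at step h = 2^level * Delta."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if not 0 <= level <= mesh.levels:
        raise ValueError(f"level must be within 0..{mesh.levels}")
    h = mesh.base_step * 2.0**level
    fp, fm = mesh.at(h), mesh.at(-h)
    if order == 1:
        return (fp - fm) / (2.0 * h)
    return (fp - 2.0 * mesh.value_at_zero + fm) / h**2


def build_romberg_triangle(
    mesh: DisplacementMesh,
    order: int,
    rel_tolerance: float = DEFAULT_ACCEPT_THRESHOLD,
) -> RombergTriangle:
    """Refine central differences and select the stable entry.

    The refinement D[k][l+1] = (4^(l+1) D[k][l] - D[k+1][l]) / (4^(l+1) - 1)
    cancels successive even powers of the step.  The selected value is the
    entry minimizing |D[k][l] - D[k+1][l]| over the triangle (the "region of
    stability"); that minimal difference is reported as the error estimate,
    and the stability flag records whether it is below ``rel_tolerance``
    relative to the selected value.
    """
    n = mesh.levels + 1
    col = [central_difference(mesh, order, k) for k in range(n)]
    columns = [col]
    for l in range(1, n):
        fac = 4.0**l
        col = [
            (fac * columns[-1][k] - columns[-1][k + 1]) / (fac - 1.0)
            for k in range(len(columns[-1]) - 1)
        ]
        columns.append(col)
    # round-off guard on the raw smallest-step difference
    scale = max(abs(mesh.value_at_zero), max(abs(v) for v in mesh.values.values()))
    h0 = mesh.base_step
    raw_span = abs(mesh.at(h0) - mesh.at(-h0)) if order == 1 else abs(
        mesh.at(h0) - 2 * mesh.value_at_zero + mesh.at(-h0)
    )
    # an exactly constant mesh (raw_span == 0) is a clean zero, not round-off
    if scale > 0 and 0 < raw_span < 1e3 * np.finfo(float).eps * scale:
        warnings.warn(
            "smallest-step difference is at round-off level; derivative "
            "precision is limited",
            RuntimeWarning,
        )

    best: tuple[int, int] | None = None
    best_diff = np.inf
    for l, column in enumerate(columns):
        for k in range(len(column) - 1):
            d = abs(column[k] - column[k + 1])
            if d < best_diff:
                best_diff = d
                best = (k, l)
    if best is None:  # single-row mesh: no stability information
        sel = columns[0][0]
        return RombergTriangle([columns[0]], sel, np.inf, False, (0, 0))
    k, l = best
    selected = columns[l][k]
    denom = max(abs(selected), np.finfo(float).tiny)
    stable = bool(best_diff <= rel_tolerance * denom or best_diff == 0.0)
    # re-shape as rows for inspection: row k holds entries for all valid l
    rows = [
        [columns[l][k] for l in range(n - k)] for k in range(n)
    ]
    return RombergTriangle(rows, selected, best_diff, stable, (k, l))


@dataclass(frozen=True)
class ModeDerivative:
    """Romberg-selected derivative of a 3x3 tensor along one normal mode."""

    mode_index: int
    order: int
    tensor: np.ndarray
    error_estimate: np.ndarray
    stable: np.ndarray
    step: float = field(default=0.0)

    def as_tensor(self) -> Rank2TransitionTensor:
        return Rank2TransitionTensor(self.tensor)


def differentiate_tensor_function(
    evaluator: Callable[[MolecularSystem], Rank2TransitionTensor],
    system: MolecularSystem,
    basis: NormalModeBasis,
    modes: Iterable[int] | None = None,
    order: int = 1,
    base_step: float = 0.01,
    levels: int = 4,
    step_unit: str = "dimensionless",
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD,
) -> dict[int, ModeDerivative]:
    """Differentiate a geometry-dependent tensor along normal modes.

    Each of the nine tensor components runs through its own Romberg triangle;
    derivatives are returned per *mass-weighted* normal coordinate (a.u.).
    ``step_unit`` controls how ``base_step`` is interpreted: "dimensionless"
    (default 0.01; converted per mode as Delta_v = step / sqrt(omega_v), which
    keeps every mode within its harmonic region) or "mass_weighted" (used
    as-is for every mode).  Components whose relative error estimate exceeds
    ``accept_threshold`` are flagged unstable so that downstream statistics
    can exclude them.
    """
    if step_unit not in ("dimensionless", "mass_weighted"):
        raise ValueError("step_unit must be 'dimensionless' or 'mass_weighted'")
    mode_list = list(modes) if modes is not None else list(range(basis.n_modes))
    out: dict[int, ModeDerivative] = {}
    for v in mode_list:
        if step_unit == "dimensionless":
            w = basis.frequencies[v]
            if w <= 0:
                raise ValueError(
                    f"mode {v} has non-positive frequency; pass a "
                    "mass-weighted step instead"
                )
            delta = base_step / np.sqrt(w)
        else:
            delta = base_step
        steps = displacement_steps(delta, levels)
        try:
            values = {
                s: evaluator(displace_along_coordinate(system, basis, v, s)).components
                for s in steps
            }
            value0 = evaluator(system).components
        except Exception as exc:
            raise RuntimeError(
                f"evaluator failed on a mesh point of mode {v}: {exc}"
            ) from exc
        tensor = np.empty((3, 3))
        err = np.empty((3, 3))
        stable = np.empty((3, 3), dtype=bool)
        for a in range(3):
            for b in range(3):
                mesh = DisplacementMesh(
                    delta,
                    levels,
                    {s: values[s][a, b] for s in steps},
                    value0[a, b],
                )
                tri = build_romberg_triangle(mesh, order, accept_threshold)
                tensor[a, b] = tri.selected_value
                err[a, b] = tri.error_estimate
                stable[a, b] = tri.stability_flag
        out[v] = ModeDerivative(v, order, tensor, err, stable, delta)
    return out
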