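"""JSON interchange format for molecular systems, tensors, expansions and
vibronic models.

Schemas are pydantic models; validation errors carry the JSON location of
the offending or missing key.  Floats are serialized at full repr precision
so that read(write(x)) round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

from .benchmark_stats import DerivativeSet
from .core_tensors import Rank2TransitionTensor
from .normal_modes import MolecularSystem
from .vibronic_models import VibronicModel
from .vibronic_spectrum import HTExpansion

__all__ = [
    "SystemRecord",
    "TensorRecord",
    "ExpansionRecord",
    "ModelRecord",
    "DerivativeSetRecord",
    "read_system",
    "write_system",
    "read_expansion",
    "write_expansion",
    "read_model",
    "write_model",
    "read_derivative_set",
    "write_derivative_set",
    "InterchangeError",
]


class InterchangeError(ValueError):
    """Raised when an interchange file fails schema validation."""


class _Record(BaseModel):
    model_config = ConfigDict(extra="allow")


class SystemRecord(_Record):
    masses_amu: list[float]
    coordinates_bohr: list[list[float]]
    hessian_au: Optional[list[list[float]]] = None
    gradient_au: Optional[list[float]] = None
    energy_hartree: float = 0.0
    label: str = ""


class TensorRecord(_Record):
    S0: list[list[float]]
    units: Literal["au"] = "au"
    hermitian: bool = True
    state_labels: str = ""


class ExpansionRecord(_Record):
    S0: list[list[float]]
    units: Literal["au"] = "au"
    dS_dQ_au: list[list[list[float]]]
    d2S_dQ2_au: Optional[list[list[list[float]]]] = None


class ModelRecord(_Record):
    model_kind: Literal["AH", "VH", "VG"]
    J: list[list[float]]
    K_au: list[float]
    freq_initial_au: list[float]
    freq_final_au: list[float]
    gap_hartree: float
    gap_kind: Literal["adiabatic", "vertical"]
    adiabatic_gap_hartree: Optional[float] = None


class DerivativeSetRecord(_Record):
    method_label: str
    modes: list[int]
    components: list[str]
    values_au: list[float]
    mode_vectors: Optional[list[list[float]]] = None


def _validate(record_cls, payload: dict, path: str | Path):
    try:
        return record_cls.model_validate(payload)
    except ValidationError as exc:
        locs = "; ".join(
            "/" + "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise InterchangeError(f"{path}: {locs}") from exc


def _load(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _dump(payload: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# -- systems ----------------------------------------------------------------

def write_system(system: MolecularSystem, path: str | Path) -> None:
    payload = {
        "masses_amu": system.masses.tolist(),
        "coordinates_bohr": system.coordinates.tolist(),
        "energy_hartree": system.energy,
        "label": system.label,
    }
    if system.hessian is not None:
        payload["hessian_au"] = system.hessian.tolist()
    if system.gradient is not None:
        payload["gradient_au"] = system.gradient.tolist()
    _dump(payload, path)


def read_system(path: str | Path) -> MolecularSystem:
    rec = _validate(SystemRecord, _load(path), path)
    return MolecularSystem(
        masses=np.array(rec.masses_amu),
        coordinates=np.array(rec.coordinates_bohr),
        hessian=None if rec.hessian_au is None else np.array(rec.hessian_au),
        gradient=None if rec.gradient_au is None else np.array(rec.gradient_au),
        energy=rec.energy_hartree,
        label=rec.label,
    )


# -- HT expansions ----------------------------------------------------------

def write_expansion(expansion: HTExpansion, path: str | Path) -> None:
    payload = {
        "S0": expansion.S0.components.tolist(),
        "units": "au",
        "dS_dQ_au": [b.components.tolist() for b in expansion.B],
    }
    if expansion.C is not None:
        payload["d2S_dQ2_au"] = [c.components.tolist() for c in expansion.C]
    _dump(payload, path)


def read_expansion(path: str | Path) -> HTExpansion:
    rec = _validate(ExpansionRecord, _load(path), path)
    return HTExpansion(
        S0=Rank2TransitionTensor(np.array(rec.S0)),
        B=tuple(Rank2TransitionTensor(np.array(b)) for b in rec.dS_dQ_au),
        C=None
        if rec.d2S_dQ2_au is None
        else tuple(Rank2TransitionTensor(np.array(c)) for c in rec.d2S_dQ2_au),
    )


# -- vibronic models --------------------------------------------------------

def write_model(model: VibronicModel, path: str | Path) -> None:
    _dump(
        {
            "model_kind": model.model_kind,
            "J": model.duschinsky_J.tolist(),
            "K_au": model.shift_K.tolist(),
            "freq_initial_au": model.initial_frequencies.tolist(),
            "freq_final_au": model.final_frequencies.tolist(),
            "gap_hartree": model.energy_gap,
            "gap_kind": model.gap_kind,
            "adiabatic_gap_hartree": model.adiabatic_gap,
        },
        path,
    )


def read_model(path: str | Path) -> VibronicModel:
    rec = _validate(ModelRecord, _load(path), path)
    return VibronicModel(
        model_kind=rec.model_kind,
        initial_frequencies=np.array(rec.freq_initial_au),
        final_frequencies=np.array(rec.freq_final_au),
        duschinsky_J=np.array(rec.J),
        shift_K=np.array(rec.K_au),
        energy_gap=rec.gap_hartree,
        gap_kind=rec.gap_kind,
        adiabatic_gap=rec.adiabatic_gap_hartree
        if rec.adiabatic_gap_hartree is not None
        else rec.gap_hartree,
    )


# -- derivative sets --------------------------------------------------------

def write_derivative_set(dset: DerivativeSet, path: str | Path) -> None:
    keys = sorted(dset.values)
    payload = {
        "method_label": dset.method_label,
        "modes": [m for m, _ in keys],
        "components": [c for _, c in keys],
        "values_au": [dset.values[k] for k in keys],
    }
    if dset.mode_vectors is not None:
        payload["mode_vectors"] = dset.mode_vectors.tolist()
    _dump(payload, path)


def read_derivative_set(path: str | Path) -> DerivativeSet:
    rec = _validate(DerivativeSetRecord, _load(path), path)
    if not len(rec.modes) == len(rec.components) == len(rec.values_au):
        raise InterchangeError(f"{path}: modes/components/values lengths differ")
    return DerivativeSet(
        method_label=rec.method_label,
        values={
            (m, c): v
            for m, c, v in zip(rec.modes, rec.components, rec.values_au)
        },
        mode_vectors=None
        if rec.mode_vectors is None
        else np.array(rec.mode_vectors),
    )
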