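"""Error statistics for normal-mode derivative sets across electronic-
structure methods.

Implements the benchmark machinery for comparing per-mode, per-component
transition-moment derivatives obtained with different methods against a
reference: phase alignment of normal modes across codes (mode phases are an
arbitrary gauge), MAPE/MAE/SDE/RMSE/MAX-AE summaries, and per-component
average/median/max tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "DerivativeSet",
    "ErrorSummary",
    "align_mode_phases",
    "error_statistics",
    "component_summary",
    "ranking_report",
    "format_markdown_table",
]

COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz", "yx", "zx", "zy")


@dataclass(frozen=True)
class DerivativeSet:
    """Per-(mode, tensor-component) derivative values of one method.

    Keys of ``values`` are (mode_index, component) pairs, components named
    "xx", "xy", ...; ``mode_vectors`` (3N x n_modes, mass-weighted) are only
    required for cross-code phase alignment.
    """

    method_label: str
    values: dict[tuple[int, str], float]
    mode_vectors: np.ndarray | None = None

    def __post_init__(self):
        keys = list(self.values)
        if len(set(keys)) != len(keys):  # dict cannot hold dupes; defensive
            raise ValueError("duplicate (mode, component) keys")
        object.__setattr__(self, "values", dict(self.values))

    def modes(self) -> list[int]:
        return sorted({m for m, _ in self.values})


@dataclass(frozen=True)
class ErrorSummary:
    """MAPE [%], MAE/SDE/RMSE/MAX_AE [a.u.] of a candidate vs a reference.

    SDE is the sample (n-1) standard deviation of the signed errors, so that
    RMSE^2 = SDE^2 (n-1)/n + mean_error^2.
    """

    MAPE: float
    MAE: float
    SDE: float
    RMSE: float
    MAX_AE: float
    n: int
    method_label: str = ""


def align_mode_phases(
    candidate: DerivativeSet,
    reference: DerivativeSet,
    min_overlap: float = 0.5,
) -> DerivativeSet:
    """Match candidate modes to reference modes and fix derivative signs.

    Modes are paired by maximal absolute overlap of their mass-weighted mode
    vectors (optimal assignment); wherever the matched overlap is negative
    the candidate derivative sign is flipped.  Candidate keys are re-indexed
    to the reference mode numbering.
    """
    if candidate.mode_vectors is None or reference.mode_vectors is None:
        raise ValueError("both sets must carry mode_vectors for alignment")
    lc = candidate.mode_vectors
    lr = reference.mode_vectors
    if lc.shape[0] != lr.shape[0]:
        raise ValueError("mode vectors are not on a common atom ordering")
    overlap = lc.T @ lr  # (n_cand, n_ref)
    row, col = linear_sum_assignment(-np.abs(overlap))
    bad = [
        (int(c), int(r))
        for c, r in zip(row, col)
        if abs(overlap[c, r]) < min_overlap
    ]
    if bad:
        raise ValueError(
            "ambiguous mode matching (|overlap| < "
            f"{min_overlap}) for candidate/reference pairs: {bad}"
        )
    cand_to_ref = {int(c): int(r) for c, r in zip(row, col)}
    signs = {int(c): float(np.sign(overlap[c, r])) for c, r in zip(row, col)}
    new_values = {}
    for (mode, comp), val in candidate.values.items():
        if mode not in cand_to_ref:
            raise KeyError(f"candidate mode {mode} has no matched reference mode")
        new_values[(cand_to_ref[mode], comp)] = signs[mode] * val
    new_vectors = lc[:, row] * np.array([signs[int(c)] for c in row])
    # order columns by reference index
    order = np.argsort(col)
    return DerivativeSet(
        method_label=candidate.method_label,
        values=new_values,
        mode_vectors=new_vectors[:, order],
    )


def error_statistics(
    candidate: DerivativeSet, reference: DerivativeSet
) -> ErrorSummary:
    """Summary statistics of candidate - reference over shared keys.

    Pairs with a reference value of exactly zero are excluded from the MAPE
    only (with a warning); an epsilon floor would make the MAPE threshold
    dependent.
    """
    if set(candidate.values) != set(reference.values):
        raise ValueError("key sets differ; align the sets first")
    keys = sorted(candidate.values)
    x = np.array([candidate.values[k] for k in keys])
    r = np.array([reference.values[k] for k in keys])
    e = x - r
    nonzero = r != 0
    if not np.all(nonzero):
        warnings.warn(
            f"{np.sum(~nonzero)} zero reference values excluded from MAPE",
            RuntimeWarning,
        )
    mape = float(100.0 * np.mean(np.abs(e[nonzero]) / np.abs(r[nonzero])))
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    sde = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    return ErrorSummary(
        MAPE=mape,
        MAE=mae,
        SDE=sde,
        RMSE=rmse,
        MAX_AE=float(np.max(np.abs(e))),
        n=int(e.size),
        method_label=candidate.method_label,
    )


def component_summary(dset: DerivativeSet) -> pd.DataFrame:
    """Average/median/max of |value| per tensor component, with the mode
    index attaining the maximum."""
    if not dset.values:
        raise ValueError("empty derivative set")
    rows = []
    comps = sorted({c for _, c in dset.values}, key=lambda c: COMPONENTS.index(c))
    for comp in comps:
        items = sorted(
            (m, abs(v)) for (m, c), v in dset.values.items() if c == comp
        )
        vals = np.array([v for _, v in items])
        imax = int(np.argmax(vals))
        rows.append(
            {
                "component": comp,
                "average": float(np.mean(vals)),
                "median": float(np.median(vals)),
                "max": float(vals[imax]),
                "argmax_mode": int(items[imax][0]),
            }
        )
    return pd.DataFrame(rows).set_index("component")


def ranking_report(
    candidates: list[DerivativeSet],
    reference: DerivativeSet,
    align: bool = False,
) -> pd.DataFrame:
    """Per-method error summaries, ordered by increasing MAPE."""
    rows = []
    for cand in candidates:
        c = align_mode_phases(cand, reference) if align else cand
        s = error_statistics(c, reference)
        rows.append(
            {
                "method": s.method_label,
                "MAPE [%]": s.MAPE,
                "MAE [a.u.]": s.MAE,
                "SDE [a.u.]": s.SDE,
                "RMSE [a.u.]": s.RMSE,
                "MAX AE [a.u.]": s.MAX_AE,
                "n": s.n,
            }
        )
    df = pd.DataFrame(rows).sort_values("MAPE [%]", kind="stable")
    return df.reset_index(drop=True)


def format_markdown_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    """Minimal Markdown rendering of a DataFrame (no external deps)."""
    df = df.reset_index() if df.index.name else df
    cols = list(df.columns)

    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)

    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"
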