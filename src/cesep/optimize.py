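"""Constrained maximization of the modeled efficiency index.

The fitted E surface is maximized over the coded hypercube [-1, 1]^k
subject to the fitted last-analyte migration time staying at or below a
separation-time limit (default 15 min).  The search is a coarse grid scan
(default 11 points per axis) followed by successive local grid refinement
around the best feasible point: the box is shrunk and re-gridded until the
step size is far below the reporting precision.  The procedure is
derivative-free, handles the constraint exactly by masking, and is fully
deterministic (the ``seed`` argument is accepted for interface symmetry but
no randomness is used).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .design import FactorSpace
from .errors import DomainError
from .rsm import QuadraticModel

#: Separation-time constraint on the last analyte (min).
DEFAULT_MT_LIMIT = 15.0


@dataclass
class OptimizationResult:
    settings: dict[str, float]  # natural units
    coded: np.ndarray
    predicted_e: float
    predicted_mt_last: float
    feasible: bool
    trace: list[dict] = field(default_factory=list)
    best_violation: float | None = None

    def as_dict(self) -> dict:
        return {
            "settings": self.settings,
            "coded": [float(v) for v in self.coded],
            "predicted_e": self.predicted_e,
            "predicted_mt_last": self.predicted_mt_last,
            "feasible": self.feasible,
            "best_violation": self.best_violation,
        }


def predict(model: QuadraticModel, settings, fs: FactorSpace) -> float:
    """Evaluate a fitted model at natural-unit factor settings."""
    coded = fs.code(settings)
    return float(model.predict_coded(np.atleast_2d(coded))[0])


def _axis_grids(center: np.ndarray, half: float, n: int, k: int) -> list[np.ndarray]:
    return [
        np.linspace(
            max(-1.0, center[i] - half), min(1.0, center[i] + half), n
        )
        for i in range(k)
    ]


def _eval_grid(e_model, mt_model, axes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    e = e_model.predict_coded(pts)
    mt = mt_model.predict_coded(pts)
    return pts, e, mt


def optimize_efficiency(
    e_model: QuadraticModel,
    mt_model: QuadraticModel,
    fs: FactorSpace,
    mt_limit: float = DEFAULT_MT_LIMIT,
    seed: int | None = None,
    grid: int = 11,
    refinements: int = 10,
    shrink: float = 0.35,
) -> OptimizationResult:
    """Maximize predicted E subject to predicted last-analyte MT <= mt_limit.

    Returns an infeasible result carrying the smallest constraint violation
    when no point of the coded box satisfies the limit.
    """
    if grid < 3:
        raise DomainError("grid must have at least 3 points per axis")
    if set(e_model.spec.factor_names) != set(fs.names) or set(
        mt_model.spec.factor_names
    ) != set(fs.names):
        raise DomainError("models and factor space must share the same factors")
    k = fs.k
    trace: list[dict] = []

    # Coarse scan of the whole box.
    axes = _axis_grids(np.zeros(k), 1.0, grid, k)
    pts, e, mt = _eval_grid(e_model, mt_model, axes)
    feasible = mt <= mt_limit
    coarse_best_e = float(np.max(e[feasible])) if np.any(feasible) else None

    if not np.any(feasible):
        j = int(np.argmin(mt))
        coded = pts[j]
        return OptimizationResult(
            settings=fs.decode_dict(coded),
            coded=coded,
            predicted_e=float(e[j]),
            predicted_mt_last=float(mt[j]),
            feasible=False,
            trace=trace,
            best_violation=float(mt[j] - mt_limit),
        )

    masked = np.where(feasible, e, -np.inf)
    j = int(np.argmax(masked))
    best_pt, best_e, best_mt = pts[j], float(e[j]), float(mt[j])
    trace.append({"stage": 0, "half_width": 1.0, "e": best_e, "mt": best_mt})

    half = 1.0
    for stage in range(1, refinements + 1):
        half *= shrink
        axes = _axis_grids(best_pt, half, grid, k)
        pts, e, mt = _eval_grid(e_model, mt_model, axes)
        masked = np.where(mt <= mt_limit, e, -np.inf)
        j = int(np.argmax(masked))
        if np.isfinite(masked[j]) and masked[j] >= best_e:
            best_pt, best_e, best_mt = pts[j], float(e[j]), float(mt[j])
        trace.append({"stage": stage, "half_width": half, "e": best_e, "mt": best_mt})

    # The refined optimum can never fall below the best coarse feasible point.
    assert coarse_best_e is None or best_e >= coarse_best_e - 1e-12
    return OptimizationResult(
        settings=fs.decode_dict(best_pt),
        coded=np.asarray(best_pt, dtype=float),
        predicted_e=best_e,
        predicted_mt_last=best_mt,
        feasible=True,
        trace=trace,
    )
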