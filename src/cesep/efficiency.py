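"""Overall separation efficiency index *E* for multi-analyte CE runs.

A single electropherogram is scored by combining the resolutions of its
critical peak pairs into one number::

    E = mean(capped Rs) * P

where every resolution is first capped at 1.5 (values beyond baseline
separation should not inflate the score), and P is a quadratic penalty that
engages only when at least one pair is under-resolved (Rs < 1)::

    P = ( sum_j Rs_j^2 / m ) ** 1.25      over the m values with Rs < 1
    P = 1                                  when no value is below 1

E therefore ranges from 0 (total co-elution of every pair) to 1.5 (all
pairs at or beyond baseline resolution).  When all resolutions are >= 1 the
index reduces exactly to the mean of the capped values.

Note that the index is deliberately discontinuous where a component crosses
Rs = 1: the penalized set changes size, so nudging one pair from 0.999 to
1.0 can *lower* E.  This is inherent to the definition and is preserved
as-is rather than smoothed away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError

#: Resolutions at or above this value count as fully separated.
DEFAULT_CAP = 1.5

#: Exponent of the quadratic penalty term.
PENALTY_EXPONENT = 1.25


@dataclass(frozen=True)
class ResolutionSet:
    """Ordered resolutions for the monitored critical pairs of one run."""

    rs: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        values = np.asarray(self.rs, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise DomainError("a ResolutionSet needs at least one resolution value")
        if not np.all(np.isfinite(values)):
            raise DomainError("resolutions must be finite")
        if np.any(values < 0):
            raise DomainError("resolutions must be nonnegative")
        if self.labels is not None and len(self.labels) != values.size:
            raise DomainError("labels length must match number of resolutions")
        object.__setattr__(self, "rs", tuple(float(v) for v in values))

    def __len__(self):
        return len(self.rs)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.rs, dtype=float)


@dataclass(frozen=True)
class EfficiencyResult:
    """Value of the E index together with its ingredients."""

    e: float
    capped: tuple[float, ...]
    penalized: tuple[float, ...]
    p: float
    n: int
    m: int
    reading: str = "mean"

    def as_dict(self) -> dict:
        return {
            "E": self.e,
            "P": self.p,
            "n": self.n,
            "m": self.m,
            "capped": list(self.capped),
            "penalized": list(self.penalized),
        }


def _as_values(rs: ResolutionSet | Sequence[float]) -> np.ndarray:
    if isinstance(rs, ResolutionSet):
        return rs.values
    values = np.asarray(rs, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise DomainError("expected a nonempty 1-D sequence of resolutions")
    if not np.all(np.isfinite(values)):
        raise DomainError("resolutions must be finite")
    if np.any(values < 0):
        raise DomainError("resolutions must be nonnegative")
    return values


def cap_resolutions(rs: ResolutionSet | Sequence[float], cap: float = DEFAULT_CAP) -> np.ndarray:
    """Clip resolutions at ``cap`` (default 1.5), preserving order."""
    if cap <= 0:
        raise DomainError("cap must be positive")
    return np.minimum(_as_values(rs), cap)


def penalty(rs: ResolutionSet | Sequence[float], reading: str = "mean") -> float:
    """Quadratic penalty P for under-resolved pairs.

    ``reading`` selects how the exponent in the penalty is attached:

    - ``"mean"`` (default): P = (sum(Rs_j^2)/m)^1.25 — damped mean of squares.
    - ``"sum"``: P = sum(Rs_j^2)/m^1.25 — exponent on the count only.

    Both stay in (0, 1] for sub-1 inputs, so the E bound is unaffected.
    P = 1 when no resolution is below 1.
    """
    values = _as_values(rs)
    sub = values[values < 1.0]
    m = sub.size
    if m == 0:
        return 1.0
    if reading == "mean":
        return float((np.sum(sub**2) / m) ** PENALTY_EXPONENT)
    if reading == "sum":
        return float(np.sum(sub**2) / m**PENALTY_EXPONENT)
    raise ValueError(f"unknown penalty reading: {reading!r}")


def efficiency_index(
    rs: ResolutionSet | Sequence[float],
    cap: float = DEFAULT_CAP,
    reading: str = "mean",
) -> EfficiencyResult:
    """Compute the overall separation efficiency index E.

    Parameters
    ----------
    rs:
        Resolutions of the critical pairs (nonnegative, at least one).
    cap:
        Upper clip applied to every resolution before averaging.
    reading:
        Penalty variant, see :func:`penalty`.

    Returns
    -------
    EfficiencyResult
        E together with the capped values, the penalized subset, P, n and m.
    """
    values = _as_values(rs)
    capped = np.minimum(values, cap)
    sub = values[values < 1.0]
    p = penalty(values, reading=reading)
    e = float(np.mean(capped) * p)
    return EfficiencyResult(
        e=e,
        capped=tuple(float(v) for v in capped),
        penalized=tuple(float(v) for v in sub),
        p=float(p),
        n=int(values.size),
        m=int(sub.size),
        reading=reading,
    )
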