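"""Factor space, coded-level handling and D-optimal design construction.

The buffer composition is described by four numerical factors, each mapped
to a coded level in [-1, 1] by the usual RSM transform
``coded = (x - center) / half_range``.  Designs for the full quadratic model
(intercept + linear + two-factor interactions + pure quadratics, 15 terms in
4 factors) are built by Fedorov point exchange over a full-factorial
candidate grid, maximizing det(X'X) of the model-expanded design matrix.

Replicate runs for a pure-error estimate are appended after the exchange by
duplicating the highest-leverage selected points.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, RankDeficiencyError


@dataclass(frozen=True)
class Factor:
    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self):
        if not self.low < self.high:
            raise DomainError(f"factor {self.name!r}: low must be < high")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


class FactorSpace:
    """Ordered collection of factors with coding/decoding utilities."""

    def __init__(self, factors: Sequence[Factor]):
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise DomainError("factor names must be unique")
        self.factors = tuple(factors)

    @classmethod
    def default(cls) -> "FactorSpace":
        """The four buffer factors of the optimized MEKC method."""
        return cls(
            [
                Factor("boric_acid", 20.0, 60.0, "mM"),
                Factor("doc", 30.0, 100.0, "mM"),
                Factor("meoh", 0.0, 25.0, "%"),
                Factor("ph", 9.0, 9.6, ""),
            ]
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def k(self) -> int:
        return len(self.factors)

    def __len__(self):
        return len(self.factors)

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise LookupError(f"unknown factor: {name!r}")

    def _as_array(self, values) -> np.ndarray:
        if isinstance(values, Mapping):
            unknown = sorted(set(values) - set(self.names))
            if unknown:
                raise LookupError(f"unknown factor(s): {unknown}")
            missing = sorted(set(self.names) - set(values))
            if missing:
                raise LookupError(f"missing factor(s): {missing}")
            values = [values[n] for n in self.names]
        arr = np.asarray(values, dtype=float)
        if arr.shape[-1] != self.k:
            raise DomainError(f"expected {self.k} factor values, got shape {arr.shape}")
        return arr

    def code(self, natural) -> np.ndarray:
        """Natural units -> coded levels; warns if slightly outside the range."""
        arr = self._as_array(natural)
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        coded = (arr - centers) / halves
        if np.any(np.abs(coded) > 1.0 + 1e-9):
            worst = np.max(np.abs(coded))
            warnings.warn(
                f"factor setting outside the design range (|coded| up to {worst:.3g})",
                stacklevel=2,
            )
        return coded

    def decode(self, coded) -> np.ndarray:
        arr = np.asarray(coded, dtype=float)
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        return centers + halves * arr

    def decode_dict(self, coded) -> dict[str, float]:
        nat = self.decode(coded)
        return {n: float(v) for n, v in zip(self.names, nat)}


def code_levels(natural, fs: FactorSpace) -> np.ndarray:
    """Functional alias for :meth:`FactorSpace.code`."""
    return fs.code(natural)


@dataclass(frozen=True)
class ModelSpec:
    """Polynomial model over coded factors, as a tuple of product terms.

    Each term is a tuple of factor names; ``()`` is the intercept,
    ``("a",)`` a linear term, ``("a", "b")`` an interaction and
    ``("a", "a")`` a pure quadratic.
    """

    factor_names: tuple[str, ...]
    terms: tuple[tuple[str, ...], ...]

    @classmethod
    def full_quadratic(cls, factor_names: Sequence[str]) -> "ModelSpec":
        names = tuple(factor_names)
        terms: list[tuple[str, ...]] = [()]
        terms += [(n,) for n in names]
        terms += [(a, b) for a, b in itertools.combinations(names, 2)]
        terms += [(n, n) for n in names]
        return cls(factor_names=names, terms=tuple(terms))

    @classmethod
    def linear(cls, factor_names: Sequence[str]) -> "ModelSpec":
        names = tuple(factor_names)
        return cls(factor_names=names, terms=tuple([()] + [(n,) for n in names]))

    @property
    def n_params(self) -> int:
        return len(self.terms)

    def labels(self) -> tuple[str, ...]:
        out = []
        for t in self.terms:
            if not t:
                out.append("Intercept")
            elif len(t) == 2 and t[0] == t[1]:
                out.append(f"{t[0]}^2")
            else:
                out.append(":".join(t))
        return tuple(out)

    def matrix(self, coded) -> np.ndarray:
        """Model-expand coded settings (n, k) into the design matrix (n, p)."""
        arr = np.atleast_2d(np.asarray(coded, dtype=float))
        if arr.shape[1] != len(self.factor_names):
            raise DomainError(
                f"expected {len(self.factor_names)} coded columns, got {arr.shape[1]}"
            )
        cols = {n: arr[:, i] for i, n in enumerate(self.factor_names)}
        X = np.ones((arr.shape[0], self.n_params))
        for j, term in enumerate(self.terms):
            for name in term:
                X[:, j] = X[:, j] * cols[name]
        return X

    def drop(self, term: tuple[str, ...]) -> "ModelSpec":
        if term not in self.terms:
            raise LookupError(f"term not in model: {term}")
        return ModelSpec(
            factor_names=self.factor_names,
            terms=tuple(t for t in self.terms if t != term),
        )

    def has_children(self, name: str) -> bool:
        """True if any interaction/quadratic term involving ``name`` is present."""
        return any(len(t) > 1 and name in t for t in self.terms)


@dataclass
class DesignMatrix:
    """Coded run settings plus replicate bookkeeping."""

    coded: np.ndarray  # (n_runs, k)
    replicate_flags: np.ndarray | None = None
    factor_space: FactorSpace | None = None

    def __post_init__(self):
        self.coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        if self.replicate_flags is None:
            self.replicate_flags = np.zeros(self.coded.shape[0], dtype=bool)
        else:
            self.replicate_flags = np.asarray(self.replicate_flags, dtype=bool)
        if self.replicate_flags.shape[0] != self.coded.shape[0]:
            raise DomainError("replicate_flags length must match number of runs")
        if np.any(np.abs(self.coded) > 1.0 + 1e-9):
            raise DomainError("coded levels must lie within [-1, 1]")

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    def natural(self) -> np.ndarray:
        if self.factor_space is None:
            raise DomainError("no factor space attached to decode to natural units")
        return self.factor_space.decode(self.coded)

    def to_frame(self):
        import pandas as pd

        names = (
            self.factor_space.names
            if self.factor_space is not None
            else tuple(f"x{i+1}" for i in range(self.coded.shape[1]))
        )
        df = pd.DataFrame(self.coded, columns=[f"{n}_coded" for n in names])
        if self.factor_space is not None:
            nat = self.natural()
            for i, n in enumerate(names):
                df[n] = nat[:, i]
        df["replicate"] = self.replicate_flags
        return df


def build_candidate_set(fs: FactorSpace, levels_per_factor: int = 5) -> np.ndarray:
    """Full-factorial grid of equally spaced coded levels in [-1, 1]."""
    if levels_per_factor < 3:
        raise DomainError("need at least 3 levels per factor for a quadratic model")
    axis = np.linspace(-1.0, 1.0, levels_per_factor)
    grids = np.meshgrid(*([axis] * fs.k), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def default_n_runs(spec: ModelSpec, lof_points: int = 5, replicates: int = 5) -> int:
    """Conventional D-optimal sizing: p parameters + lack-of-fit points + replicates."""
    return spec.n_params + lof_points + replicates


def _nonsingular_start(F: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    p = F.shape[1]
    for _ in range(100):
        idx = rng.choice(F.shape[0], size=n, replace=True)
        X = F[idx]
        sign, logdet = np.linalg.slogdet(X.T @ X)
        if sign > 0 and np.isfinite(logdet):
            return idx
    # Greedy fallback: build up a nonsingular design deterministically.
    idx = []
    M = np.eye(p) * 1e-10
    for _ in range(n):
        gains = np.einsum("ij,jk,ik->i", F, np.linalg.inv(M), F)
        best = int(np.argmax(gains))
        idx.append(best)
        M = M + np.outer(F[best], F[best])
    return np.asarray(idx)


def _fedorov_exchange(
    F: np.ndarray, idx: np.ndarray, max_iter: int = 500, tol: float = 1e-9
) -> tuple[np.ndarray, float]:
    """Classic Fedorov point exchange; returns indices and final log-det.

    Per iteration the (design point, candidate) swap with the largest
    determinant gain is applied; det(X'X) is non-decreasing by construction
    and asserted so.
    """
    idx = np.array(idx, dtype=int)
    X = F[idx]
    M = X.T @ X
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise RankDeficiencyError("starting design is singular")
    for _ in range(max_iter):
        Minv = np.linalg.inv(M)
        d_all = np.einsum("ij,jk,ik->i", F, Minv, F)
        Xd = F[idx]
        d_des = d_all[idx]
        C = Xd @ Minv @ F.T  # (n, N) cross variances
        delta = (
            d_all[None, :]
            - d_des[:, None]
            - (d_des[:, None] * d_all[None, :] - C**2)
        )
        i, j = np.unravel_index(np.argmax(delta), delta.shape)
        gain = delta[i, j]
        if gain <= tol:
            break
        idx[i] = j
        X = F[idx]
        M = X.T @ X
        sign, new_logdet = np.linalg.slogdet(M)
        if sign <= 0 or new_logdet < logdet - 1e-9:
            raise AssertionError("det(X'X) decreased during Fedorov exchange")
        logdet = new_logdet
    return idx, float(logdet)


def d_optimal(
    candidates: np.ndarray,
    n_runs: int,
    spec: ModelSpec,
    n_replicates: int = 0,
    seed: int | None = 0,
    n_starts: int = 10,
) -> DesignMatrix:
    """D-optimal design by multi-start Fedorov exchange.

    ``n_runs`` counts all rows including the ``n_replicates`` replicate rows,
    which are appended after convergence by duplicating the highest-leverage
    distinct selected points (supplying pure error for the lack-of-fit test).
    Selection from the candidate set is with replacement.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    F = spec.matrix(candidates)
    p = spec.n_params
    base = n_runs - n_replicates
    if n_replicates < 0 or base < p:
        raise RankDeficiencyError(
            f"n_runs={n_runs} with {n_replicates} replicates leaves {base} "
            f"exchange points for a {p}-parameter model"
        )
    rng = np.random.default_rng(seed)
    best_idx, best_logdet = None, -np.inf
    for _ in range(max(1, n_starts)):
        start = _nonsingular_start(F, base, rng)
        idx, logdet = _fedorov_exchange(F, start)
        if logdet > best_logdet:
            best_idx, best_logdet = idx, logdet
    X = F[best_idx]
    Minv = np.linalg.inv(X.T @ X)
    leverage = np.einsum("ij,jk,ik->i", X, Minv, X)
    # Replicate the highest-leverage *distinct* points.
    order = np.argsort(-leverage, kind="stable")
    chosen: list[int] = []
    seen: set[int] = set()
    for i in order:
        cand = int(best_idx[i])
        if cand not in seen:
            chosen.append(i)
            seen.add(cand)
        if len(chosen) == n_replicates:
            break
    while len(chosen) < n_replicates:  # fewer distinct points than replicates
        chosen.append(int(order[len(chosen) % len(order)]))
    rows = np.vstack([candidates[best_idx], candidates[best_idx][chosen]]) if n_replicates else candidates[best_idx]
    flags = np.zeros(rows.shape[0], dtype=bool)
    flags[base:] = True
    return DesignMatrix(coded=rows, replicate_flags=flags)
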