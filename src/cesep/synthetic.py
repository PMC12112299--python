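"""Synthetic ground truth for every upstream input of the pipeline.

The generator emulates the study conditions end to end:

- quadratic response surfaces for the five critical-pair resolutions over
  the four coded buffer factors, with additive Gaussian noise;
- the per-run efficiency index E computed *from* the simulated resolutions
  through the efficiency module (never planted directly), so capping and
  penalty behave exactly as in the analysis path;
- a last-analyte migration-time response increasing in boric acid, DOC and
  methanol content;
- Gaussian-peak electropherograms whose migration times increase with
  boric acid, DOC and methanol, with peak widths growing linearly with
  migration time (plate-count-like broadening);
- replicate peak tables with controlled migration-time/area jitter,
  calibration dilution series, and block-structured species x metabolite
  matrices.

Difficulty presets
------------------
``easy``
    One shared concave resolution surface with an interior maximum drawn in
    [-0.5, 0.5]^4 and per-pair offsets chosen so every resolution stays
    strictly inside (1.0, 1.5) over the whole box.  Capping and penalty are
    then inactive, E is exactly the mean of the resolutions (an analytic
    quadratic), and the planted argmax is known in closed form — the basis
    of all parameter-recovery checks.  Noise SD 0.02 on resolutions.
``realistic``
    Independent random surfaces per resolution with effect-to-noise ratios
    drawn so that refined-model R² typically lands mid-range (about
    0.5-0.95); resolutions may dip below 1, engaging the penalty.
``null``
    All non-intercept coefficients exactly zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorSpace, ModelSpec
from .efficiency import efficiency_index
from .errors import DomainError
from .peaks import HYPOGYMNIA_ANALYTES, Electropherogram, PeakRecord, PeakTable

RS_NAMES = ("Rs1", "Rs2", "Rs3", "Rs4", "Rs5")

#: Base migration times (min) of the seven analytes at the factor-space center.
BASE_MT = {
    "3-hydroxyphysodic acid": 7.50,
    "physodic acid": 8.17,
    "atranorin": 8.94,
    "physodalic acid": 9.34,
    "chloroatranorin": 9.80,
    "salazinic acid": 13.91,
    "protocetraric acid": 14.59,
}

#: Base raw peak areas (mAU·s).
BASE_AREA = {
    "3-hydroxyphysodic acid": 620.0,
    "physodic acid": 540.0,
    "atranorin": 480.0,
    "physodalic acid": 400.0,
    "chloroatranorin": 250.0,
    "salazinic acid": 330.0,
    "protocetraric acid": 300.0,
}

#: Relative migration-time sensitivity to (boric, DOC, MeOH, pH); all three
#: mobile-phase factors prolong migration for every analyte, with a weak
#: MeOH response for physodic acid so the leading pair compresses (towards
#: co-elution) at high boric acid + methanol.
MT_SENSITIVITY = {
    "3-hydroxyphysodic acid": (0.04, 0.03, 0.10, 0.01),
    "physodic acid": (0.04, 0.03, 0.02, 0.01),
    "atranorin": (0.04, 0.03, 0.06, 0.01),
    "physodalic acid": (0.04, 0.03, 0.06, 0.01),
    "chloroatranorin": (0.04, 0.03, 0.06, 0.01),
    "salazinic acid": (0.04, 0.03, 0.05, 0.01),
    "protocetraric acid": (0.04, 0.03, 0.05, 0.01),
}

#: Baseline peak width (min) grows linearly with migration time.
WIDTH_INTERCEPT = 0.05
WIDTH_SLOPE = 0.02

DIFFICULTIES = ("easy", "realistic", "null")


@dataclass
class SyntheticTruth:
    """Planted coefficients (coded scale) and noise levels per response."""

    factor_space: FactorSpace
    spec: ModelSpec
    coef: dict[str, np.ndarray]  # Rs1..Rs5 and MT
    noise_sd: dict[str, float]
    difficulty: str
    seed: int

    @property
    def responses(self) -> tuple[str, ...]:
        return tuple(self.coef)

    def surface(self, name: str, coded) -> np.ndarray:
        """Noise-free response surface value(s)."""
        return self.spec.matrix(coded) @ self.coef[name]

    def e_coefficients(self) -> np.ndarray:
        """Coefficients of the planted E surface = mean of the Rs surfaces.

        Exact whenever every resolution stays within [1, 1.5] over the box
        (capping and penalty inactive), which the ``easy`` preset guarantees.
        """
        return np.mean([self.coef[r] for r in RS_NAMES], axis=0)

    def analytic_argmax(self) -> np.ndarray:
        """Interior stationary maximum of the planted E quadratic (coded)."""
        beta = self.e_coefficients()
        names = self.spec.factor_names
        k = len(names)
        b = np.zeros(k)
        Q = np.zeros((k, k))
        for c, term in zip(beta, self.spec.terms):
            if len(term) == 1:
                b[names.index(term[0])] += c
            elif len(term) == 2:
                i, j = names.index(term[0]), names.index(term[1])
                if i == j:
                    Q[i, i] += c
                else:
                    Q[i, j] += c / 2.0
                    Q[j, i] += c / 2.0
        eigvals = np.linalg.eigvalsh(Q)
        if np.any(eigvals >= 0):
            raise DomainError("planted E surface is not strictly concave")
        x = np.linalg.solve(-2.0 * Q, b)
        if np.any(np.abs(x) > 1.0):
            raise DomainError("planted argmax lies outside the coded box")
        return x

    def as_dict(self) -> dict:
        return {
            "difficulty": self.difficulty,
            "seed": self.seed,
            "terms": [list(t) for t in self.spec.terms],
            "coef": {k: [float(v) for v in vals] for k, vals in self.coef.items()},
            "noise_sd": {k: float(v) for k, v in self.noise_sd.items()},
        }


def _box_vertices(k: int) -> np.ndarray:
    return np.array(list(itertools.product((-1.0, 1.0), repeat=k)))


def _quadratic_form_coefs(spec: ModelSpec, const: float, lin: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Pack c + b'x + x'Qx into the term basis of ``spec``."""
    names = spec.factor_names
    beta = np.zeros(spec.n_params)
    for j, term in enumerate(spec.terms):
        if not term:
            beta[j] = const
        elif len(term) == 1:
            beta[j] = lin[names.index(term[0])]
        else:
            a, b = names.index(term[0]), names.index(term[1])
            beta[j] = Q[a, a] if a == b else 2.0 * Q[a, b]
    return beta


def make_truth(
    seed: int,
    fs: FactorSpace | None = None,
    difficulty: str = "easy",
    zero_factors: tuple[str, ...] = (),
) -> SyntheticTruth:
    """Draw a reproducible ground truth for the DoE simulation.

    ``zero_factors`` forces every coefficient of any term involving the
    named factors to exactly zero (used to study elimination specificity).
    """
    if difficulty not in DIFFICULTIES:
        raise DomainError(f"unknown difficulty preset: {difficulty!r}")
    fs = fs or FactorSpace.default()
    spec = ModelSpec.full_quadratic(fs.names)
    rng = np.random.default_rng(seed)
    k = fs.k
    coef: dict[str, np.ndarray] = {}
    noise: dict[str, float] = {}

    if difficulty == "easy":
        a = rng.uniform(-0.5, 0.5, size=k)
        D = np.diag(rng.uniform(0.05, 0.12, size=k))
        off = rng.uniform(-0.01, 0.01, size=(k, k))
        off = np.triu(off, 1)
        D = D + off + off.T
        # Rescale the concave bowl so its depth over the box is ~0.18,
        # keeping every resolution inside (1, 1.5).
        v = _box_vertices(k) - a
        depth = np.max(np.einsum("ij,jk,ik->i", v, D, v))
        D *= 0.18 / depth
        Q = -D
        lin = 2.0 * D @ a
        const_q = -float(a @ D @ a)
        for name in RS_NAMES:
            base = rng.uniform(1.22, 1.30)
            coef[name] = _quadratic_form_coefs(spec, base + const_q, lin, Q)
            noise[name] = 0.02
    elif difficulty == "realistic":
        grid = np.stack(
            [g.ravel() for g in np.meshgrid(*([np.linspace(-1, 1, 5)] * k), indexing="ij")],
            axis=1,
        )
        X = spec.matrix(grid)
        for name in RS_NAMES:
            beta = np.zeros(spec.n_params)
            for j, term in enumerate(spec.terms):
                if not term:
                    beta[j] = rng.uniform(1.1, 1.6)
                elif len(term) == 1:
                    beta[j] = rng.normal(0.0, 0.18)
                elif term[0] == term[1]:
                    beta[j] = rng.normal(0.0, 0.12)
                else:
                    beta[j] = rng.normal(0.0, 0.10)
            coef[name] = beta
            signal_sd = float(np.std(X @ beta))
            noise[name] = float(rng.uniform(0.6, 1.5) * signal_sd)
    else:  # null
        for name in RS_NAMES:
            beta = np.zeros(spec.n_params)
            beta[0] = 1.2
            coef[name] = beta
            noise[name] = 0.05

    # Last-analyte migration-time response: increasing in boric acid, DOC
    # and MeOH over the whole box (checked below), weak pH effect.
    if difficulty == "null":
        mt = np.zeros(spec.n_params)
        mt[0] = 12.0
        coef["MT"] = mt
        noise["MT"] = 0.05
    else:
        lin_mt = np.array(
            [
                rng.uniform(0.8, 1.2),
                rng.uniform(0.5, 0.9),
                rng.uniform(1.0, 1.6),
                rng.uniform(0.0, 0.2),
            ]
        )
        Q_mt = np.zeros((k, k))
        Q_mt[2, 2] = rng.uniform(0.0, 0.1)  # mild MeOH curvature, still monotone
        coef["MT"] = _quadratic_form_coefs(spec, rng.uniform(11.5, 12.5), lin_mt, Q_mt)
        noise["MT"] = 0.05

    if zero_factors:
        unknown = sorted(set(zero_factors) - set(fs.names))
        if unknown:
            raise LookupError(f"unknown factor(s) to zero: {unknown}")
        for name, beta in coef.items():
            for j, term in enumerate(spec.terms):
                if any(f in term for f in zero_factors):
                    beta[j] = 0.0

    return SyntheticTruth(
        factor_space=fs,
        spec=spec,
        coef=coef,
        noise_sd=noise,
        difficulty=difficulty,
        seed=int(seed),
    )


def simulate_doe_responses(
    truth: SyntheticTruth,
    design: DesignMatrix | np.ndarray,
    seed: int,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Noisy responses for every design run.

    Resolutions get independent Gaussian noise per run (replicate rows get
    independent draws), are clipped at zero, and the per-run E is computed
    from them through the efficiency module.  ``noise_scale`` multiplies all
    noise SDs (0 gives exact polynomial values).
    """
    coded = design.coded if isinstance(design, DesignMatrix) else np.atleast_2d(design)
    rng = np.random.default_rng(seed)
    n = coded.shape[0]
    out: dict[str, np.ndarray] = {}
    for name in RS_NAMES:
        y = truth.surface(name, coded)
        y = y + rng.normal(0.0, truth.noise_sd[name] * noise_scale, size=n)
        out[name] = np.clip(y, 0.0, None)
    out["E"] = np.array(
        [efficiency_index([out[r][i] for r in RS_NAMES]).e for i in range(n)]
    )
    y_mt = truth.surface("MT", coded)
    out["MT"] = y_mt + rng.normal(0.0, truth.noise_sd["MT"] * noise_scale, size=n)
    return pd.DataFrame(out)


def true_peak_table(
    truth: SyntheticTruth, settings, run_id: str = "truth"
) -> PeakTable:
    """Ground-truth peak table at natural-unit settings."""
    coded = truth.factor_space.code(settings)
    peaks = []
    for analyte in HYPOGYMNIA_ANALYTES:
        s = np.asarray(MT_SENSITIVITY[analyte])
        mt = BASE_MT[analyte] * (1.0 + float(s @ coded))
        width = WIDTH_INTERCEPT + WIDTH_SLOPE * mt
        peaks.append(
            PeakRecord(analyte=analyte, mt=mt, area=BASE_AREA[analyte], width=width)
        )
    table = PeakTable(run_id=run_id, peaks=peaks)
    if table.analytes != HYPOGYMNIA_ANALYTES:
        raise DomainError("migration order changed; settings outside generator validity")
    return table


def simulate_electropherogram(
    truth: SyntheticTruth,
    settings,
    seed: int,
    noise_sd: float = 0.3,
    dt: float = 0.005,
    t_max: float | None = None,
    run_id: str = "sim",
) -> tuple[Electropherogram, PeakTable]:
    """Gaussian-peak trace plus its ground-truth peak table.

    Peaks are Gaussians centered at the analyte migration times with
    baseline width 4σ; white detector noise of ``noise_sd`` mAU is added.
    """
    table = true_peak_table(truth, settings, run_id=run_id)
    if t_max is None:
        t_max = table.last_mt() + 2.0
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max, dt)
    y = np.zeros_like(t)
    for p in table:
        sigma = p.width / 4.0
        amp = (p.area / 60.0) / (sigma * np.sqrt(2.0 * np.pi))
        y += amp * np.exp(-0.5 * ((t - p.mt) / sigma) ** 2)
    y += rng.normal(0.0, noise_sd, size=t.size)
    return Electropherogram(time=t, signal=y), table


def simulate_replicate_runs(
    truth: SyntheticTruth,
    settings,
    n_runs: int = 5,
    mt_rsd_pct: float = 1.0,
    area_rsd_pct: float = 3.0,
    seed: int = 0,
) -> list[PeakTable]:
    """Replicate injections with relative jitter on MT and raw area."""
    if n_runs < 2:
        raise DomainError("need at least two replicate runs")
    base = true_peak_table(truth, settings)
    rng = np.random.default_rng(seed)
    runs = []
    for i in range(n_runs):
        peaks = []
        for p in base:
            mt = p.mt * (1.0 + rng.normal(0.0, mt_rsd_pct / 100.0))
            area = max(p.area * (1.0 + rng.normal(0.0, area_rsd_pct / 100.0)), 0.0)
            peaks.append(PeakRecord(analyte=p.analyte, mt=mt, area=area, width=p.width))
        runs.append(PeakTable(run_id=f"rep{i + 1}", peaks=peaks))
    return runs


def simulate_calibration(
    slope: float,
    intercept: float,
    concentrations=(2.0, 5.0, 10.0, 25.0, 50.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Five-point dilution series with Gaussian response noise."""
    rng = np.random.default_rng(seed)
    x = np.asarray(concentrations, dtype=float)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=x.size)
    return x, y


def simulate_species_profiles(
    n_species: int,
    n_compounds: int,
    groups: tuple[int, ...],
    seed: int = 0,
    core_mean_log: float = 1.6,
    core_sd_log: float = 0.5,
    background: float = 0.05,
) -> pd.DataFrame:
    """Block-structured species x metabolite matrix (mg/g DW).

    Each group carries a disjoint core compound set with log-normal
    abundances; all species share a small noisy background so no profile is
    constant.  Same seed, same matrix.
    """
    if sum(groups) != n_species:
        raise DomainError("group sizes must sum to n_species")
    if n_compounds < len(groups):
        raise DomainError("need at least one compound per group")
    rng = np.random.default_rng(seed)
    g_of_compound = np.arange(n_compounds) % len(groups)
    rows = []
    index = []
    species_group = np.repeat(np.arange(len(groups)), groups)
    for i, g in enumerate(species_group):
        core = g_of_compound == g
        values = rng.lognormal(np.log(background), 0.4, size=n_compounds) * 0.5
        values[core] = rng.lognormal(core_mean_log, core_sd_log, size=int(core.sum()))
        rows.append(values)
        index.append(f"sp{g + 1}_{i + 1}")
    return pd.DataFrame(
        np.array(rows), index=index, columns=[f"c{j + 1}" for j in range(n_compounds)]
    )
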