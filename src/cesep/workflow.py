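"""End-to-end orchestration: responses -> models -> diagnostics -> optimum.

Given a DoE design and either a response table or per-run peak tables, the
pipeline

1. (peak tables only) computes the critical-pair resolutions, the per-run
   efficiency index E and the last-analyte migration time;
2. fits a full quadratic model per response (Rs1..Rs5, E, MT);
3. refines each model by hierarchy-preserving backward elimination at
   p > 0.1;
4. assembles the diagnostic table (ANOVA with lack of fit, R² family,
   Adequate Precision, Shapiro-Wilk residual normality) with health flags;
5. maximizes the refined E model subject to the refined MT model staying
   at or below the separation-time limit (default 15 min);
6. emits a deterministic JSON-serializable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorSpace, ModelSpec
from .efficiency import efficiency_index
from .errors import DomainError
from .optimize import optimize_efficiency
from .peaks import HYPOGYMNIA_CRITICAL_PAIRS, PeakTable, resolution_set
from .rsm import (
    anova,
    backward_eliminate,
    fit_quadratic,
    fit_statistics,
    residual_normality,
    term_tests,
)

#: Modified buffer used to pull apart evernic acid and atranorin in samples
#: where both occur (natural units).
EVERNIC_ATRANORIN_BUFFER = {"boric_acid": 40.0, "doc": 100.0, "meoh": 12.5, "ph": 9.6}


@dataclass
class PipelineConfig:
    factor_space: FactorSpace = field(default_factory=FactorSpace.default)
    pair_spec: tuple = HYPOGYMNIA_CRITICAL_PAIRS
    alpha: float = 0.1
    mt_limit: float = 15.0
    cap: float = 1.5
    grid: int = 11
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must lie in (0, 1)")

    def model_spec(self) -> ModelSpec:
        return ModelSpec.full_quadratic(self.factor_space.names)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        fs = FactorSpace.default()
        if "factors" in raw:
            from .design import Factor

            fs = FactorSpace(
                [Factor(f["name"], f["low"], f["high"], f.get("units", "")) for f in raw["factors"]]
            )
        pairs = tuple(
            (p["label"], (p["pair"][0], p["pair"][1])) for p in raw.get("pairs", [])
        ) or HYPOGYMNIA_CRITICAL_PAIRS
        return cls(
            factor_space=fs,
            pair_spec=pairs,
            alpha=raw.get("alpha", 0.1),
            mt_limit=raw.get("mt_limit", 15.0),
            cap=raw.get("cap", 1.5),
            grid=raw.get("grid", 11),
            seed=raw.get("seed", 0),
        )


def responses_from_peak_tables(config: PipelineConfig, tables: Sequence[PeakTable]) -> pd.DataFrame:
    """Per-run Rs values, E and last-analyte MT from integrated peak tables."""
    rows = []
    for pt in tables:
        rs = resolution_set(pt, config.pair_spec)
        row = {label: value for label, value in zip(rs.labels, rs.rs)}
        row["E"] = efficiency_index(rs, cap=config.cap).e
        row["MT"] = pt.last_mt()
        rows.append(row)
    return pd.DataFrame(rows)


def _model_report(name, refined, design, y):
    tests = term_tests(refined, design, y)
    stats = fit_statistics(refined, design, y)
    table = anova(refined, design, y)
    norm = residual_normality(refined, design, y)
    report = {
        "terms": [
            {"term": t, "coef": float(c), "p": float(p)}
            for t, c, p in zip(tests["term"], tests["coef"], tests["p"])
        ],
        "anova": {
            "model_f": table.model.f,
            "model_p": table.model.p,
            "lof_f": table.lack_of_fit.f if table.lof_available else None,
            "lof_p": table.lack_of_fit.p if table.lof_available else None,
        },
        "fit": {
            "r2": stats.r2,
            "adj_r2": stats.adj_r2,
            "pred_r2": stats.pred_r2,
            "press": stats.press,
            "adeq_precision": stats.adeq_precision,
        },
        "shapiro": {"W": norm.statistic, "p": norm.pvalue, "computable": norm.computable},
        "flags": stats.health_flags(),
    }
    return report


def run_pipeline(
    config: PipelineConfig,
    design: DesignMatrix,
    responses: pd.DataFrame | None = None,
    peak_tables: Sequence[PeakTable] | None = None,
) -> dict:
    """Run the full analysis; returns a JSON-serializable report."""
    if (responses is None) == (peak_tables is None):
        raise DomainError("provide exactly one of responses or peak_tables")
    if peak_tables is not None:
        responses = responses_from_peak_tables(config, peak_tables)
    labels = [label for label, _ in config.pair_spec]
    needed = labels + ["E", "MT"]
    missing = [c for c in needed if c not in responses.columns]
    if missing:
        raise DomainError(f"response table missing columns: {missing}")
    if len(responses) != design.n_runs:
        raise DomainError(
            f"design has {design.n_runs} runs but responses has {len(responses)} rows"
        )
    e_values = responses["E"].to_numpy(float)
    if np.any(e_values < 0) or np.any(e_values > config.cap + 1e-9):
        raise DomainError("per-run E outside [0, cap]; inputs inconsistent")

    spec = config.model_spec()
    report: dict = {
        "config": {
            "factors": [
                {"name": f.name, "low": f.low, "high": f.high, "units": f.units}
                for f in config.factor_space.factors
            ],
            "pairs": [{"label": l, "pair": list(p)} for l, p in config.pair_spec],
            "alpha": config.alpha,
            "mt_limit": config.mt_limit,
            "cap": config.cap,
            "seed": config.seed,
        },
        "n_runs": int(design.n_runs),
        "models": {},
    }
    refined_models = {}
    for name in needed:
        y = responses[name].to_numpy(float)
        full = fit_quadratic(design, y, spec, response_name=name)
        refined = backward_eliminate(full, design, y, alpha=config.alpha)
        refined_models[name] = refined
        report["models"][name] = _model_report(name, refined, design, y)

    opt = optimize_efficiency(
        refined_models["E"],
        refined_models["MT"],
        config.factor_space,
        mt_limit=config.mt_limit,
        seed=config.seed,
        grid=config.grid,
    )
    report["optimum"] = opt.as_dict()
    return report


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a pipeline report."""
    return json.dumps(report, sort_keys=True, indent=2)


def reanalyze_deposit(path, config: PipelineConfig | None = None) -> dict:
    """Re-analyze a deposited DoE run table.

    Expects a CSV with natural-unit factor columns (boric_acid, doc, meoh,
    ph) and response columns Rs1..Rs5, E, MT — the layout to which the
    published raw-data deposit's run table should be exported (see README).
    """
    config = config or PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"deposit run table not found at {path}; download the archived raw "
            "data and export its DoE table to this CSV layout first"
        )
    df = pd.read_csv(path)
    fs = config.factor_space
    missing = [n for n in fs.names if n not in df.columns]
    if missing:
        raise DomainError(f"deposit table missing factor columns: {missing}")
    coded = fs.code(df[list(fs.names)].to_numpy(float))
    design = DesignMatrix(coded=coded, factor_space=fs)
    responses = df.drop(columns=list(fs.names))
    return run_pipeline(config, design, responses=responses)
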