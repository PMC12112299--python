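"""Method-validation statistics: calibration, LOD/LOQ, repeatability.

Calibration lines regress corrected peak area (CPA) on concentration
(µg/mL) by ordinary least squares.  Detection and quantification limits
follow the signal-to-noise convention: LOD at S/N = 3 and LOQ at S/N = 10,
with the noise SD taken over a stated blank region of the trace and
converted to concentration through the calibration slope.  Repeatability is
summarized per analyte as RSD% of migration time and of CPA across
replicate runs; analytes at or above 10 % RSD are flagged as failing the
commonly accepted precision threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import DegenerateDesignError, DomainError
from .peaks import PeakTable, rsd

#: Signal-to-noise multipliers for the detection and quantification limits.
LOD_SNR = 3.0
LOQ_SNR = 10.0

#: RSD% threshold above which precision is considered inadequate.
RSD_THRESHOLD_PCT = 10.0


@dataclass
class CalibrationResult:
    slope: float  # CPA per (µg/mL)
    intercept: float  # CPA
    r2: float
    lod: float | None = None  # µg/mL
    loq: float | None = None  # µg/mL


def calibrate(concentrations: Sequence[float], responses: Sequence[float]) -> CalibrationResult:
    """Least-squares calibration line of CPA response vs concentration."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DomainError("calibration needs >= 3 matched points")
    if np.unique(x).size < 2:
        raise DegenerateDesignError("calibration needs at least two distinct concentrations")
    fit = _stats.linregress(x, y)
    return CalibrationResult(
        slope=float(fit.slope), intercept=float(fit.intercept), r2=float(fit.rvalue**2)
    )


def lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits from blank noise and slope.

    LOD = 3·noise/slope (S/N = 3); LOQ = 10·noise/slope (S/N = 10); µg/mL.
    """
    if slope <= 0:
        raise DomainError("calibration slope must be positive for LOD/LOQ")
    if noise_sd < 0:
        raise DomainError("noise SD must be nonnegative")
    return LOD_SNR * noise_sd / slope, LOQ_SNR * noise_sd / slope


def with_limits(cal: CalibrationResult, noise_sd: float) -> CalibrationResult:
    lod, loq = lod_loq(noise_sd, cal.slope)
    return CalibrationResult(cal.slope, cal.intercept, cal.r2, lod=lod, loq=loq)


def repeatability(runs: Iterable[PeakTable], analytes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-analyte migration-time and CPA repeatability across replicate runs.

    Analytes missing from some run are excluded with a warning.  Returns a
    frame with MT mean/SD/RSD%, CPA RSD% and a precision pass flag
    (RSD% below 10 for both quantities).
    """
    runs = list(runs)
    if len(runs) < 2:
        raise DomainError("repeatability needs at least two runs")
    if analytes is None:
        analytes = runs[0].analytes
    rows = []
    for analyte in analytes:
        present = [r for r in runs if analyte in r.analytes]
        if len(present) < len(runs):
            warnings.warn(
                f"analyte {analyte!r} missing from {len(runs) - len(present)} run(s); excluded",
                stacklevel=2,
            )
            continue
        mts = np.array([r[analyte].mt for r in present])
        cpas = np.array([r[analyte].cpa for r in present])
        mt_rsd = rsd(mts)
        cpa_rsd = rsd(cpas)
        rows.append(
            {
                "analyte": analyte,
                "n": len(present),
                "mt_mean": mts.mean(),
                "mt_sd": mts.std(ddof=1),
                "mt_rsd_pct": mt_rsd,
                "cpa_rsd_pct": cpa_rsd,
                "precision_ok": abs(mt_rsd) < RSD_THRESHOLD_PCT
                and abs(cpa_rsd) < RSD_THRESHOLD_PCT,
            }
        )
    return pd.DataFrame(rows)
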