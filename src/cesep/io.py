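"""Delimited-text readers and writers for the pipeline's tables.

Formats (all plain CSV):

- peak tables: ``run_id,analyte,mt_min,area,width_min``
- spectra: ``wavelength_nm,absorbance``
- DoE designs: one natural-unit column per factor plus a ``replicate`` flag
- response tables: ``Rs1..Rs5,E,MT`` aligned row-by-row with the design
- species x compound matrices: species ids in the first column
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorSpace
from .errors import DomainError
from .peaks import PeakRecord, PeakTable, SpectrumRecord

PEAK_COLUMNS = ["run_id", "analyte", "mt_min", "area", "width_min"]


def read_peak_tables(path) -> list[PeakTable]:
    df = pd.read_csv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"peak table {path} missing columns: {missing}")
    tables = []
    for run_id, grp in df.groupby("run_id", sort=False):
        peaks = [
            PeakRecord(
                analyte=str(r.analyte), mt=float(r.mt_min), area=float(r.area), width=float(r.width_min)
            )
            for r in grp.itertuples()
        ]
        tables.append(PeakTable(run_id=str(run_id), peaks=peaks))
    return tables


def write_peak_tables(tables, path) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(path, index=False)


def read_spectrum(path) -> SpectrumRecord:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DomainError(f"spectrum {path} needs two columns (wavelength_nm, absorbance)")
    return SpectrumRecord(
        wavelengths=df.iloc[:, 0].to_numpy(float), absorbances=df.iloc[:, 1].to_numpy(float)
    )


def write_design(design: DesignMatrix, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path, fs: FactorSpace) -> DesignMatrix:
    """Read a design from natural-unit factor columns (coded columns optional)."""
    df = pd.read_csv(path)
    missing = [n for n in fs.names if n not in df.columns]
    if missing:
        raise DomainError(f"design {path} missing factor columns: {missing}")
    coded = fs.code(df[list(fs.names)].to_numpy(float))
    flags = df["replicate"].to_numpy(bool) if "replicate" in df.columns else None
    return DesignMatrix(coded=coded, replicate_flags=flags, factor_space=fs)


def read_responses(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
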