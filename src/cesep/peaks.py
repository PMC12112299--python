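"""Electropherogram traces, peak tables and per-peak statistics.

The data model mirrors what a CE-UV-VIS instrument exports after
integration: per run, a list of detected analyte peaks with migration time
(min), raw peak area (mAU·s) and baseline peak width (min).  On top of that
this module provides

- peak picking on a raw trace (`detect_peaks`),
- pairwise resolution Rs = 2·Δt/(w_a + w_b) for critical pairs,
- the corrected peak area CPA = area / (60 · MT), which normalises peak
  areas for the different velocities with which analytes pass the detector,
- repeatability statistics (RSD%) and
- UV-VIS spectral similarity scoring for identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .efficiency import ResolutionSet
from .errors import (
    DomainError,
    InvalidPeakError,
    MissingAnalyteError,
    SpectralCoverageError,
)

SECONDS_PER_MINUTE = 60.0

#: Detection wavelength used throughout the method (nm).
DETECTION_WAVELENGTH_NM = 218.0

#: Spectral-similarity threshold for a positive identification.
SIMILARITY_THRESHOLD = 0.95

#: Default wavelength window (nm) for spectral comparison.
SIMILARITY_WINDOW = (192.0, 600.0)

#: Migration order of the seven H. physodes analytes under the optimized buffer.
HYPOGYMNIA_ANALYTES = (
    "3-hydroxyphysodic acid",
    "physodic acid",
    "atranorin",
    "physodalic acid",
    "chloroatranorin",
    "salazinic acid",
    "protocetraric acid",
)

#: Critical pairs monitored during optimization, labelled Rs1..Rs5.  Each Rs
#: tracks the separation of one co-elution-prone pair; the chloroatranorin /
#: salazinic acid gap is wide and is not monitored.
HYPOGYMNIA_CRITICAL_PAIRS = (
    ("Rs1", ("3-hydroxyphysodic acid", "physodic acid")),
    ("Rs2", ("physodic acid", "atranorin")),
    ("Rs3", ("atranorin", "physodalic acid")),
    ("Rs4", ("physodalic acid", "chloroatranorin")),
    ("Rs5", ("salazinic acid", "protocetraric acid")),
)


@dataclass(frozen=True)
class PeakRecord:
    """One integrated peak: analyte id, migration time, area, baseline width."""

    analyte: str
    mt: float
    area: float
    width: float

    def __post_init__(self):
        if not np.isfinite(self.mt) or self.mt <= 0:
            raise InvalidPeakError(f"migration time must be positive, got {self.mt}")
        if not np.isfinite(self.area) or self.area < 0:
            raise InvalidPeakError(f"peak area must be nonnegative, got {self.area}")
        if not np.isfinite(self.width) or self.width <= 0:
            raise InvalidPeakError(f"peak width must be positive, got {self.width}")

    @property
    def cpa(self) -> float:
        return corrected_peak_area(self.area, self.mt)


@dataclass
class PeakTable:
    """Peaks of a single run, kept sorted by migration time."""

    run_id: str
    peaks: list[PeakRecord] = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.mt)
        names = [p.analyte for p in self.peaks]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvalidPeakError(f"duplicate analyte ids in run {self.run_id!r}: {dupes}")

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(p.analyte for p in self.peaks)

    def __getitem__(self, analyte: str) -> PeakRecord:
        for p in self.peaks:
            if p.analyte == analyte:
                return p
        raise MissingAnalyteError([analyte])

    def last_mt(self) -> float:
        """Migration time of the last-migrating peak (min)."""
        if not self.peaks:
            raise MissingAnalyteError(["<any>"])
        return self.peaks[-1].mt

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "run_id": self.run_id,
                "analyte": [p.analyte for p in self.peaks],
                "mt_min": [p.mt for p in self.peaks],
                "area": [p.area for p in self.peaks],
                "width_min": [p.width for p in self.peaks],
            }
        )


@dataclass
class Electropherogram:
    """Uniformly sampled detector trace at a single wavelength."""

    time: np.ndarray  # minutes
    signal: np.ndarray  # mAU
    wavelength_nm: float = DETECTION_WAVELENGTH_NM

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 2 or self.time.shape != self.signal.shape:
            raise DomainError("trace needs >= 2 samples with matching time/signal shapes")
        if not np.all(np.diff(self.time) > 0):
            raise DomainError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise DomainError("signal must be finite")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass
class SpectrumRecord:
    """UV-VIS absorbance spectrum of one analyte."""

    wavelengths: np.ndarray  # nm, ascending
    absorbances: np.ndarray  # AU

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavelengths.shape != self.absorbances.shape or self.wavelengths.ndim != 1:
            raise DomainError("wavelengths and absorbances must be equal-length 1-D arrays")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise DomainError("wavelengths must be strictly ascending")


def resolution(a: PeakRecord, b: PeakRecord, half_height: bool = False) -> float:
    """Resolution of a peak pair.

    Baseline-width definition (default)::

        Rs = 2 (MT_b - MT_a) / (w_a + w_b)

    With ``half_height=True`` the widths are interpreted as half-height
    widths and the pharmacopoeial factor 1.18 is used instead of 2.
    Argument order does not matter; the pair is sorted by migration time.
    """
    if a.width <= 0 or b.width <= 0:
        raise InvalidPeakError("peak widths must be positive for resolution")
    if a.mt > b.mt:
        a, b = b, a
    factor = 1.18 if half_height else 2.0
    return factor * (b.mt - a.mt) / (a.width + b.width)


def resolution_set(
    pt: PeakTable,
    pair_spec: Sequence[tuple[str, tuple[str, str]]] = HYPOGYMNIA_CRITICAL_PAIRS,
    half_height: bool = False,
) -> ResolutionSet:
    """Resolutions of the named critical pairs, in ``pair_spec`` order."""
    missing = sorted(
        {name for _, pair in pair_spec for name in pair if name not in pt.analytes}
    )
    if missing:
        raise MissingAnalyteError(missing)
    labels = tuple(label for label, _ in pair_spec)
    values = tuple(
        resolution(pt[pair[0]], pt[pair[1]], half_height=half_height)
        for _, pair in pair_spec
    )
    return ResolutionSet(rs=values, labels=labels)


def corrected_peak_area(area: float, mt: float) -> float:
    """Corrected peak area CPA = area / (60 · MT) with MT in minutes.

    Equivalently area divided by migration time in seconds; this removes the
    residence-time bias of on-capillary UV detection.
    """
    if mt <= 0:
        raise DomainError(f"migration time must be positive, got {mt}")
    if area < 0:
        raise DomainError(f"peak area must be nonnegative, got {area}")
    return area / (SECONDS_PER_MINUTE * mt)


def rsd(values: Iterable[float]) -> float:
    """Relative standard deviation in percent: 100 · sample SD / mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise DomainError("RSD needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise DomainError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def spectral_similarity(
    a: SpectrumRecord,
    b: SpectrumRecord,
    window: tuple[float, float] = SIMILARITY_WINDOW,
    step_nm: float = 1.0,
) -> float:
    """Pearson correlation of two spectra on a common 1-nm grid inside ``window``."""
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise DomainError("similarity window must have positive width")
    for name, s in (("first", a), ("second", b)):
        if s.wavelengths[0] > lo or s.wavelengths[-1] < hi:
            raise SpectralCoverageError(
                f"{name} spectrum covers {s.wavelengths[0]:g}-{s.wavelengths[-1]:g} nm, "
                f"window requires {lo:g}-{hi:g} nm"
            )
    grid = np.arange(lo, hi + 0.5 * step_nm, step_nm)
    ya = np.interp(grid, a.wavelengths, a.absorbances)
    yb = np.interp(grid, b.wavelengths, b.absorbances)
    if np.std(ya) == 0 or np.std(yb) == 0:
        raise DomainError("spectral similarity undefined for a constant spectrum")
    r, _ = _stats.pearsonr(ya, yb)
    return float(r)


def spectra_match(
    a: SpectrumRecord,
    b: SpectrumRecord,
    window: tuple[float, float] = SIMILARITY_WINDOW,
    threshold: float = SIMILARITY_THRESHOLD,
) -> bool:
    """Identification decision: similarity at or above the threshold (default 95 %)."""
    return spectral_similarity(a, b, window=window) >= threshold


def detect_peaks(
    eg: Electropherogram,
    min_snr: float = 10.0,
    baseline_window: int = 201,
    run_id: str = "detected",
) -> PeakTable:
    """Pick peaks from a raw trace.

    The baseline is estimated with a running median (``baseline_window``
    points, wider than any expected peak), noise as the scaled median
    absolute deviation of the baseline-subtracted trace.  Local maxima
    exceeding ``min_snr`` times the noise SD are kept; each peak's extent is
    taken between the surrounding zero-crossings of the baseline-subtracted
    signal, giving a (noise-floor) baseline width and a trapezoidal area in
    mAU·s.

    A flat or featureless trace yields an empty table rather than an error.
    """
    if min_snr <= 0:
        raise DomainError("min_snr must be positive")
    y = eg.signal
    if np.ptp(y) == 0:
        return PeakTable(run_id=run_id, peaks=[])
    win = int(baseline_window) | 1  # odd kernel
    baseline = _signal.medfilt(y, kernel_size=min(win, (y.size - 1) | 1))
    resid = y - baseline
    mad = np.median(np.abs(resid - np.median(resid)))
    noise_sd = 1.4826 * mad
    if noise_sd == 0:
        # noise-free trace: any threshold far below the peaks will do
        noise_sd = 1e-6 * np.max(np.abs(resid))
    if noise_sd == 0:
        return PeakTable(run_id=run_id, peaks=[])
    height = min_snr * noise_sd
    idx, _ = _signal.find_peaks(resid, height=height, prominence=0.5 * height)
    peaks: list[PeakRecord] = []
    below = resid <= 0
    for k, i in enumerate(idx):
        left = i
        while left > 0 and not below[left]:
            left -= 1
        right = i
        while right < resid.size - 1 and not below[right]:
            right += 1
        if right - left < 2:
            continue
        width = eg.time[right] - eg.time[left]
        area_min = np.trapezoid(resid[left : right + 1], eg.time[left : right + 1])
        peaks.append(
            PeakRecord(
                analyte=f"peak{k + 1}",
                mt=float(eg.time[i]),
                area=float(max(area_min, 0.0) * SECONDS_PER_MINUTE),
                width=float(width),
            )
        )
    return PeakTable(run_id=run_id, peaks=peaks)
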