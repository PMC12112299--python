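"""Quadratic response-surface fitting and model diagnostics.

Responses (Rs1..Rs5, the efficiency index E, migration time) are fitted by
ordinary least squares on the model-expanded coded design matrix.  The
diagnostic battery mirrors standard DoE software output:

- ANOVA with the model / residual partition, plus a lack-of-fit vs.
  pure-error split whenever the design carries replicate runs;
- R², adjusted R², PRESS / predicted R² (leave-one-out via the leverage
  identity e_i / (1 - h_ii)), and Adequate Precision
  (max(yhat) - min(yhat)) / sqrt(p·MSE/n);
- hierarchy-preserving backward elimination of terms at p > alpha
  (default 0.1), largest p first, refitting after each removal;
- Shapiro-Wilk normality check of the residuals.

Model-health conventions: a fitted surface is considered sound when
adjusted and predicted R² differ by less than 0.2 and Adequate Precision
exceeds 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as _linalg
from scipy import stats as _stats

from .design import DesignMatrix, ModelSpec
from .errors import DomainError, RankDeficiencyError

#: Default significance threshold for term elimination.
ELIMINATION_ALPHA = 0.1

#: Largest acceptable gap between adjusted and predicted R².
R2_GAP_THRESHOLD = 0.2

#: Minimum Adequate Precision for a usable model.
ADEQ_PRECISION_MIN = 4.0


def _coded(design) -> np.ndarray:
    if isinstance(design, DesignMatrix):
        return design.coded
    return np.atleast_2d(np.asarray(design, dtype=float))


@dataclass
class QuadraticModel:
    """Fitted polynomial on the coded scale."""

    spec: ModelSpec
    coef: np.ndarray
    response_name: str = ""
    saturated: bool = False

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.size != self.spec.n_params:
            raise DomainError("coefficient count must equal active-term count")

    def predict_coded(self, coded) -> np.ndarray:
        return self.spec.matrix(coded) @ self.coef

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.spec.labels(), "coef": self.coef})


@dataclass
class AnovaRow:
    ss: float
    df: int
    ms: float | None = None
    f: float | None = None
    p: float | None = None


@dataclass
class AnovaTable:
    model: AnovaRow
    residual: AnovaRow
    total: AnovaRow
    lack_of_fit: AnovaRow | None = None
    pure_error: AnovaRow | None = None

    @property
    def lof_available(self) -> bool:
        return self.lack_of_fit is not None

    def to_frame(self) -> pd.DataFrame:
        rows = {"model": self.model, "residual": self.residual}
        if self.lack_of_fit is not None:
            rows["lack_of_fit"] = self.lack_of_fit
        if self.pure_error is not None:
            rows["pure_error"] = self.pure_error
        rows["total"] = self.total
        return pd.DataFrame(
            {
                name: {"SS": r.ss, "df": r.df, "MS": r.ms, "F": r.f, "p": r.p}
                for name, r in rows.items()
            }
        ).T


@dataclass
class FitStats:
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    adeq_precision: float

    def health_flags(self) -> dict[str, bool]:
        """Model-health screens: R² consistency gap and signal-to-noise."""
        return {
            "r2_gap_ok": (self.adj_r2 - self.pred_r2) <= R2_GAP_THRESHOLD,
            "adeq_precision_ok": self.adeq_precision > ADEQ_PRECISION_MIN,
        }


@dataclass
class NormalityResult:
    statistic: float | None
    pvalue: float | None
    computable: bool

    def passes(self, alpha: float = 0.05) -> bool | None:
        if not self.computable:
            return None
        return self.pvalue > alpha


def fit_quadratic(design, y, spec: ModelSpec, response_name: str = "") -> QuadraticModel:
    """Ordinary least squares on the model-expanded coded matrix."""
    coded = _coded(design)
    y = np.asarray(y, dtype=float).ravel()
    if coded.shape[0] != y.size:
        raise DomainError("design rows and response length differ")
    X = spec.matrix(coded)
    n, p = X.shape
    if n < p:
        raise RankDeficiencyError(f"{n} runs cannot estimate {p} parameters")
    q, r, piv = _linalg.qr(X, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(r)) > np.abs(r[0, 0]) * max(n, p) * np.finfo(float).eps))
    if rank < p:
        aliased = [spec.labels()[j] for j in piv[rank:]]
        raise RankDeficiencyError(
            f"model matrix is rank deficient; aliased terms: {aliased}", aliased=aliased
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return QuadraticModel(spec=spec, coef=coef, response_name=response_name, saturated=(n == p))


def _fit_pieces(model: QuadraticModel, design, y):
    coded = _coded(design)
    y = np.asarray(y, dtype=float).ravel()
    X = model.spec.matrix(coded)
    yhat = X @ model.coef
    resid = y - yhat
    return coded, y, X, yhat, resid


def term_tests(model: QuadraticModel, design, y) -> pd.DataFrame:
    """Partial t-tests per coefficient on the coded scale (Type III)."""
    coded, y, X, yhat, resid = _fit_pieces(model, design, y)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise DomainError("term tests need at least one residual degree of freedom")
    mse = float(resid @ resid) / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * mse, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, model.coef / se, np.inf * np.sign(model.coef))
    pvals = 2.0 * _stats.t.sf(np.abs(t), df_resid)
    return pd.DataFrame(
        {
            "term": model.spec.labels(),
            "coef": model.coef,
            "se": se,
            "t": t,
            "p": pvals,
        }
    )


def anova(model: QuadraticModel, design, y) -> AnovaTable:
    """ANOVA partition with a lack-of-fit row when replicates exist."""
    coded, y, X, yhat, resid = _fit_pieces(model, design, y)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise DomainError("ANOVA needs at least one residual degree of freedom")
    ybar = y.mean()
    ss_total = float(np.sum((y - ybar) ** 2))
    ss_model = float(np.sum((yhat - ybar) ** 2))
    ss_resid = float(np.sum(resid**2))
    df_model = p - 1
    ms_resid = ss_resid / df_resid
    if df_model >= 1 and ms_resid > 0:
        f_model = (ss_model / df_model) / ms_resid
        p_model = float(_stats.f.sf(f_model, df_model, df_resid))
    else:
        f_model, p_model = (np.inf if df_model >= 1 else None), (0.0 if df_model >= 1 else None)
    table = AnovaTable(
        model=AnovaRow(ss_model, df_model, ss_model / df_model if df_model else None, f_model, p_model),
        residual=AnovaRow(ss_resid, df_resid, ms_resid),
        total=AnovaRow(ss_total, n - 1),
    )
    # Pure error from groups of identical coded rows.
    rounded = np.round(coded, 12)
    _, inverse, counts = np.unique(rounded, axis=0, return_inverse=True, return_counts=True)
    df_pe = int(np.sum(counts - 1))
    if df_pe >= 1:
        group_means = np.bincount(inverse, weights=y) / np.bincount(inverse)
        ss_pe = float(np.sum((y - group_means[inverse]) ** 2))
        ss_lof = max(ss_resid - ss_pe, 0.0)
        df_lof = df_resid - df_pe
        if df_lof >= 1:
            ms_pe = ss_pe / df_pe
            ms_lof = ss_lof / df_lof
            if ms_pe > 0:
                f_lof = ms_lof / ms_pe
                p_lof = float(_stats.f.sf(f_lof, df_lof, df_pe))
            else:
                f_lof = np.inf if ss_lof > 0 else 0.0
                p_lof = 0.0 if ss_lof > 0 else 1.0
            table.lack_of_fit = AnovaRow(ss_lof, df_lof, ms_lof, f_lof, p_lof)
            table.pure_error = AnovaRow(ss_pe, df_pe, ss_pe / df_pe)
    return table


def fit_statistics(model: QuadraticModel, design, y) -> FitStats:
    """R² family, PRESS and Adequate Precision at the fitted design points."""
    coded, y, X, yhat, resid = _fit_pieces(model, design, y)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise DomainError("fit statistics need at least one residual degree of freedom")
    ybar = y.mean()
    ss_total = float(np.sum((y - ybar) ** 2))
    ss_resid = float(np.sum(resid**2))
    if ss_total <= 0:
        raise DomainError("constant response: R² undefined")
    r2 = 1.0 - ss_resid / ss_total
    adj_r2 = 1.0 - (ss_resid / df_resid) / (ss_total / (n - 1))
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    h = np.clip(np.diag(H), 0.0, 1.0)
    usable = h < 1.0 - 1e-10
    if not np.all(usable):
        warnings.warn(
            f"{int(np.sum(~usable))} run(s) with leverage 1 excluded from PRESS",
            stacklevel=2,
        )
    press = float(np.sum((resid[usable] / (1.0 - h[usable])) ** 2))
    pred_r2 = 1.0 - press / ss_total
    mse = ss_resid / df_resid
    adeq = float((yhat.max() - yhat.min()) / np.sqrt(p * mse / n)) if mse > 0 else np.inf
    return FitStats(r2=float(r2), adj_r2=float(adj_r2), pred_r2=float(pred_r2), press=press, adeq_precision=adeq)


def backward_eliminate(
    model: QuadraticModel,
    design,
    y,
    alpha: float = ELIMINATION_ALPHA,
    hierarchy: bool = True,
) -> QuadraticModel:
    """Iteratively drop the least significant term with p > alpha.

    One term is removed per round (the largest p among removable terms) and
    the model is refit.  With ``hierarchy`` on, a linear term is kept as long
    as any of its interaction or quadratic children remain in the model.  The
    intercept is never removed.  The procedure is deterministic.
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    coded = _coded(design)
    y = np.asarray(y, dtype=float).ravel()
    current = model
    while True:
        tests = term_tests(current, coded, y)
        spec = current.spec
        removable = []
        for term, pval in zip(spec.terms, tests["p"]):
            if not term:
                continue  # intercept stays
            if hierarchy and len(term) == 1 and spec.has_children(term[0]):
                continue
            if np.isfinite(pval) and pval > alpha:
                removable.append((pval, term))
        if not removable:
            return current
        _, worst = max(removable, key=lambda item: (item[0], item[1]))
        current = fit_quadratic(coded, y, spec.drop(worst), response_name=current.response_name)


def residual_normality(model: QuadraticModel, design, y) -> NormalityResult:
    """Shapiro-Wilk test of the fit residuals (pass recorded at alpha = 0.05)."""
    _, _, _, _, resid = _fit_pieces(model, design, y)
    n_param = model.spec.n_params
    if resid.size - n_param < 3 or resid.size < 3:
        return NormalityResult(None, None, computable=False)
    if np.ptp(resid) < 1e-12 * max(1.0, np.max(np.abs(resid))):
        return NormalityResult(None, None, computable=False)
    if resid.size > 5000:
        raise DomainError("Shapiro-Wilk limited to 5000 residuals")
    w, p = _stats.shapiro(resid)
    return NormalityResult(float(w), float(p), computable=True)
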