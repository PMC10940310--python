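"""Cohort summaries and the metric-versus-risk-index comparison.

The risk index (RI) is taken as the closest available surrogate of patient
radiation risk, and each effective-dose style metric ``y`` (E_DLP, E_OD, E_r)
is regressed on it through the origin:

    slope = sum(x*y) / sum(x**2)

Two diagnostics rank the metrics:

* Risk Sensitivity Index, ``RSI = slope / (mean(y) / mean(x))`` — how the
  fitted proportionality compares with the crude mean ratio; 1 is ideal.
* Risk Differentiability Index, ``RDI = RMSE / slope`` — residual scatter on
  the risk-index scale; 0 is ideal.

RMSE is ``sqrt(sum(residual**2) / n)`` and the normalized RMSE is
``RMSE / mean(y)``.  Because the through-origin R² convention is ambiguous,
both the uncentered (``1 - SSE/sum(y**2)``) and centered
(``1 - SSE/sum((y-mean(y))**2)``) versions are reported; neither enters RSI
or RDI.  The slope's significance is a two-sided t test with n-1 degrees of
freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .dose_metrics import METRIC_COLUMNS, PatientRecord

__all__ = [
    "MetricSummary",
    "OriginFit",
    "CohortReport",
    "ThroughOriginRegression",
    "RiskMetricComparator",
    "summarize",
    "fit_origin",
    "risk_sensitivity_index",
    "risk_differentiability_index",
    "compare_metrics",
]

#: Metrics regressed against the risk index.
COMPARED_METRICS = ("e_dlp", "e_od", "e_r")
DISPLAY_NAMES = {
    "e_dlp": "E_DLP",
    "e_od": "E_OD",
    "ri": "RI",
    "ri_rp": "RI_rp",
    "f": "f",
    "e_r": "E_r",
}


@dataclass(frozen=True)
class MetricSummary:
    """Mean, median, range, and sample standard deviation of one metric."""

    mean: float
    median: float
    min: float
    max: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("requires min <= median <= max")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class OriginFit:
    """Zero-intercept least-squares fit of a metric on the risk index."""

    slope: float
    rmse: float
    nrmse: float
    r2_uncentered: float
    r2_centered: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CohortReport:
    """Per-metric summaries plus the RSI/RDI comparison against RI."""

    n_patients: int
    summaries: Mapping[str, MetricSummary]
    fits: Mapping[str, OriginFit]
    rsi: Mapping[str, float]
    rdi: Mapping[str, float]
    best_rsi_metric: str = field(default="")
    best_rdi_metric: str = field(default="")

    def summary_frame(self) -> pd.DataFrame:
        """Mean/median/range/SD table, one row per metric (full precision)."""
        rows = []
        for key, s in self.summaries.items():
            rows.append(
                {
                    "metric": DISPLAY_NAMES.get(key, key),
                    "mean": s.mean,
                    "median": s.median,
                    "min": s.min,
                    "max": s.max,
                    "sd": s.sd,
                }
            )
        return pd.DataFrame(rows)

    def fit_frame(self) -> pd.DataFrame:
        """Slope/R²/nRMSE/RSI/RDI table, one row per compared metric."""
        rows = []
        for key, fit in self.fits.items():
            rows.append(
                {
                    "metric": DISPLAY_NAMES.get(key, key),
                    "slope": fit.slope,
                    "r2_uncentered": fit.r2_uncentered,
                    "r2_centered": fit.r2_centered,
                    "nrmse": fit.nrmse,
                    "rmse": fit.rmse,
                    "p_value": fit.p_value,
                    "rsi": self.rsi[key],
                    "rdi": self.rdi[key],
                }
            )
        return pd.DataFrame(rows)

    def to_text(self, decimals_summary: int = 1, decimals_fit: int = 2) -> str:
        """Human-readable report, rounded for display only."""
        lines = [f"Cohort of {self.n_patients} patients", "", "Metric summaries:"]
        s = self.summary_frame().round(decimals_summary)
        lines.append(s.to_string(index=False))
        lines += ["", "Dependency on the risk index (zero-intercept fits):"]
        f = self.fit_frame().copy()
        for col in ("slope", "r2_uncentered", "r2_centered", "nrmse", "rsi", "rdi"):
            f[col] = f[col].round(decimals_fit)
        lines.append(f.drop(columns=["rmse", "p_value"]).to_string(index=False))
        lines += [
            "",
            f"Best risk sensitivity (RSI nearest 1): {DISPLAY_NAMES.get(self.best_rsi_metric, self.best_rsi_metric)}",
            f"Best risk differentiability (smallest RDI): {DISPLAY_NAMES.get(self.best_rdi_metric, self.best_rdi_metric)}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# elementary operations


def summarize(values: Sequence[float]) -> MetricSummary:
    """Arithmetic mean, midpoint median, min/max and (n-1) SD."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return MetricSummary(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        sd=sd,
    )


class ThroughOriginRegression(RegressorMixin, BaseEstimator):
    """Least-squares regression forced through the origin.

    Fitted attributes: ``slope_``, ``rmse_``, ``nrmse_``, ``r2_uncentered_``,
    ``r2_centered_``, ``p_value_``, ``n_``.
    """

    def _vector(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("exactly one regressor is supported")
            x = x[:, 0]
        return x

    def fit(self, X, y) -> "ThroughOriginRegression":
        x = self._vector(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.size < 2:
            raise ValueError("x and y must be equal-length with n >= 2")
        sxx = float(x @ x)
        if sxx == 0.0:
            raise ValueError("degenerate regressor: all x are zero")
        n = x.size
        slope = float(x @ y) / sxx
        resid = y - slope * x
        sse = float(resid @ resid)
        self.slope_ = slope
        self.rmse_ = math.sqrt(sse / n)
        mean_y = float(y.mean())
        self.nrmse_ = self.rmse_ / mean_y if mean_y != 0 else math.inf
        syy = float(y @ y)
        self.r2_uncentered_ = 1.0 - sse / syy if syy > 0 else 1.0
        tss = float(((y - mean_y) ** 2).sum())
        self.r2_centered_ = 1.0 - sse / tss if tss > 0 else 1.0
        # t test on the through-origin slope, n - 1 residual dof
        df = n - 1
        se = math.sqrt(sse / df / sxx)
        if se == 0.0:
            self.p_value_ = 0.0
        else:
            t = slope / se
            self.p_value_ = float(2.0 * stats.t.sf(abs(t), df))
        self.n_ = n
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        return self.slope_ * self._vector(X)

    def result(self) -> OriginFit:
        check_is_fitted(self, "slope_")
        return OriginFit(
            slope=self.slope_,
            rmse=self.rmse_,
            nrmse=self.nrmse_,
            r2_uncentered=self.r2_uncentered_,
            r2_centered=self.r2_centered_,
            p_value=self.p_value_,
            n=self.n_,
        )


def fit_origin(x: Sequence[float], y: Sequence[float]) -> OriginFit:
    """Zero-intercept fit of ``y`` on ``x``; see :class:`ThroughOriginRegression`."""
    return ThroughOriginRegression().fit(np.asarray(x), np.asarray(y)).result()


def risk_sensitivity_index(slope: float, mean_y: float, mean_x: float) -> float:
    """RSI: fit slope normalized by the mean(metric)/mean(RI) ratio."""
    if mean_x <= 0 or mean_y <= 0:
        raise ValueError("means must be positive")
    return slope / (mean_y / mean_x)


def risk_differentiability_index(rmse: float, slope: float) -> float:
    """RDI: fit RMSE divided by the fit slope (risk-index units)."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if rmse < 0:
        raise ValueError("rmse must be >= 0")
    return rmse / slope


# ---------------------------------------------------------------------------
# cohort comparison


class RiskMetricComparator(BaseEstimator):
    """Fits E_DLP, E_OD and E_r against RI and ranks them by RSI and RDI.

    ``fit`` accepts a patient-level metric table (one row per patient with
    the six cumulative metric columns) and exposes ``report_``.
    """

    def __init__(self, compared_metrics: tuple[str, ...] = COMPARED_METRICS):
        self.compared_metrics = compared_metrics

    def fit(self, X: pd.DataFrame, y=None) -> "RiskMetricComparator":
        if len(X) == 0:
            raise ValueError("empty cohort")
        for col in METRIC_COLUMNS:
            if col not in X.columns:
                raise ValueError(f"missing metric column {col!r}")
        ri = X["ri"].to_numpy(dtype=float)
        summaries = {m: summarize(X[m].to_numpy(dtype=float)) for m in METRIC_COLUMNS}
        fits: dict[str, OriginFit] = {}
        rsi: dict[str, float] = {}
        rdi: dict[str, float] = {}
        for m in self.compared_metrics:
            yv = X[m].to_numpy(dtype=float)
            fit = fit_origin(ri, yv)
            fits[m] = fit
            rsi[m] = risk_sensitivity_index(fit.slope, summaries[m].mean, summaries["ri"].mean)
            rdi[m] = risk_differentiability_index(fit.rmse, fit.slope)
        best_rsi = min(rsi, key=lambda m: abs(rsi[m] - 1.0))
        best_rdi = min(rdi, key=lambda m: rdi[m])
        self.report_ = CohortReport(
            n_patients=len(X),
            summaries=summaries,
            fits=fits,
            rsi=rsi,
            rdi=rdi,
            best_rsi_metric=best_rsi,
            best_rdi_metric=best_rdi,
        )
        return self


def _patients_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = {"patient_id": p.patient_id, "sex": p.sex}
        row.update(p.cumulative.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def compare_metrics(cohort: Sequence[PatientRecord] | pd.DataFrame) -> CohortReport:
    """Assemble the cohort report from patient records or a patient table."""
    frame = cohort if isinstance(cohort, pd.DataFrame) else _patients_to_frame(cohort)
    return RiskMetricComparator().fit(frame).report_
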