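"""Per-exam risk metrics and patient-level accumulation.

Six quantities are computed for every CT exam:

===========  =============================================================
``e_dlp``    DLP-based effective dose, ``k(region) * DLP`` (mSv)
``e_od``     organ-dose based effective dose, ``sum_T w_T * OD_T`` (mSv)
``ri``       risk index, ``sum_T r_T(sex, age) * OD_T`` (cancers / 100)
``ri_rp``    risk index of a 35-year-old reference patient with
             sex-averaged coefficients, same organ doses (cancers / 100)
``f``        age/sex risk factor, ``ri / ri_rp`` (dimensionless)
``e_r``      relative effective dose, ``f * e_od`` (mSv')
===========  =============================================================

Patients with recurrent imaging accumulate per-exam metrics by summation
(each exam evaluated at the age it occurred); the cumulative ``f`` is the
ratio of the cumulative risk indices, and the cumulative ``e_r`` is the sum
of the per-exam ``f * e_od`` terms, which is the additive (canonical) choice.
The cohort inclusion rule keeps patients whose cumulative ``e_od`` reaches
100 mSv.

The module exposes both a record-level API (:class:`ExamRecord`,
:func:`compute_ri`, :func:`accumulate_patient`, ...) and a vectorised
DataFrame path wrapped in scikit-learn style transformers
(:class:`ExamMetrics`, :class:`PatientAccumulator`, :class:`CohortFilter`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .reference_data import (
    GONAD_ORGANS,
    SEX_SPECIFIC_ORGANS,
    SEXES,
    DLPConversionTable,
    LARTable,
    OrganSiteMap,
    ReferenceTables,
    TissueWeights,
    VocabularyError,
    default_tables,
)

__all__ = [
    "ExamRecord",
    "MetricSet",
    "PatientRecord",
    "UndefinedFactorError",
    "ConsistencyError",
    "METRIC_COLUMNS",
    "BASE_COLUMNS",
    "DEFAULT_THRESHOLD_MSV",
    "compute_e_dlp",
    "compute_e_od",
    "compute_ri",
    "compute_ri_rp",
    "compute_f",
    "compute_e_r",
    "compute_metrics",
    "accumulate_patient",
    "filter_cohort",
    "compute_exam_metrics_frame",
    "accumulate_patients_frame",
    "validate_exam_frame",
    "ExamMetrics",
    "PatientAccumulator",
    "CohortFilter",
]

BASE_COLUMNS = ("patient_id", "sex", "age_at_exam", "region", "dlp")
METRIC_COLUMNS = ("e_dlp", "e_od", "ri", "ri_rp", "f", "e_r")

#: Cumulative organ-dose based effective dose defining the recurrent
#: high-exposure cohort (mSv); inclusive comparison.
DEFAULT_THRESHOLD_MSV = 100.0


class UndefinedFactorError(ValueError):
    """f = RI / RI_rp requested with RI_rp = 0 but RI > 0."""


class ConsistencyError(ValueError):
    """Exams of one patient disagree on id, sex, or age ordering."""


def _tissue_of(organ: str) -> str:
    return "gonads" if organ in GONAD_ORGANS else organ


@dataclass(frozen=True)
class ExamRecord:
    """One CT exam: identifiers, body region, DLP and the organ-dose vector."""

    patient_id: str
    sex: str
    age_at_exam: float
    region: str
    dlp: float
    organ_doses: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_at_exam < 0:
            raise ValueError("age_at_exam must be >= 0")
        if self.dlp < 0:
            raise ValueError("dlp must be >= 0")
        for organ, dose in self.organ_doses.items():
            if dose < 0:
                raise ValueError(f"negative dose for organ {organ!r}")
            required = SEX_SPECIFIC_ORGANS.get(organ)
            if required is not None and required != self.sex and dose > 0:
                raise ValueError(
                    f"organ {organ!r} incompatible with sex {self.sex!r}"
                )

    def validate_vocabulary(self, site_map: OrganSiteMap) -> None:
        unknown = set(self.organ_doses) - set(site_map.organs)
        if unknown:
            raise VocabularyError(f"organs outside vocabulary: {sorted(unknown)}")


@dataclass(frozen=True)
class MetricSet:
    """The six metrics for one exam (or, accumulated, for one patient)."""

    e_dlp: float
    e_od: float
    ri: float
    ri_rp: float
    f: float
    e_r: float

    def __post_init__(self) -> None:
        for name in METRIC_COLUMNS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def check_exam_identities(self, rtol: float = 1e-9) -> None:
        """Verify e_r = f*e_od and f = ri/ri_rp (exam-level identities)."""
        if not np.isclose(self.e_r, self.f * self.e_od, rtol=rtol, atol=0.0):
            raise ValueError("e_r != f * e_od")
        if self.ri_rp > 0 and not np.isclose(
            self.f, self.ri / self.ri_rp, rtol=rtol, atol=0.0
        ):
            raise ValueError("f != ri / ri_rp")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_COLUMNS}


@dataclass(frozen=True)
class PatientRecord:
    """A patient's exams with per-exam and cumulative metrics.

    ``cumulative.e_r`` is the sum of per-exam ``f * e_od`` (canonical);
    ``e_r_from_cumulative_f`` is the alternative ``cum_f * cum_e_od``, which
    differs whenever exams occur at different ages.
    """

    patient_id: str
    sex: str
    exams: tuple[ExamRecord, ...]
    per_exam: tuple[MetricSet, ...]
    cumulative: MetricSet
    e_r_from_cumulative_f: float


# ---------------------------------------------------------------------------
# record-level metric operations


def compute_e_dlp(exam: ExamRecord, k_table: DLPConversionTable) -> float:
    """DLP-based effective dose: DLP times the adult region coefficient."""
    return exam.dlp * k_table.k_factor(exam.region)


def compute_e_od(exam: ExamRecord, weights: TissueWeights) -> float:
    """Organ-dose based effective dose, ICRP 103 weighting.

    Remainder organs enter through the arithmetic-mean remainder rule; this
    is identical to giving each remainder member the weight
    ``remainder_weight / member_count``.  Absent organs contribute 0.
    """
    total = 0.0
    for organ, dose in exam.organ_doses.items():
        total += weights.tissue_weight(_tissue_of(organ)) * dose
    return total


def _ri_sum(
    organ_doses: Mapping[str, float],
    site_map: OrganSiteMap,
    coefficient: "callable",
) -> float:
    total = 0.0
    for organ, dose in organ_doses.items():
        total += coefficient(site_map.site(organ)) * dose
    return total


def compute_ri(exam: ExamRecord, lar_table: LARTable, site_map: OrganSiteMap) -> float:
    """Risk index: sum of LAR(site, sex, age) times organ dose.

    An organ whose cancer site does not exist for the patient's sex (e.g.
    breast dose in a male) contributes 0.
    """

    def coef(site: str) -> float:
        if not lar_table.has(site, exam.sex):
            return 0.0
        return lar_table.lar(site, exam.sex, exam.age_at_exam)

    return _ri_sum(exam.organ_doses, site_map, coef)


def compute_ri_rp(exam: ExamRecord, lar_table: LARTable, site_map: OrganSiteMap) -> float:
    """Reference-patient risk index: sex-averaged LAR at age 35, same doses."""
    return _ri_sum(
        exam.organ_doses,
        site_map,
        lambda site: lar_table.sex_averaged_lar(site, 35.0),
    )


def compute_f(ri: float, ri_rp: float) -> float:
    """Age/sex factor f = RI / RI_rp; defined as 0 at zero dose."""
    if ri_rp > 0:
        return ri / ri_rp
    if ri == 0:
        return 0.0
    raise UndefinedFactorError("RI > 0 with RI_rp = 0")


def compute_e_r(f: float, e_od: float) -> float:
    """Relative effective dose: f times the organ-dose effective dose."""
    if f < 0 or e_od < 0:
        raise ValueError("f and e_od must be >= 0")
    return f * e_od


def compute_metrics(exam: ExamRecord, tables: ReferenceTables) -> MetricSet:
    """All six metrics for one exam."""
    exam.validate_vocabulary(tables.site_map)
    e_dlp = compute_e_dlp(exam, tables.dlp)
    e_od = compute_e_od(exam, tables.tissue_weights)
    ri = compute_ri(exam, tables.lar, tables.site_map)
    ri_rp = compute_ri_rp(exam, tables.lar, tables.site_map)
    f = compute_f(ri, ri_rp)
    return MetricSet(e_dlp=e_dlp, e_od=e_od, ri=ri, ri_rp=ri_rp, f=f, e_r=compute_e_r(f, e_od))


def accumulate_patient(
    exams: Sequence[ExamRecord], tables: ReferenceTables
) -> PatientRecord:
    """Per-exam metrics at the age of each exam, then summation.

    Cumulative ``f`` is the ratio of cumulative risk indices; cumulative
    ``e_r`` is the sum of per-exam ``f * e_od``.
    """
    if not exams:
        raise ConsistencyError("patient has no exams")
    ids = {e.patient_id for e in exams}
    sexes = {e.sex for e in exams}
    if len(ids) != 1 or len(sexes) != 1:
        raise ConsistencyError(f"mixed patient ids {ids} or sexes {sexes}")
    ages = [e.age_at_exam for e in exams]
    if any(b < a for a, b in zip(ages, ages[1:])):
        raise ConsistencyError("exam ages must be non-decreasing")

    per_exam = tuple(compute_metrics(e, tables) for e in exams)
    sums = {
        name: float(sum(getattr(m, name) for m in per_exam))
        for name in ("e_dlp", "e_od", "ri", "ri_rp", "e_r")
    }
    cum_f = compute_f(sums["ri"], sums["ri_rp"])
    cumulative = MetricSet(f=cum_f, **sums)
    return PatientRecord(
        patient_id=exams[0].patient_id,
        sex=exams[0].sex,
        exams=tuple(exams),
        per_exam=per_exam,
        cumulative=cumulative,
        e_r_from_cumulative_f=cum_f * sums["e_od"],
    )


def filter_cohort(
    patients: Sequence[PatientRecord], threshold: float = DEFAULT_THRESHOLD_MSV
) -> list[PatientRecord]:
    """Keep patients with cumulative E_OD >= threshold (inclusive), in order."""
    return [p for p in patients if p.cumulative.e_od >= threshold]


# ---------------------------------------------------------------------------
# vectorised DataFrame path


def validate_exam_frame(df: pd.DataFrame, tables: ReferenceTables) -> list[str]:
    """Validate an exam table; returns the organ columns actually present.

    Raises ``ValueError``/``VocabularyError`` naming offending rows and
    columns. Organ cells may be empty (NaN), meaning the organ is absent.
    """
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"exam table missing required columns: {missing}")
    # "protocol" is optional provenance metadata written by the simulator
    extra = set(df.columns) - set(BASE_COLUMNS) - set(tables.organs) - {"protocol"}
    if extra:
        raise VocabularyError(f"unknown organ columns: {sorted(extra)}")
    organ_cols = [c for c in tables.organs if c in df.columns]

    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValueError(f"invalid sex at rows {df.index[bad_sex].tolist()[:5]}")
    for col in ("age_at_exam", "dlp"):
        neg = df[col].to_numpy(dtype=float) < 0
        if neg.any():
            row = df.index[neg][0]
            raise ValueError(f"negative {col} at row {row}")
    unknown_region = ~df["region"].isin(tables.dlp.regions)
    if unknown_region.any():
        row = df.index[unknown_region][0]
        raise VocabularyError(f"unknown region {df.loc[row, 'region']!r} at row {row}")
    for col in organ_cols:
        values = df[col].to_numpy(dtype=float)
        neg = values < 0  # NaN compares False
        if neg.any():
            row = df.index[neg][0]
            raise ValueError(f"negative dose in column {col!r} at row {row}")
        required = SEX_SPECIFIC_ORGANS.get(col)
        if required is not None:
            clash = (df["sex"] != required).to_numpy() & (values > 0)
            if clash.any():
                row = df.index[clash][0]
                raise ValueError(
                    f"organ {col!r} incompatible with sex at row {row}"
                )
    return organ_cols


def compute_exam_metrics_frame(
    df: pd.DataFrame, tables: ReferenceTables | None = None
) -> pd.DataFrame:
    """Append the six per-exam metric columns to an exam table."""
    tables = tables or default_tables()
    organ_cols = validate_exam_frame(df, tables)
    out = df.copy()
    n = len(df)
    doses = {
        c: np.nan_to_num(df[c].to_numpy(dtype=float), nan=0.0) for c in organ_cols
    }
    ages = df["age_at_exam"].to_numpy(dtype=float)
    sex = df["sex"].to_numpy()

    out["e_dlp"] = df["dlp"].to_numpy(dtype=float) * df["region"].map(
        tables.dlp.k
    ).to_numpy(dtype=float)

    weights = tables.tissue_weights
    e_od = np.zeros(n)
    for organ, dose in doses.items():
        e_od += weights.tissue_weight(_tissue_of(organ)) * dose
    out["e_od"] = e_od

    ri = np.zeros(n)
    for s in SEXES:
        mask = sex == s
        if not mask.any():
            continue
        for organ, dose in doses.items():
            site = tables.site_map.site(organ)
            if not tables.lar.has(site, s):
                continue
            ri[mask] += tables.lar.lar_many(site, s, ages[mask]) * dose[mask]
    out["ri"] = ri

    r35 = {site: tables.lar.sex_averaged_lar(site, 35.0) for site in tables.lar.sites}
    ri_rp = np.zeros(n)
    for organ, dose in doses.items():
        ri_rp += r35[tables.site_map.site(organ)] * dose
    out["ri_rp"] = ri_rp

    undefined = (ri_rp == 0) & (ri > 0)
    if undefined.any():
        raise UndefinedFactorError(
            f"RI > 0 with RI_rp = 0 at row {df.index[undefined][0]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(ri_rp > 0, ri / np.where(ri_rp > 0, ri_rp, 1.0), 0.0)
    out["f"] = f
    out["e_r"] = f * e_od
    return out


def accumulate_patients_frame(exam_metrics: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-exam metric rows to one cumulative row per patient.

    Input must already carry the metric columns (see
    :func:`compute_exam_metrics_frame`) and be ordered by exam age within
    each patient.
    """
    for col in METRIC_COLUMNS:
        if col not in exam_metrics.columns:
            raise ValueError(f"missing metric column {col!r}; compute exam metrics first")
    if exam_metrics.empty:
        raise ValueError("no exams to accumulate")
    sex_counts = exam_metrics.groupby("patient_id")["sex"].nunique()
    mixed = sex_counts[sex_counts > 1]
    if not mixed.empty:
        raise ConsistencyError(f"patients with inconsistent sex: {list(mixed.index[:5])}")
    decreasing = exam_metrics.groupby("patient_id")["age_at_exam"].apply(
        lambda a: bool((a.diff().dropna() < 0).any())
    )
    if decreasing.any():
        raise ConsistencyError(
            f"exam ages decrease within patients: {list(decreasing[decreasing].index[:5])}"
        )

    grouped = exam_metrics.groupby("patient_id", sort=False)
    out = grouped.agg(
        sex=("sex", "first"),
        n_exams=("age_at_exam", "size"),
        age_first_exam=("age_at_exam", "first"),
        age_last_exam=("age_at_exam", "last"),
        e_dlp=("e_dlp", "sum"),
        e_od=("e_od", "sum"),
        ri=("ri", "sum"),
        ri_rp=("ri_rp", "sum"),
        e_r=("e_r", "sum"),
    ).reset_index()
    ri, ri_rp = out["ri"].to_numpy(), out["ri_rp"].to_numpy()
    if ((ri_rp == 0) & (ri > 0)).any():
        raise UndefinedFactorError("cumulative RI > 0 with cumulative RI_rp = 0")
    out["f"] = np.where(ri_rp > 0, ri / np.where(ri_rp > 0, ri_rp, 1.0), 0.0)
    out["e_r_from_cumulative_f"] = out["f"] * out["e_od"]
    return out[
        ["patient_id", "sex", "n_exams", "age_first_exam", "age_last_exam"]
        + list(METRIC_COLUMNS)
        + ["e_r_from_cumulative_f"]
    ]


# ---------------------------------------------------------------------------
# scikit-learn estimators


class ExamMetrics(TransformerMixin, BaseEstimator):
    """Transformer adding the six metric columns to an exam table.

    Parameters
    ----------
    tables : ReferenceTables, optional
        Coefficient bundle; the packaged ICRP 102/103 + BEIR VII resources
        when omitted.
    """

    def __init__(self, tables: ReferenceTables | None = None):
        self.tables = tables

    def fit(self, X: pd.DataFrame, y=None) -> "ExamMetrics":
        self.tables_ = self.tables if self.tables is not None else default_tables()
        self.organ_columns_ = validate_exam_frame(X, self.tables_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "tables_")
        return compute_exam_metrics_frame(X, self.tables_)


class PatientAccumulator(TransformerMixin, BaseEstimator):
    """Transformer collapsing exam-level metrics to patient-level sums."""

    def fit(self, X: pd.DataFrame, y=None) -> "PatientAccumulator":
        self.n_exams_seen_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return accumulate_patients_frame(X)


class CohortFilter(TransformerMixin, BaseEstimator):
    """Inclusion filter: cumulative organ-dose effective dose >= threshold.

    Parameters
    ----------
    threshold : float, default 100.0
        Cumulative E_OD cut in mSv, compared inclusively.
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD_MSV):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None) -> "CohortFilter":
        self.n_seen_ = len(X)
        self.n_retained_ = int((X["e_od"] >= self.threshold).sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[X["e_od"] >= self.threshold]
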