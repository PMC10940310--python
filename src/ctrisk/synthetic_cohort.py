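"""Seeded synthetic cohorts of recurrent CT exams.

Stands in for the (proprietary) dose-monitoring extract the analysis expects:
an elderly-skewed age/sex mix sampled from banded demographic weights,
several exams per patient inside a five-year window, and per-exam organ-dose
vectors obtained by scaling a protocol-specific template by a log-normally
distributed dose-length product.  Doses are globally calibrated so that a
configurable fraction of patients accumulates at least the 100 mSv
organ-dose effective dose that defines the study cohort.

Within a protocol, organ doses are strictly proportional to DLP; this
deliberately ignores tube-current modulation, which in reality perturbs the
dose vector patient by patient (an optional multiplicative jitter,
``tcm_noise``, emulates it and is off by default).  In single-protocol mode
every exam uses one sex-neutral chest template, which makes the relative
effective dose exactly proportional to the risk index across the cohort — a
useful end-to-end oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dose_metrics import (
    BASE_COLUMNS,
    DEFAULT_THRESHOLD_MSV,
    ExamRecord,
    compute_e_od,
    compute_exam_metrics_frame,
    compute_ri_rp,
)
from .reference_data import SEX_SPECIFIC_ORGANS, ReferenceTables, default_tables

__all__ = [
    "DemographicModel",
    "ProtocolTemplate",
    "CohortConfig",
    "CohortGenerator",
    "default_demographics",
    "default_protocols",
    "sample_demographics",
    "generate_cohort",
    "template_unit_metrics",
]


@dataclass(frozen=True)
class DemographicModel:
    """Banded age/sex weights; age is uniform within a band.

    ``bands`` rows are (age_low, age_high, female_weight, male_weight); the
    default weights are the study cohort's printed counts per decade.
    """

    bands: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("no demographic bands")
        prev_high = None
        total = 0.0
        for low, high, fw, mw in self.bands:
            if high <= low:
                raise ValueError(f"empty band [{low}, {high})")
            if fw < 0 or mw < 0:
                raise ValueError("negative band weight")
            if prev_high is not None and low < prev_high:
                raise ValueError("overlapping bands")
            prev_high = high
            total += fw + mw
        if total <= 0:
            raise ValueError("all demographic weights are zero")

    @property
    def total_weight(self) -> float:
        return float(sum(fw + mw for _, _, fw, mw in self.bands))

    def cell_probabilities(self) -> tuple[list[tuple[float, float, str]], np.ndarray]:
        """Flatten to (low, high, sex) cells with normalized probabilities."""
        cells: list[tuple[float, float, str]] = []
        weights: list[float] = []
        for low, high, fw, mw in self.bands:
            cells.append((low, high, "female"))
            weights.append(fw)
            cells.append((low, high, "male"))
            weights.append(mw)
        w = np.asarray(weights, dtype=float)
        return cells, w / w.sum()


def default_demographics() -> DemographicModel:
    """Age/sex counts of the 8918-patient recurrent-imaging cohort."""
    return DemographicModel(
        bands=(
            (20, 30, 21, 30),
            (30, 40, 129, 152),
            (40, 50, 261, 211),
            (50, 60, 538, 584),
            (60, 70, 1104, 1106),
            (70, 80, 1279, 1391),
            (80, 90, 757, 930),
            (90, 100, 222, 203),
        )
    )


@dataclass(frozen=True)
class ProtocolTemplate:
    """An exam protocol: body region, organ doses per unit DLP, DLP law.

    ``unit_organ_doses`` are mGy per mGy·cm; the per-exam dose vector is this
    template times a DLP drawn log-normally with the given median (mGy·cm)
    and geometric standard deviation.
    """

    name: str
    region: str
    unit_organ_doses: Mapping[str, float]
    dlp_median: float
    dlp_gsd: float = 1.6

    def __post_init__(self) -> None:
        if not self.unit_organ_doses or all(v <= 0 for v in self.unit_organ_doses.values()):
            raise ValueError(f"protocol {self.name!r} deposits no dose")
        if any(v < 0 for v in self.unit_organ_doses.values()):
            raise ValueError("negative unit organ dose")
        if self.dlp_median <= 0 or self.dlp_gsd < 1.0:
            raise ValueError("dlp_median must be > 0 and dlp_gsd >= 1")

    @property
    def sex_neutral(self) -> bool:
        return not any(o in SEX_SPECIFIC_ORGANS for o in self.unit_organ_doses)


def default_protocols() -> tuple[ProtocolTemplate, ...]:
    """Four adult CT protocols typical of recurrent high-dose imaging."""
    chest = ProtocolTemplate(
        name="chest",
        region="chest",
        dlp_median=450.0,
        dlp_gsd=1.6,
        unit_organ_doses={
            "lung": 0.040,
            "breast": 0.037,
            "heart": 0.040,
            "esophagus": 0.035,
            "thymus": 0.038,
            "thyroid": 0.015,
            "stomach": 0.012,
            "liver": 0.018,
            "adrenals": 0.012,
            "spleen": 0.015,
            "red_bone_marrow": 0.010,
            "bone_surface": 0.020,
            "skin": 0.010,
            "salivary_glands": 0.002,
            "brain": 0.001,
            "kidneys": 0.006,
            "pancreas": 0.008,
            "gall_bladder": 0.006,
            "small_intestine": 0.002,
            "colon": 0.001,
            "bladder": 0.0003,
        },
    )
    abdomen_pelvis = ProtocolTemplate(
        name="abdomen_pelvis",
        region="abdomen_pelvis",
        dlp_median=1100.0,
        dlp_gsd=1.6,
        unit_organ_doses={
            "stomach": 0.035,
            "liver": 0.035,
            "colon": 0.035,
            "small_intestine": 0.035,
            "kidneys": 0.035,
            "pancreas": 0.032,
            "spleen": 0.033,
            "gall_bladder": 0.034,
            "adrenals": 0.030,
            "bladder": 0.035,
            "prostate": 0.033,
            "uterus": 0.033,
            "ovaries": 0.033,
            "testes": 0.020,
            "red_bone_marrow": 0.012,
            "bone_surface": 0.022,
            "lung": 0.008,
            "heart": 0.006,
            "esophagus": 0.003,
            "breast": 0.004,
            "skin": 0.010,
            "thymus": 0.002,
            "thyroid": 0.001,
            "brain": 0.0002,
            "salivary_glands": 0.0003,
        },
    )
    head = ProtocolTemplate(
        name="head",
        region="head",
        dlp_median=950.0,
        dlp_gsd=1.4,
        unit_organ_doses={
            "brain": 0.045,
            "salivary_glands": 0.030,
            "thyroid": 0.008,
            "skin": 0.012,
            "bone_surface": 0.030,
            "red_bone_marrow": 0.004,
            "esophagus": 0.001,
            "lung": 0.0002,
        },
    )
    pelvis = ProtocolTemplate(
        name="pelvis",
        region="pelvis",
        dlp_median=600.0,
        dlp_gsd=1.6,
        unit_organ_doses={
            "bladder": 0.035,
            "prostate": 0.035,
            "uterus": 0.035,
            "ovaries": 0.035,
            "testes": 0.030,
            "small_intestine": 0.020,
            "colon": 0.030,
            "red_bone_marrow": 0.010,
            "bone_surface": 0.020,
            "skin": 0.010,
            "kidneys": 0.003,
            "liver": 0.001,
            "stomach": 0.002,
        },
    )
    return (chest, abdomen_pelvis, head, pelvis)


#: Default protocol mix: recurrent high-dose imaging is dominated by
#: chest and abdomen-pelvis acquisitions.
DEFAULT_PROTOCOL_WEIGHTS = {
    "chest": 0.35,
    "abdomen_pelvis": 0.45,
    "head": 0.12,
    "pelvis": 0.08,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; ``seed`` is mandatory for reproducibility.

    Exam counts follow ``exam_count_min`` plus a negative-binomial draw
    (mean ``exam_count_mean - exam_count_min``, dispersion
    ``exam_count_shape``), truncated at ``exam_count_max``.  Exam times are
    uniform in a ``followup_years`` window.  ``filter_pass_fraction``
    calibrates a global dose scale so that this fraction of patients exceeds
    ``threshold`` mSv of cumulative E_OD (None disables calibration).
    ``tcm_noise`` is the geometric SD (as sigma of log) of an optional
    per-organ dose jitter emulating tube-current modulation.
    """

    seed: int
    n_patients: int = 500
    exam_count_min: int = 2
    exam_count_max: int = 30
    exam_count_mean: float = 8.0
    exam_count_shape: float = 2.0
    followup_years: float = 5.0
    protocol_weights: Mapping[str, float] | None = None
    single_protocol: bool = False
    filter_pass_fraction: float | None = 0.75
    threshold: float = DEFAULT_THRESHOLD_MSV
    tcm_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (2 <= self.exam_count_min <= self.exam_count_max):
            raise ValueError("need 2 <= exam_count_min <= exam_count_max")
        if self.exam_count_mean < self.exam_count_min:
            raise ValueError("exam_count_mean below exam_count_min")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be > 0")
        if self.filter_pass_fraction is not None and not (
            0.0 < self.filter_pass_fraction <= 1.0
        ):
            raise ValueError("filter_pass_fraction must be in (0, 1]")
        if self.tcm_noise < 0:
            raise ValueError("tcm_noise must be >= 0")


def sample_demographics(
    n: int,
    model: DemographicModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (sex, age) pairs: multinomial over band×sex cells, then
    uniform age within the band.  Returns (sexes, ages) arrays."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or default_demographics()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells, probs = model.cell_probabilities()
    counts = rng.multinomial(n, probs)
    sexes: list[str] = []
    ages: list[np.ndarray] = []
    for (low, high, sex), count in zip(cells, counts):
        if count == 0:
            continue
        sexes.extend([sex] * count)
        ages.append(rng.uniform(low, high, count))
    sex_arr = np.asarray(sexes, dtype=object)
    age_arr = np.concatenate(ages)
    order = rng.permutation(n)
    return sex_arr[order], age_arr[order]


def _draw_exam_count(config: CohortConfig, rng: np.random.Generator) -> int:
    mu = config.exam_count_mean - config.exam_count_min
    if mu <= 0:
        return config.exam_count_min
    k = config.exam_count_shape
    p = k / (k + mu)
    extra = int(rng.negative_binomial(k, p))
    return min(config.exam_count_min + extra, config.exam_count_max)


def generate_cohort(
    config: CohortConfig,
    templates: Sequence[ProtocolTemplate] | None = None,
    model: DemographicModel | None = None,
    tables: ReferenceTables | None = None,
) -> pd.DataFrame:
    """Generate an exam table (the dose-metrics input dialect).

    One row per exam with base columns plus one dose column per monitored
    organ; organs a protocol does not irradiate, and organs incompatible
    with the patient's sex, are left empty.
    """
    templates = tuple(templates) if templates is not None else default_protocols()
    if not templates:
        raise ValueError("empty template list")
    model = model or default_demographics()
    tables = tables or default_tables()
    organs = list(tables.organs)
    rng = np.random.default_rng(config.seed)

    if config.single_protocol:
        neutral = [i for i, t in enumerate(templates) if t.sex_neutral]
        if not neutral:
            raise ValueError("single-protocol mode needs a sex-neutral template")
        protocol_probs = None
        single_idx = neutral[0]
    else:
        weights = config.protocol_weights or DEFAULT_PROTOCOL_WEIGHTS
        w = np.asarray([weights.get(t.name, 0.0) for t in templates], dtype=float)
        if w.sum() <= 0:
            raise ValueError("protocol weights select no template")
        protocol_probs = w / w.sum()
        single_idx = None

    sexes, ages0 = sample_demographics(config.n_patients, model, rng)

    pid_col: list[str] = []
    sex_col: list[str] = []
    age_col: list[float] = []
    proto_idx: list[int] = []
    dlp_col: list[float] = []
    for i in range(config.n_patients):
        count = _draw_exam_count(config, rng)
        offsets = np.sort(rng.uniform(0.0, config.followup_years, count))
        offsets = offsets + np.arange(count) * 1e-9  # break exact ties
        if single_idx is not None:
            idx = np.full(count, single_idx)
        else:
            idx = rng.choice(len(templates), size=count, p=protocol_probs)
        log_dlp = np.array(
            [
                rng.normal(math.log(templates[j].dlp_median), math.log(templates[j].dlp_gsd))
                for j in idx
            ]
        )
        pid = f"P{i + 1:06d}"
        pid_col.extend([pid] * count)
        sex_col.extend([sexes[i]] * count)
        age_col.extend((ages0[i] + offsets).tolist())
        proto_idx.extend(idx.tolist())
        dlp_col.extend(np.exp(log_dlp).tolist())

    n_exams = len(pid_col)
    proto_arr = np.asarray(proto_idx)
    dlp_arr = np.asarray(dlp_col)
    unit = np.zeros((len(templates), len(organs)))
    for j, t in enumerate(templates):
        for organ, v in t.unit_organ_doses.items():
            unit[j, organs.index(organ)] = v
    dose = unit[proto_arr] * dlp_arr[:, None]
    if config.tcm_noise > 0:
        dose = dose * np.exp(rng.normal(0.0, config.tcm_noise, size=dose.shape))
    dose[unit[proto_arr] == 0] = np.nan

    sex_arr = np.asarray(sex_col, dtype=object)
    for organ, required in SEX_SPECIFIC_ORGANS.items():
        col = organs.index(organ)
        dose[sex_arr != required, col] = np.nan

    df = pd.DataFrame(
        {
            "patient_id": pid_col,
            "sex": sex_col,
            "age_at_exam": age_col,
            "region": [templates[j].region for j in proto_arr],
            "protocol": [templates[j].name for j in proto_arr],
            "dlp": dlp_arr,
        }
    )
    for c, organ in enumerate(organs):
        df[organ] = dose[:, c]

    if config.filter_pass_fraction is not None:
        metrics = compute_exam_metrics_frame(df, tables)
        cum = metrics.groupby("patient_id", sort=False)["e_od"].sum().to_numpy()
        anchor = float(np.quantile(cum, 1.0 - config.filter_pass_fraction))
        if anchor <= 0:
            raise ValueError("cannot calibrate doses: anchor quantile is zero")
        scale = config.threshold / anchor
        df["dlp"] = df["dlp"] * scale
        df[organs] = df[organs] * scale
    return df


def template_unit_metrics(
    template: ProtocolTemplate,
    tables: ReferenceTables | None = None,
    sex: str = "female",
) -> tuple[float, float]:
    """(E_OD, RI_rp) of the template at unit DLP for the given sex.

    For a sex-neutral template both values are sex-independent; their ratio
    E_OD0 / RI_rp0 is the exact E_r-versus-RI slope of any single-protocol
    cohort.
    """
    tables = tables or default_tables()
    doses = {
        o: v
        for o, v in template.unit_organ_doses.items()
        if SEX_SPECIFIC_ORGANS.get(o, sex) == sex
    }
    exam = ExamRecord(
        patient_id="template",
        sex=sex,
        age_at_exam=35.0,
        region=template.region,
        dlp=1.0,
        organ_doses=doses,
    )
    e_od0 = compute_e_od(exam, tables.tissue_weights)
    ri_rp0 = compute_ri_rp(exam, tables.lar, tables.site_map)
    return e_od0, ri_rp0


class CohortGenerator(BaseEstimator):
    """scikit-learn style front end over :func:`generate_cohort`.

    Parameters mirror :class:`CohortConfig`; ``generate()`` (or ``sample()``)
    returns the exam table.
    """

    def __init__(
        self,
        seed: int = 0,
        n_patients: int = 500,
        exam_count_min: int = 2,
        exam_count_max: int = 30,
        exam_count_mean: float = 8.0,
        exam_count_shape: float = 2.0,
        followup_years: float = 5.0,
        protocol_weights: Mapping[str, float] | None = None,
        single_protocol: bool = False,
        filter_pass_fraction: float | None = 0.75,
        threshold: float = DEFAULT_THRESHOLD_MSV,
        tcm_noise: float = 0.0,
    ):
        self.seed = seed
        self.n_patients = n_patients
        self.exam_count_min = exam_count_min
        self.exam_count_max = exam_count_max
        self.exam_count_mean = exam_count_mean
        self.exam_count_shape = exam_count_shape
        self.followup_years = followup_years
        self.protocol_weights = protocol_weights
        self.single_protocol = single_protocol
        self.filter_pass_fraction = filter_pass_fraction
        self.threshold = threshold
        self.tcm_noise = tcm_noise

    def config(self) -> CohortConfig:
        return CohortConfig(**self.get_params())

    def generate(
        self,
        templates: Sequence[ProtocolTemplate] | None = None,
        model: DemographicModel | None = None,
        tables: ReferenceTables | None = None,
    ) -> pd.DataFrame:
        return generate_cohort(self.config(), templates, model, tables)

    sample = generate
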