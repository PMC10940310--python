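"""Readers, writers, and the end-to-end pipeline.

Exam tables are comma-delimited UTF-8 text with a header row: the base
columns ``patient_id, sex, age_at_exam, region, dlp`` followed by one column
per monitored organ (empty cell = organ absent).  Machine outputs keep full
precision; rounding happens only in the human-readable report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort_analysis import CohortReport, compare_metrics
from .dose_metrics import (
    DEFAULT_THRESHOLD_MSV,
    ExamRecord,
    accumulate_patients_frame,
    compute_exam_metrics_frame,
    validate_exam_frame,
)
from .reference_data import (
    ReferenceTables,
    default_tables,
    load_dlp_table,
    load_lar_table,
    load_organ_site_map,
    load_tissue_weights,
)

__all__ = [
    "PipelineConfig",
    "EmptyCohortError",
    "read_exam_table",
    "read_exam_records",
    "write_table",
    "run_pipeline",
]

log = logging.getLogger("ctrisk")


class EmptyCohortError(RuntimeError):
    """No patient passed the inclusion filter."""


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline settings: coefficient resources, filter threshold, rounding.

    ``None`` resource paths select the packaged (checksummed) tables.
    """

    tissue_weights_path: str | None = None
    dlp_k_path: str | None = None
    lar_path: str | None = None
    organ_site_map_path: str | None = None
    threshold: float = DEFAULT_THRESHOLD_MSV
    summary_decimals: int = 1
    fit_decimals: int = 2
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    def load_tables(self) -> ReferenceTables:
        if all(
            p is None
            for p in (
                self.tissue_weights_path,
                self.dlp_k_path,
                self.lar_path,
                self.organ_site_map_path,
            )
        ):
            return default_tables()
        tables = ReferenceTables(
            tissue_weights=load_tissue_weights(self.tissue_weights_path),
            dlp=load_dlp_table(self.dlp_k_path),
            lar=load_lar_table(self.lar_path),
            site_map=load_organ_site_map(self.organ_site_map_path),
        )
        tables.site_map.validate_against(tables.lar)
        return tables


def read_exam_table(
    path: str | Path, tables: ReferenceTables | None = None
) -> pd.DataFrame:
    """Read and validate an exam table; errors name the offending row/column."""
    tables = tables or default_tables()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    validate_exam_frame(df, tables)
    return df


def read_exam_records(
    path: str | Path, tables: ReferenceTables | None = None
) -> list[ExamRecord]:
    """Exam table as validated :class:`ExamRecord` objects."""
    tables = tables or default_tables()
    df = read_exam_table(path, tables)
    organ_cols = [c for c in tables.organs if c in df.columns]
    records = []
    for _, row in df.iterrows():
        doses = {
            o: float(row[o]) for o in organ_cols if pd.notna(row[o])
        }
        records.append(
            ExamRecord(
                patient_id=str(row["patient_id"]),
                sex=row["sex"],
                age_at_exam=float(row["age_at_exam"]),
                region=row["region"],
                dlp=float(row["dlp"]),
                organ_doses=doses,
            )
        )
    return records


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table at full stored precision (comma, UTF-8, header)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_pipeline(
    config: PipelineConfig, exam_path: str | Path
) -> tuple[CohortReport, pd.DataFrame]:
    """read -> compute -> accumulate -> filter -> compare.

    Returns the cohort report and the (filtered) per-patient metric table.
    Raises :class:`EmptyCohortError` if no patient reaches the threshold.
    """
    tables = config.load_tables()
    exams = read_exam_table(exam_path, tables)
    log.info("read %d exam rows from %s", len(exams), exam_path)
    metrics = compute_exam_metrics_frame(exams, tables)
    patients = accumulate_patients_frame(metrics)
    kept = patients[patients["e_od"] >= config.threshold]
    n_read, n_kept = len(patients), len(kept)
    log.info(
        "patients read=%d filtered_out=%d analyzed=%d (threshold %.6g mSv)",
        n_read,
        n_read - n_kept,
        n_kept,
        config.threshold,
    )
    if n_kept == 0:
        raise EmptyCohortError(
            f"no patient reaches cumulative E_OD >= {config.threshold} mSv"
        )
    report = compare_metrics(kept)
    return report, kept.reset_index(drop=True)
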