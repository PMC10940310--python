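"""Published coefficient sets behind the dose and risk metrics.

Three tables drive every metric in the package:

* ICRP 103 tissue weighting factors ``w_T`` (with the remainder handled as an
  arithmetic mean over its member tissues), used for the organ-dose based
  effective dose ``E_OD = sum_T w_T * OD_T``.
* ICRP 102 (Table A.2) DLP-to-effective-dose conversion coefficients ``k`` for
  adult body regions, used for ``E_DLP = k * DLP``.
* BEIR VII lifetime attributable risk (LAR) of cancer *incidence* in the US
  population, by cancer site, sex, and age at exposure, used as the
  coefficients ``r_T`` of the risk index ``RI = sum_T r_T * OD_T``.

The raw BEIR VII values are tabulated as cases per 100,000 persons exposed to
0.1 Gy.  They are converted on access to cases per 100 persons per mSv
(divide by 100,000), so that ``RI`` comes out directly as a number of cancers
per 100 patients when organ doses are in mGy (numerically ~mSv for the photon
exposures of CT).

All four coefficient files ship as CSV resources under ``ctrisk/data`` and are
integrity-checked against a sha256 checksum when loaded from the package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VocabularyError",
    "SiteSexError",
    "TissueWeights",
    "DLPConversionTable",
    "LARTable",
    "OrganSiteMap",
    "ReferenceTables",
    "load_tissue_weights",
    "load_dlp_table",
    "load_lar_table",
    "load_organ_site_map",
    "default_tables",
    "tissue_weight",
    "k_factor",
    "lar",
    "sex_averaged_lar",
]

SEXES = ("male", "female")

#: BEIR VII sites that exist for exactly one sex.
SEX_SPECIFIC_SITES: Mapping[str, str] = {
    "breast": "female",
    "ovary": "female",
    "uterus": "female",
    "prostate": "male",
}

#: Monitored organs that may only appear on one sex's exams.
SEX_SPECIFIC_ORGANS: Mapping[str, str] = {
    "ovaries": "female",
    "uterus": "female",
    "prostate": "male",
    "testes": "male",
}

#: Monitored organs contributing to the ICRP 103 "gonads" tissue.
GONAD_ORGANS = ("testes", "ovaries")

# sha256 of the packaged resources; guards against silent corruption of the
# transcribed coefficient tables.
_CHECKSUMS = {
    "tissue_weights.csv": "dca7687f95b4cca3234f37129ee38aae9d7b500dedb8a13a8ef1b3383a8e2a59",
    "dlp_k.csv": "2011cc11a62c791b13f04a1ff60e818331fde4342bad6ab274a2c3c6c7fa8166",
    "beir7_lar_incidence.csv": "6884c9d9fcfeccd7c02091ed2f13acb82471279e8f1484bbc49180fe895fbd8d",
    "organ_site_map.csv": "ae64a802adba992099d207eeaa9cae0a6d8a5f13ed8eabaf13019ca92e5f0ca9",
}

_RAW_TO_PER100_PER_MSV = 1.0 / 100_000.0


class VocabularyError(KeyError):
    """An organ, tissue, region, or site outside the closed vocabulary."""


class SiteSexError(ValueError):
    """A cancer site queried for a sex in which it does not exist."""


def _resource_path(name: str) -> Path:
    return Path(str(files("ctrisk").joinpath("data", name)))


def _verify_checksum(path: Path, name: str) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected = _CHECKSUMS[name]
    if digest != expected:
        raise ValueError(
            f"coefficient resource {name!r} failed its integrity check "
            f"(sha256 {digest} != {expected})"
        )


@dataclass(frozen=True)
class TissueWeights:
    """ICRP 103 tissue weighting factors.

    ``weights`` holds the individually weighted tissues; ``remainder_members``
    the tissues pooled into the remainder block, which carries
    ``remainder_weight`` as a whole and is evaluated as the arithmetic mean of
    its member doses.  Prostate and uterus are alternate (sex-specific)
    members occupying a single slot, so the per-person member count used as
    the averaging divisor is ``len(remainder_members) - 1`` when both are
    present.
    """

    weights: Mapping[str, float]
    remainder_members: tuple[str, ...]
    remainder_weight: float = 0.12

    def __post_init__(self) -> None:
        if not self.remainder_members:
            raise ValueError("remainder_members must be non-empty")
        overlap = set(self.weights) & set(self.remainder_members)
        if overlap:
            raise ValueError(f"tissues both weighted and remainder: {sorted(overlap)}")
        for t, w in self.weights.items():
            if not 0.0 < w < 1.0:
                raise ValueError(f"weight for {t!r} outside (0, 1): {w}")
        if not 0.0 < self.remainder_weight < 1.0:
            raise ValueError("remainder weight outside (0, 1)")
        total = sum(self.weights.values()) + self.remainder_weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tissue weights sum to {total!r}, expected 1.0")

    @property
    def member_count(self) -> int:
        """Remainder members per reference person of a single sex."""
        n = len(self.remainder_members)
        if {"prostate", "uterus"} <= set(self.remainder_members):
            n -= 1
        return n

    def tissue_weight(self, tissue: str) -> float:
        if tissue in self.weights:
            return self.weights[tissue]
        if tissue in self.remainder_members:
            return self.remainder_weight / self.member_count
        raise VocabularyError(f"unknown tissue {tissue!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, w, 0) for t, w in self.weights.items()]
        rows += [(t, self.remainder_weight, 1) for t in self.remainder_members]
        return pd.DataFrame(rows, columns=["tissue", "weight", "is_remainder"])


@dataclass(frozen=True)
class DLPConversionTable:
    """Adult DLP-to-effective-dose conversion coefficients (mSv per mGy·cm)."""

    k: Mapping[str, float]

    def __post_init__(self) -> None:
        for region, value in self.k.items():
            if not 0.0 < value < 0.1:
                raise ValueError(f"k for {region!r} outside (0, 0.1): {value}")

    @property
    def regions(self) -> frozenset[str]:
        return frozenset(self.k)

    def k_factor(self, region: str) -> float:
        try:
            return self.k[region]
        except KeyError:
            raise VocabularyError(f"unknown body region {region!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.k.items()), columns=["region", "k"])


class LARTable:
    """Sex- and age-at-exposure-specific lifetime attributable risk of cancer
    incidence, linearly interpolated in age.

    Raw entries are cases per 100,000 persons exposed to 0.1 Gy; :meth:`lar`
    returns cases per 100 persons per mSv.  Ages above the last tabulated age
    are clamped to it (the table ends at 80; cohorts reach ~100).
    """

    def __init__(self, entries: Mapping[tuple[str, str], np.ndarray], tabulated_ages: Iterable[float]):
        self.tabulated_ages = np.asarray(list(tabulated_ages), dtype=float)
        if self.tabulated_ages.ndim != 1 or len(self.tabulated_ages) < 2:
            raise ValueError("need at least two tabulated ages")
        if not np.all(np.diff(self.tabulated_ages) > 0):
            raise ValueError("tabulated ages must be strictly increasing")
        self.entries: dict[tuple[str, str], np.ndarray] = {}
        for (site, sex), values in entries.items():
            if sex not in SEXES:
                raise ValueError(f"unknown sex {sex!r}")
            v = np.asarray(values, dtype=float)
            if v.shape != self.tabulated_ages.shape:
                raise ValueError(f"{site}/{sex}: {v.size} values for {self.tabulated_ages.size} ages")
            if np.any(v < 0):
                raise ValueError(f"{site}/{sex}: negative LAR value")
            self.entries[(site, sex)] = v
        sites = self.sites
        for site in sites:
            only_sex = SEX_SPECIFIC_SITES.get(site)
            for sex in SEXES:
                present = (site, sex) in self.entries
                if only_sex is None and not present:
                    raise ValueError(f"site {site!r} missing values for {sex}")
                if only_sex is not None and present and sex != only_sex:
                    raise ValueError(f"sex-specific site {site!r} has values for {sex}")

    @property
    def sites(self) -> frozenset[str]:
        return frozenset(site for site, _ in self.entries)

    def has(self, site: str, sex: str) -> bool:
        return (site, sex) in self.entries

    def lar_many(self, site: str, sex: str, ages: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`lar`: cases per 100 persons per mSv."""
        if site not in self.sites:
            raise VocabularyError(f"unknown cancer site {site!r}")
        if (site, sex) not in self.entries:
            raise SiteSexError(f"site {site!r} does not exist for sex {sex!r}")
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < 0):
            raise ValueError("age at exposure must be >= 0")
        raw = np.interp(ages, self.tabulated_ages, self.entries[(site, sex)])
        return raw * _RAW_TO_PER100_PER_MSV

    def lar(self, site: str, sex: str, age: float) -> float:
        return float(self.lar_many(site, sex, np.asarray([age]))[0])

    def sex_averaged_lar_many(self, site: str, ages: np.ndarray) -> np.ndarray:
        """Arithmetic mean over sexes; a sex lacking the site contributes 0."""
        if site not in self.sites:
            raise VocabularyError(f"unknown cancer site {site!r}")
        ages = np.asarray(ages, dtype=float)
        total = np.zeros_like(ages, dtype=float)
        for sex in SEXES:
            if (site, sex) in self.entries:
                total = total + self.lar_many(site, sex, ages)
        return total / 2.0

    def sex_averaged_lar(self, site: str, age: float) -> float:
        return float(self.sex_averaged_lar_many(site, np.asarray([age]))[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (site, sex), values in self.entries.items():
            for age, value in zip(self.tabulated_ages, values):
                rows.append((site, sex, age, value))
        return pd.DataFrame(rows, columns=["site", "sex", "age", "value"])


@dataclass(frozen=True)
class OrganSiteMap:
    """Bridge from the monitored-organ vocabulary to BEIR VII cancer sites.

    Organs without a site-specific coefficient map to the catch-all
    ``other`` (solid) site; red bone marrow maps to ``leukemia``.
    ``remainder_organs`` flags the organs pooled into the ICRP 103 remainder
    for the effective-dose calculation.
    """

    mapping: Mapping[str, str]
    remainder_organs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.remainder_organs) - set(self.mapping)
        if unknown:
            raise ValueError(f"remainder organs outside vocabulary: {sorted(unknown)}")

    @property
    def organs(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    def site(self, organ: str) -> str:
        try:
            return self.mapping[organ]
        except KeyError:
            raise VocabularyError(f"unknown organ {organ!r}") from None

    def validate_against(self, lar_table: LARTable) -> None:
        missing = {s for s in self.mapping.values() if s not in lar_table.sites}
        if missing:
            raise ValueError(f"sites absent from the LAR table: {sorted(missing)}")

    def to_frame(self) -> pd.DataFrame:
        rows = [(o, s, int(o in self.remainder_organs)) for o, s in self.mapping.items()]
        return pd.DataFrame(rows, columns=["organ", "site", "in_remainder"])


@dataclass(frozen=True)
class ReferenceTables:
    """Bundle of the four coefficient sets used throughout the pipeline."""

    tissue_weights: TissueWeights
    dlp: DLPConversionTable
    lar: LARTable
    site_map: OrganSiteMap

    @property
    def organs(self) -> tuple[str, ...]:
        return self.site_map.organs


# ---------------------------------------------------------------------------
# loaders


def _read_csv(path: str | Path | None, name: str) -> pd.DataFrame:
    if path is None:
        path = _resource_path(name)
        _verify_checksum(path, name)
    return pd.read_csv(path)


def load_tissue_weights(path: str | Path | None = None) -> TissueWeights:
    df = _read_csv(path, "tissue_weights.csv")
    weighted = df[df["is_remainder"] == 0]
    remainder = df[df["is_remainder"] == 1]
    remainder_weights = set(remainder["weight"])
    if len(remainder_weights) != 1:
        raise ValueError("remainder rows must share a single block weight")
    return TissueWeights(
        weights=dict(zip(weighted["tissue"], weighted["weight"].astype(float))),
        remainder_members=tuple(remainder["tissue"]),
        remainder_weight=float(remainder_weights.pop()),
    )


def load_dlp_table(path: str | Path | None = None) -> DLPConversionTable:
    df = _read_csv(path, "dlp_k.csv")
    return DLPConversionTable(k=dict(zip(df["region"], df["k"].astype(float))))


def load_lar_table(path: str | Path | None = None) -> LARTable:
    df = _read_csv(path, "beir7_lar_incidence.csv")
    ages = np.sort(df["age"].unique().astype(float))
    entries: dict[tuple[str, str], np.ndarray] = {}
    for (site, sex), grp in df.groupby(["site", "sex"], sort=False):
        grp = grp.sort_values("age")
        if not np.array_equal(grp["age"].to_numpy(dtype=float), ages):
            raise ValueError(f"{site}/{sex}: age grid differs from the common grid")
        entries[(site, sex)] = grp["value"].to_numpy(dtype=float)
    return LARTable(entries, ages)


def load_organ_site_map(path: str | Path | None = None) -> OrganSiteMap:
    df = _read_csv(path, "organ_site_map.csv")
    return OrganSiteMap(
        mapping=dict(zip(df["organ"], df["site"])),
        remainder_organs=frozenset(df.loc[df["in_remainder"] == 1, "organ"]),
    )


def default_tables() -> ReferenceTables:
    """Load the packaged coefficient resources as one validated bundle."""
    tables = ReferenceTables(
        tissue_weights=load_tissue_weights(),
        dlp=load_dlp_table(),
        lar=load_lar_table(),
        site_map=load_organ_site_map(),
    )
    tables.site_map.validate_against(tables.lar)
    return tables


# ---------------------------------------------------------------------------
# thin functional wrappers


def tissue_weight(tissue: str, table: TissueWeights) -> float:
    """ICRP 103 weight w_T; remainder members get the block weight / count."""
    return table.tissue_weight(tissue)


def k_factor(region: str, table: DLPConversionTable) -> float:
    """Adult DLP conversion coefficient in mSv per mGy·cm."""
    return table.k_factor(region)


def lar(site: str, sex: str, age: float, table: LARTable) -> float:
    """LAR of cancer incidence, cases per 100 persons per mSv."""
    return table.lar(site, sex, age)


def sex_averaged_lar(site: str, age: float, table: LARTable) -> float:
    """Sex-averaged LAR; a site absent in one sex contributes 0 for that sex."""
    return table.sex_averaged_lar(site, age)
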