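"""Synthetic cohort generation and delimited-text cohort I/O.

One subject record holds sex, stature, body mass, the full 3D-scanner
measurement map (landmark heights, circumferences, cross-sectional areas,
volumes) and the six regional DEXA fat percentages. Generation is
stratified by sex and adiposity class, fully vectorized per stratum, and
byte-reproducible for a given seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import CLASSES, REGIONS, CohortConfig
from .errors import DomainError, SchemaError
from .reference import DEFAULT_PARTITIONS, SEXES, ClassPartition, FatClass

#: column order of the serialized cohort table (after the metadata columns)
MEASUREMENT_ORDER = tuple(k for k in CohortConfig().loading_table if k != "weight")

_META_COLUMNS = ("subject_id", "sex", "height", "weight", "latent_adiposity", "true_class")
_FAT_COLUMNS = tuple(f"fat_{r}" for r in REGIONS)


@dataclass
class SubjectRecord:
    """One participant: raw measurements plus regional DEXA fat percentages."""

    subject_id: str
    sex: str
    height: float  # cm
    weight: float  # kg
    measurements: dict[str, float]  # variable name -> cm / cm^2 / cm^3
    fat_pct: dict[str, float]  # region -> percent fat in tissue
    latent_adiposity: float | None = None  # simulation truth, in [0, 1]
    true_class: FatClass | None = None

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise SchemaError(f"{self.subject_id}: sex must be one of {SEXES}, got {self.sex!r}")
        if not self.height > 0:
            raise DomainError(f"{self.subject_id}: height must be > 0, got {self.height}")
        if not self.weight > 0:
            raise DomainError(f"{self.subject_id}: weight must be > 0, got {self.weight}")
        for region in REGIONS:
            pct = self.fat_pct.get(region)
            if pct is None:
                raise SchemaError(f"{self.subject_id}: missing fat percentage for region {region!r}")
            if not 0.0 <= pct <= 100.0:
                raise DomainError(
                    f"{self.subject_id}: fat_pct[{region}] must be in [0, 100], got {pct}"
                )
        missing = [v for v in MEASUREMENT_ORDER if v not in self.measurements]
        if missing:
            raise SchemaError(f"{self.subject_id}: missing measurement(s) {missing}")


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _clip_into_class(values: np.ndarray, partition: ClassPartition, cls: FatClass) -> np.ndarray:
    """Clip fat percentages into the (low, high] interval of a class."""
    lo, hi = partition.interval(cls)
    lo = np.nextafter(lo, np.inf) if cls is not FatClass.A else 0.0
    return np.clip(values, lo, hi)


def generate_cohort(config: CohortConfig | None = None) -> list[SubjectRecord]:
    """Draw a stratified synthetic cohort; deterministic for a given seed.

    Per stratum (sex x class), latent adiposity is uniform within the
    class's latent interval; every measurement and regional fat percentage
    follows its linear link plus Gaussian noise; regional fat percentages
    are then clipped into the stratum's class interval so the stratum
    label is honored by construction.
    """
    config = config if config is not None else CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    cohort: list[SubjectRecord] = []
    var_names = list(config.loading_table)
    for sex in SEXES:
        partition = DEFAULT_PARTITIONS[sex]
        counter = 0
        for cls_name in CLASSES:
            cls = FatClass[cls_name]
            n = config.strata_counts[sex][cls_name]
            if n == 0:
                continue
            lo, hi = config.adiposity_ranges[sex][cls_name]
            a = rng.uniform(lo, hi, size=n)
            hmin, hmax = config.height_range_cm[sex]
            heights = _truncated_normal(
                rng, config.height_mean_cm[sex], config.height_sd_cm[sex], hmin, hmax, n
            )
            values = {}
            for name in var_names:
                load = config.loading_table[name]
                values[name] = (
                    load.intercept[sex] + load.slope * a + rng.normal(0.0, load.noise_sd, size=n)
                )
            fat = {}
            for region in REGIONS:
                link = config.fat_link[region]
                raw = link.intercept[sex] + link.slope * a + rng.normal(0.0, link.noise_sd, size=n)
                fat[region] = _clip_into_class(raw, partition, cls)
            for i in range(n):
                counter += 1
                record = SubjectRecord(
                    subject_id=f"{sex[0].upper()}{counter:03d}",
                    sex=sex,
                    height=float(heights[i]),
                    weight=float(values["weight"][i]),
                    measurements={
                        name: float(values[name][i]) for name in var_names if name != "weight"
                    },
                    fat_pct={region: float(fat[region][i]) for region in REGIONS},
                    latent_adiposity=float(a[i]),
                    true_class=cls,
                )
                record.validate()
                cohort.append(record)
    return cohort


# ---------------------------------------------------------------------------
# delimited-text round trip


def cohort_to_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    if not cohort:
        raise DomainError("cannot serialize an empty cohort")
    rows = []
    for rec in cohort:
        rec.validate()
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "sex": rec.sex,
            "height": rec.height,
            "weight": rec.weight,
            "latent_adiposity": rec.latent_adiposity,
            "true_class": str(rec.true_class) if rec.true_class is not None else "",
        }
        row.update({f"fat_{r}": rec.fat_pct[r] for r in REGIONS})
        row.update({v: rec.measurements[v] for v in MEASUREMENT_ORDER})
        rows.append(row)
    columns = list(_META_COLUMNS) + list(_FAT_COLUMNS) + list(MEASUREMENT_ORDER)
    return pd.DataFrame(rows, columns=columns)


def cohort_to_table(cohort: list[SubjectRecord]) -> str:
    """Serialize a cohort as comma-delimited text (header + one row per
    subject); floats use shortest-repr formatting, so the round trip
    through :func:`read_cohort` is lossless."""
    return cohort_to_frame(cohort).to_csv(index=False)


def write_cohort(cohort: list[SubjectRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(cohort_to_table(cohort))


def frame_to_cohort(frame: pd.DataFrame) -> list[SubjectRecord]:
    required = set(_META_COLUMNS[:4]) | set(_FAT_COLUMNS) | set(MEASUREMENT_ORDER)
    missing = sorted(required - set(frame.columns))
    if missing:
        raise SchemaError(f"cohort table missing column(s): {missing}")
    cohort = []
    for _, row in frame.iterrows():
        latent = row.get("latent_adiposity")
        true_cls = row.get("true_class")
        rec = SubjectRecord(
            subject_id=str(row["subject_id"]),
            sex=str(row["sex"]),
            height=float(row["height"]),
            weight=float(row["weight"]),
            measurements={v: float(row[v]) for v in MEASUREMENT_ORDER},
            fat_pct={r: float(row[f"fat_{r}"]) for r in REGIONS},
            latent_adiposity=None if pd.isna(latent) else float(latent),
            true_class=(
                None if true_cls is None or pd.isna(true_cls) or str(true_cls) == ""
                else FatClass.from_label(str(true_cls))
            ),
        )
        rec.validate()
        cohort.append(rec)
    return cohort


def read_cohort(path_or_buffer) -> list[SubjectRecord]:
    """Read a cohort table written by :func:`write_cohort` (or any table
    with the same schema); raises SchemaError on missing columns."""
    if isinstance(path_or_buffer, str) and "\n" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    frame = pd.read_csv(path_or_buffer)
    return frame_to_cohort(frame)
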