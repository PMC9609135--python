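"""From raw subject records to the four per-part analysis datasets.

The analysis assumes body values scale linearly with stature, so every
body value (weight included) is divided by the subject's height; stature
itself is kept on its raw scale, since a height/height column would be a
constant. Absolute landmark heights that only serve length derivation
(shoulder, chest, waist and hip heights) are replaced by the four derived
lengths before normalization.

Each sex yields four datasets — chest, abdomen, hips and a pooled
arms/legs set (arm circumference correlates at r >= 0.9 with the leg
variables, so the limbs are analysed together). Per-part class labels
come from the regional DEXA fat percentage graded on the whole-body
partition; the pooled arms/legs label uses the mean of the arm and leg
tissue percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .errors import DomainError, SchemaError
from .reference import DEFAULT_PARTITIONS, SEXES, ClassPartition, FatClass, fat_class

PARTS = ("chest", "abdomen", "hips", "arms_legs")

#: derived length -> (upper landmark height, lower landmark height)
LENGTH_DEFINITIONS: Mapping[str, tuple[str, str]] = {
    "chest_length": ("shoulder_height", "chest_height"),
    "waist_length": ("waist_height", "hip_height"),
    "hip_length": ("hip_height", "groin_height"),
    "thigh_length": ("hip_height", "knee_height"),
}

#: absolute heights consumed by length derivation and absent from all
#: per-part variable sets (groin/knee/calf heights remain as variables)
_DROPPED_HEIGHTS = ("shoulder_height", "chest_height", "waist_height", "hip_height")

#: per-part analysis variables, in column order
PART_VARIABLES: Mapping[str, tuple[str, ...]] = {
    "chest": (
        "height", "weight", "chest_length", "shoulder_area", "chest_area",
        "breast_area", "shoulder_volume", "chest_volume",
    ),
    "abdomen": (
        "height", "weight", "waist_length", "waist_circumference",
        "navel_waist_circumference", "lower_navel_circumference", "waist_area",
        "navel_waist_area", "lower_navel_area", "upper_abdominal_volume",
        "lower_abdominal_volume",
    ),
    "hips": (
        "height", "weight", "hip_length", "hip_circumference",
        "groin_circumference", "hip_area", "groin_area",
    ),
    "arms_legs": (
        "height", "weight", "groin_height", "thigh_length", "knee_height",
        "calf_height", "thick_thigh_circumference", "mid_thigh_circumference",
        "knee_circumference", "calf_circumference", "thick_thigh_area",
        "mid_thigh_area", "knee_area", "calf_area", "arm_circumference",
    ),
}

#: DEXA region supplying each part's class label
PART_REGION = {"chest": "chest", "abdomen": "abdomen", "hips": "hip"}

LEG_CIRCUMFERENCE_VARIABLES = (
    "thick_thigh_circumference",
    "mid_thigh_circumference",
    "knee_circumference",
    "calf_circumference",
)


class HeightNormalized(dict):
    """Measurement map divided by height exactly once (unit tag 'per_cm';
    the raw 'height' entry keeps its cm scale)."""

    units = "per_cm"


@dataclass
class PartDataset:
    """Per-part, per-sex matrix of height-normalized analysis variables
    with one fat-class label per subject."""

    part: str
    sex: str
    variable_names: tuple[str, ...]
    matrix: np.ndarray  # subjects x variables
    labels: list[FatClass]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, p = self.matrix.shape
        if p != len(self.variable_names):
            raise SchemaError(
                f"{self.part}/{self.sex}: matrix has {p} columns for "
                f"{len(self.variable_names)} variables"
            )
        if n != len(self.labels) or n != len(self.subject_ids):
            raise SchemaError(f"{self.part}/{self.sex}: rows, labels and ids misaligned")
        if not np.all(np.isfinite(self.matrix)):
            raise DomainError(f"{self.part}/{self.sex}: non-finite normalized values")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.matrix, columns=list(self.variable_names))
        frame.insert(0, "subject_id", self.subject_ids)
        frame["fat_class"] = [str(c) for c in self.labels]
        return frame


def derive_lengths(measurements: Mapping[str, float]) -> dict[str, float]:
    """Add the four derived lengths and drop the absolute heights they
    replace; raises on any anatomically impossible (non-positive) length."""
    out = dict(measurements)
    for length, (upper, lower) in LENGTH_DEFINITIONS.items():
        for key in (upper, lower):
            if key not in out:
                raise SchemaError(f"cannot derive {length}: missing {key}")
        value = out[upper] - out[lower]
        if value <= 0:
            raise DomainError(
                f"anatomical ordering violated: {length} = {upper} - {lower} = {value:g} <= 0"
            )
        out[length] = value
    for key in _DROPPED_HEIGHTS:
        out.pop(key, None)
    return out


def normalize_by_height(record: SubjectRecord) -> HeightNormalized:
    """Divide every body value (weight included) by the subject's height.

    Stature stays raw under the 'height' key. Applying the function to a
    record whose measurements already carry the per-cm tag is an error:
    normalization must happen exactly once.
    """
    if getattr(record.measurements, "units", None) == "per_cm":
        raise SchemaError(f"{record.subject_id}: measurements are already height-normalized")
    if not record.height > 0:
        raise DomainError(f"{record.subject_id}: height must be > 0, got {record.height}")
    out = HeightNormalized()
    out["height"] = record.height
    out["weight"] = record.weight / record.height
    for name, value in record.measurements.items():
        out[name] = value / record.height
    return out


def part_label(
    record: SubjectRecord, part: str, partition: ClassPartition | None = None
) -> FatClass:
    """Fat class of one body part from its regional DEXA percentage; the
    pooled arms/legs part uses the mean of arm and leg tissue percentages."""
    if part == "arms_legs":
        pct = (record.fat_pct["arm"] + record.fat_pct["leg"]) / 2.0
    else:
        pct = record.fat_pct[PART_REGION[part]]
    return fat_class(pct, record.sex, partition)


def normalize_record(record: SubjectRecord) -> HeightNormalized:
    """Full per-record preprocessing: length derivation then height
    normalization (the projection-ready variable map)."""
    derived = derive_lengths(record.measurements)
    staged = SubjectRecord(
        subject_id=record.subject_id,
        sex=record.sex,
        height=record.height,
        weight=record.weight,
        measurements=derived,
        fat_pct=record.fat_pct,
        latent_adiposity=record.latent_adiposity,
        true_class=record.true_class,
    )
    return normalize_by_height(staged)


def build_part_datasets(
    cohort: Iterable[SubjectRecord],
    partition_by_sex: Mapping[str, ClassPartition] | None = None,
) -> dict[tuple[str, str], PartDataset]:
    """Assemble the eight analysis datasets (4 parts x 2 sexes present).

    Every subject appears exactly once in each of its sex's four part
    datasets; variables follow the per-part catalogue order.
    """
    cohort = list(cohort)
    if not cohort:
        raise DomainError("cannot build part datasets from an empty cohort")
    partitions = partition_by_sex if partition_by_sex is not None else DEFAULT_PARTITIONS
    rows: dict[tuple[str, str], list[np.ndarray]] = {}
    labels: dict[tuple[str, str], list[FatClass]] = {}
    ids: dict[tuple[str, str], list[str]] = {}
    for record in cohort:
        normalized = normalize_record(record)
        for part in PARTS:
            key = (record.sex, part)
            try:
                vector = np.array([normalized[v] for v in PART_VARIABLES[part]])
            except KeyError as exc:
                raise SchemaError(
                    f"{record.subject_id}: missing variable {exc.args[0]!r} for part {part!r}"
                ) from None
            rows.setdefault(key, []).append(vector)
            labels.setdefault(key, []).append(part_label(record, part, partitions[record.sex]))
            ids.setdefault(key, []).append(record.subject_id)
    return {
        key: PartDataset(
            part=key[1],
            sex=key[0],
            variable_names=PART_VARIABLES[key[1]],
            matrix=np.vstack(rows[key]),
            labels=labels[key],
            subject_ids=ids[key],
        )
        for key in rows
    }


def arm_leg_correlation(cohort: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Pearson correlation matrix of the height-normalized arm
    circumference with the four leg circumference variables.

    The off-diagonal arm row justifies pooling arms and legs into one
    dataset when all entries reach 0.9.
    """
    cohort = list(cohort)
    if len(cohort) < 3:
        raise DomainError("need at least 3 subjects for a correlation estimate")
    names = ("arm_circumference",) + LEG_CIRCUMFERENCE_VARIABLES
    columns = {name: [] for name in names}
    for record in cohort:
        normalized = normalize_by_height(record)
        for name in names:
            columns[name].append(normalized[name])
    frame = pd.DataFrame(columns)
    degenerate = [name for name in names if np.std(frame[name].to_numpy()) == 0]
    if degenerate:
        raise DomainError(f"correlation undefined for zero-variance variable(s): {degenerate}")
    return frame.corr(method="pearson")


def min_arm_leg_correlation(cohort: Iterable[SubjectRecord]) -> float:
    """Smallest correlation between arm circumference and a leg variable."""
    corr = arm_leg_correlation(cohort)
    return float(corr.loc["arm_circumference", list(LEG_CIRCUMFERENCE_VARIABLES)].min())
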