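"""Ground-truth fat-class partition and comparator obesity indices.

Whole-body obesity is graded into four ordered classes from the DEXA total
fat percentage, using sex-specific cut points:

================  ==============  ==============
class             men             women
================  ==============  ==============
A (underweight)   <= 8 %          <= 14 %
B (normal)        (8, 18.6] %     (14, 22.7] %
C (overweight)    (18.6, 23.1] %  (22.7, 27.1] %
D (obese)         > 23.1 %        > 27.1 %
================  ==============  ==============

The bottom class is left-closed ("8% or less"); every other boundary is
upper-inclusive so the partition covers [0, 100] monotonically with no gaps.
The same partition grades each regional (per-body-part) fat percentage.

Comparator indices — BMI (kg/m^2), waist-to-height ratio and waist-to-hip
ratio — are mapped onto the same A-D scale through configurable cut points.
The shipped defaults (Asian-Pacific BMI bands, common WHtR/WHR screening
bands) are documentation defaults only: validation against the printed
10-sample table uses that table's own index classes, never these defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

from .errors import ConfigError, DomainError

SEXES = ("male", "female")

_WORD_TO_LETTER = {
    "underweight": "A",
    "normal": "B",
    "overweight": "C",
    "obese": "D",
    "obesity": "D",
}


class FatClass(IntEnum):
    """Ordered obesity class: A (underweight) < B < C < D (obese)."""

    A = 1
    B = 2
    C = 3
    D = 4

    @classmethod
    def from_label(cls, label: str) -> "FatClass":
        """Parse 'A'..'D' or the words underweight/normal/overweight/obese."""
        key = str(label).strip()
        if key.lower() in _WORD_TO_LETTER:
            key = _WORD_TO_LETTER[key.lower()]
        try:
            return cls[key.upper()]
        except KeyError:
            raise DomainError(f"unknown fat class label: {label!r}") from None

    def __str__(self) -> str:  # serialize as the letter
        return self.name


@dataclass(frozen=True)
class ClassPartition:
    """Sex-specific fat-percentage cut points defining classes A-D."""

    sex: str
    cut1: float
    cut2: float
    cut3: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigError(f"ClassPartition.sex must be one of {SEXES}, got {self.sex!r}")
        if not (0.0 < self.cut1 < self.cut2 < self.cut3 < 100.0):
            raise ConfigError(
                "ClassPartition cut points must satisfy 0 < cut1 < cut2 < cut3 < 100, "
                f"got ({self.cut1}, {self.cut2}, {self.cut3})"
            )

    @property
    def cuts(self) -> tuple[float, float, float]:
        return (self.cut1, self.cut2, self.cut3)

    def classify(self, fat_pct: float) -> FatClass:
        if not 0.0 <= fat_pct <= 100.0:
            raise DomainError(f"fat percentage must be in [0, 100], got {fat_pct}")
        if fat_pct <= self.cut1:
            return FatClass.A
        if fat_pct <= self.cut2:
            return FatClass.B
        if fat_pct <= self.cut3:
            return FatClass.C
        return FatClass.D

    def interval(self, cls: FatClass) -> tuple[float, float]:
        """(low, high] bounds of a class; class A is [0, cut1]."""
        bounds = (0.0, self.cut1, self.cut2, self.cut3, 100.0)
        return bounds[cls - 1], bounds[cls]


DEFAULT_PARTITIONS: Mapping[str, ClassPartition] = {
    "male": ClassPartition("male", 8.0, 18.6, 23.1),
    "female": ClassPartition("female", 14.0, 22.7, 27.1),
}


def fat_class(fat_pct: float, sex: str, partition: ClassPartition | None = None) -> FatClass:
    """Grade a fat percentage into class A-D for the given sex."""
    if partition is None:
        try:
            partition = DEFAULT_PARTITIONS[sex]
        except KeyError:
            raise DomainError(f"sex must be one of {SEXES}, got {sex!r}") from None
    return partition.classify(fat_pct)


def bmi(height_cm: float, weight_kg: float) -> float:
    """Body mass index, weight / (height in m)^2."""
    if height_cm <= 0:
        raise DomainError(f"height must be positive, got {height_cm}")
    if weight_kg <= 0:
        raise DomainError(f"weight must be positive, got {weight_kg}")
    return weight_kg / (height_cm / 100.0) ** 2


def whtr(waist_circ_cm: float, height_cm: float) -> float:
    """Waist-to-height ratio."""
    if waist_circ_cm <= 0 or height_cm <= 0:
        raise DomainError("waist circumference and height must be positive")
    return waist_circ_cm / height_cm


def whr(waist_circ_cm: float, hip_circ_cm: float) -> float:
    """Waist-to-hip circumference ratio."""
    if waist_circ_cm <= 0 or hip_circ_cm <= 0:
        raise DomainError("waist and hip circumferences must be positive")
    return waist_circ_cm / hip_circ_cm


@dataclass(frozen=True)
class IndexThresholds:
    """Three ascending cut points per (index, sex) mapping an index value
    to A-D with the same boundary convention as the fat partition."""

    cutpoints: Mapping[str, Mapping[str, tuple[float, float, float]]]

    def __post_init__(self) -> None:
        for index, per_sex in self.cutpoints.items():
            for sex, cuts in per_sex.items():
                if sex not in SEXES:
                    raise ConfigError(f"IndexThresholds[{index}]: unknown sex {sex!r}")
                if not (cuts[0] < cuts[1] < cuts[2]):
                    raise ConfigError(
                        f"IndexThresholds[{index}][{sex}] must be strictly ascending, got {cuts}"
                    )

    def classify(self, value: float, index_name: str, sex: str) -> FatClass:
        try:
            cuts = self.cutpoints[index_name][sex]
        except KeyError:
            raise DomainError(
                f"no thresholds for index {index_name!r} and sex {sex!r}"
            ) from None
        if value <= cuts[0]:
            return FatClass.A
        if value <= cuts[1]:
            return FatClass.B
        if value <= cuts[2]:
            return FatClass.C
        return FatClass.D


DEFAULT_INDEX_THRESHOLDS = IndexThresholds(
    {
        "bmi": {"male": (18.5, 23.0, 25.0), "female": (18.5, 23.0, 25.0)},
        "whtr": {"male": (0.40, 0.50, 0.57), "female": (0.40, 0.50, 0.57)},
        "whr": {"male": (0.85, 0.90, 0.95), "female": (0.80, 0.85, 0.90)},
    }
)


def index_class(
    value: float,
    index_name: str,
    sex: str,
    thresholds: IndexThresholds | None = None,
) -> FatClass:
    """Grade an obesity-index value (BMI, WHtR or WHR) into class A-D."""
    thresholds = thresholds if thresholds is not None else DEFAULT_INDEX_THRESHOLDS
    return thresholds.classify(value, index_name.lower(), sex)
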