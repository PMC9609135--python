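"""Configuration of the synthetic-cohort generator.

The generator emulates the study population: 170 young adults (87 men,
73 women) stratified into four adiposity classes per sex. A single latent
adiposity factor ``a`` in [0, 1] drives every fat-linked measurement
(circumferences, cross-sectional areas, volumes, weight) linearly:

    value = intercept(sex) + slope * a + Gaussian noise

Skeletal landmark heights carry zero slope (they are stature, not fat).
Regional DEXA fat percentages follow the same linear-link form and are
finally clipped into the fat-percentage interval of the subject's stratum
so the stratum label is always honored.

Default latent-class breakpoints are the exact preimages of the sex-specific
fat-percentage cut points under the total-fat link, so with zero noise the
generated total fat percentage lands inside its class interval without any
clipping and class recovery from the fat partition is exact.

All configuration is plain data and can round-trip through a YAML file.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigError
from .reference import DEFAULT_PARTITIONS, SEXES

CLASSES = ("A", "B", "C", "D")
REGIONS = ("chest", "abdomen", "hip", "arm", "leg", "total")


@dataclass(frozen=True)
class VariableLoading:
    """Linear link of one measurement to latent adiposity.

    intercept: per-sex value at zero adiposity (cm, cm^2, cm^3 or kg);
    slope: increase over the full adiposity range (same unit);
    noise_sd: additive Gaussian measurement/biological noise (same unit).
    """

    intercept: Mapping[str, float]
    slope: float
    noise_sd: float


# Measurement catalogue: every variable required by the four per-part
# analysis sets, plus the raw landmark heights consumed by length
# derivation. Units: heights/circumferences cm, areas cm^2, volumes cm^3,
# weight kg. Intercepts are the lean (a=0) values; slopes span a in [0,1].
DEFAULT_LOADINGS: dict[str, VariableLoading] = {
    # skeletal landmark heights (stature, not adiposity-driven)
    "shoulder_height": VariableLoading({"male": 139.0, "female": 134.0}, 0.0, 0.25),
    "chest_height": VariableLoading({"male": 123.0, "female": 118.5}, 0.0, 0.25),
    "waist_height": VariableLoading({"male": 103.0, "female": 99.5}, 0.0, 0.25),
    "hip_height": VariableLoading({"male": 86.0, "female": 83.0}, 0.0, 0.25),
    "groin_height": VariableLoading({"male": 78.0, "female": 75.0}, 0.0, 0.25),
    "knee_height": VariableLoading({"male": 46.0, "female": 44.0}, 0.0, 0.25),
    "calf_height": VariableLoading({"male": 34.0, "female": 33.0}, 0.0, 0.25),
    # circumferences
    "waist_circumference": VariableLoading({"male": 68.0, "female": 60.0}, 44.0, 0.8),
    "navel_waist_circumference": VariableLoading({"male": 70.0, "female": 62.0}, 46.0, 0.8),
    "lower_navel_circumference": VariableLoading({"male": 72.0, "female": 64.0}, 44.0, 0.8),
    "hip_circumference": VariableLoading({"male": 88.0, "female": 86.0}, 30.0, 0.8),
    "groin_circumference": VariableLoading({"male": 56.0, "female": 54.0}, 22.0, 0.7),
    "thick_thigh_circumference": VariableLoading({"male": 50.0, "female": 48.0}, 20.0, 0.6),
    "mid_thigh_circumference": VariableLoading({"male": 45.0, "female": 43.0}, 18.0, 0.6),
    "knee_circumference": VariableLoading({"male": 35.0, "female": 34.0}, 10.0, 0.5),
    "calf_circumference": VariableLoading({"male": 33.0, "female": 32.0}, 10.0, 0.5),
    "arm_circumference": VariableLoading({"male": 26.0, "female": 24.0}, 12.0, 0.5),
    # cross-sectional areas
    "shoulder_area": VariableLoading({"male": 380.0, "female": 330.0}, 260.0, 9.0),
    "chest_area": VariableLoading({"male": 350.0, "female": 310.0}, 250.0, 9.0),
    "breast_area": VariableLoading({"male": 360.0, "female": 330.0}, 255.0, 9.0),
    "waist_area": VariableLoading({"male": 330.0, "female": 280.0}, 320.0, 10.0),
    "navel_waist_area": VariableLoading({"male": 350.0, "female": 300.0}, 340.0, 10.0),
    "lower_navel_area": VariableLoading({"male": 370.0, "female": 320.0}, 330.0, 10.0),
    "hip_area": VariableLoading({"male": 500.0, "female": 480.0}, 280.0, 10.0),
    "groin_area": VariableLoading({"male": 330.0, "female": 315.0}, 180.0, 9.0),
    "thick_thigh_area": VariableLoading({"male": 190.0, "female": 180.0}, 120.0, 6.0),
    "mid_thigh_area": VariableLoading({"male": 155.0, "female": 148.0}, 100.0, 5.0),
    "knee_area": VariableLoading({"male": 95.0, "female": 90.0}, 45.0, 4.0),
    "calf_area": VariableLoading({"male": 85.0, "female": 80.0}, 40.0, 4.0),
    # volumes
    "shoulder_volume": VariableLoading({"male": 6000.0, "female": 5200.0}, 4000.0, 130.0),
    "chest_volume": VariableLoading({"male": 9000.0, "female": 7800.0}, 6200.0, 150.0),
    "upper_abdominal_volume": VariableLoading({"male": 8000.0, "female": 6800.0}, 6600.0, 150.0),
    "lower_abdominal_volume": VariableLoading({"male": 9000.0, "female": 7600.0}, 7000.0, 150.0),
    # body mass (kg); treated as a body value like any other
    "weight": VariableLoading({"male": 55.0, "female": 45.0}, 32.0, 1.0),
}

# Regional DEXA fat-percentage links. The total link maps the latent class
# breakpoints exactly onto the sex-specific fat cut points; regional links
# deviate mildly (android slightly steeper, gynoid higher in women, limbs
# leaner) and rely on clipping at class boundaries.
DEFAULT_FAT_LINK: dict[str, VariableLoading] = {
    "total": VariableLoading({"male": 4.0, "female": 8.0}, 26.0, 0.8),
    "chest": VariableLoading({"male": 3.0, "female": 7.0}, 26.0, 1.0),
    "abdomen": VariableLoading({"male": 5.5, "female": 9.5}, 28.0, 1.0),
    "hip": VariableLoading({"male": 5.0, "female": 11.0}, 26.0, 1.0),
    "arm": VariableLoading({"male": 2.0, "female": 6.0}, 24.0, 1.0),
    "leg": VariableLoading({"male": 3.0, "female": 7.0}, 25.0, 1.0),
}


def adiposity_ranges_from_link(
    link: VariableLoading | None = None,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Latent class intervals whose images under the total-fat link are
    exactly the Table-style fat-percentage class intervals, per sex."""
    link = link if link is not None else DEFAULT_FAT_LINK["total"]
    ranges: dict[str, dict[str, tuple[float, float]]] = {}
    for sex in SEXES:
        cuts = DEFAULT_PARTITIONS[sex].cuts
        b = [0.0] + [(c - link.intercept[sex]) / link.slope for c in cuts] + [1.0]
        if not all(b[i] < b[i + 1] for i in range(4)):
            raise ConfigError(f"fat link for {sex} yields non-increasing latent breakpoints {b}")
        ranges[sex] = {cls: (b[i], b[i + 1]) for i, cls in enumerate(CLASSES)}
    return ranges


def _default_strata() -> dict[str, dict[str, int]]:
    return {
        "male": {"A": 20, "B": 24, "C": 23, "D": 20},
        "female": {"A": 20, "B": 20, "C": 18, "D": 15},
    }


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort (seeded, deterministic)."""

    strata_counts: dict[str, dict[str, int]] = field(default_factory=_default_strata)
    height_mean_cm: dict[str, float] = field(
        default_factory=lambda: {"male": 169.15, "female": 162.8}
    )
    height_sd_cm: dict[str, float] = field(default_factory=lambda: {"male": 6.0, "female": 5.0})
    height_range_cm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (161.0, 197.0), "female": (151.0, 175.7)}
    )
    adiposity_ranges: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=adiposity_ranges_from_link
    )
    loading_table: dict[str, VariableLoading] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS)
    )
    fat_link: dict[str, VariableLoading] = field(default_factory=lambda: dict(DEFAULT_FAT_LINK))
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for sex in SEXES:
            if sex not in self.strata_counts:
                raise ConfigError(f"strata_counts missing sex {sex!r}")
            for cls in CLASSES:
                n = self.strata_counts[sex].get(cls)
                if not isinstance(n, int) or n < 0:
                    raise ConfigError(f"strata_counts[{sex}][{cls}] must be a non-negative int, got {n!r}")
            if self.height_sd_cm[sex] < 0:
                raise ConfigError(f"height_sd_cm[{sex}] must be >= 0")
            lo, hi = self.height_range_cm[sex]
            if not lo < hi:
                raise ConfigError(f"height_range_cm[{sex}] must be an increasing interval")
            self._validate_ranges(sex)
        for name, load in self.loading_table.items():
            if load.noise_sd < 0:
                raise ConfigError(f"loading_table[{name}].noise_sd must be >= 0")
            for sex in SEXES:
                if sex not in load.intercept:
                    raise ConfigError(f"loading_table[{name}].intercept missing sex {sex!r}")
        for region in REGIONS:
            if region not in self.fat_link:
                raise ConfigError(f"fat_link missing region {region!r}")
            if self.fat_link[region].noise_sd < 0:
                raise ConfigError(f"fat_link[{region}].noise_sd must be >= 0")

    def _validate_ranges(self, sex: str) -> None:
        ranges = self.adiposity_ranges.get(sex)
        if ranges is None:
            raise ConfigError(f"adiposity_ranges missing sex {sex!r}")
        prev_hi = 0.0
        for cls in CLASSES:
            if cls not in ranges:
                raise ConfigError(f"adiposity_ranges[{sex}] missing class {cls!r}")
            lo, hi = ranges[cls]
            if not (abs(lo - prev_hi) < 1e-12 and lo < hi):
                raise ConfigError(
                    f"adiposity_ranges[{sex}] must be disjoint, ordered A<B<C<D and "
                    f"cover [0,1]; class {cls} starts at {lo}, expected {prev_hi}"
                )
            prev_hi = hi
        if abs(prev_hi - 1.0) > 1e-12:
            raise ConfigError(f"adiposity_ranges[{sex}] must end at 1.0, got {prev_hi}")

    # -- derived configs ----------------------------------------------------

    def noise_free(self) -> "CohortConfig":
        """Copy with every measurement and fat-link noise sd set to zero.

        Population spread (height sd, the latent adiposity draw) is kept:
        it is structure, not noise.
        """
        cfg = copy.deepcopy(self)
        cfg.loading_table = {
            k: dataclasses.replace(v, noise_sd=0.0) for k, v in cfg.loading_table.items()
        }
        cfg.fat_link = {
            k: dataclasses.replace(v, noise_sd=0.0) for k, v in cfg.fat_link.items()
        }
        return cfg

    def with_seed(self, seed: int) -> "CohortConfig":
        cfg = copy.deepcopy(self)
        cfg.seed = int(seed)
        return cfg

    @property
    def n_subjects(self) -> int:
        return sum(sum(per.values()) for per in self.strata_counts.values())

    # -- YAML round-trip -----------------------------------------------------

    _FIELDS = (
        "strata_counts",
        "height_mean_cm",
        "height_sd_cm",
        "height_range_cm",
        "adiposity_ranges",
        "loading_table",
        "fat_link",
        "seed",
    )

    def to_dict(self) -> dict:
        def link_out(link: VariableLoading) -> dict:
            return {
                "intercept": dict(link.intercept),
                "slope": link.slope,
                "noise_sd": link.noise_sd,
            }

        return {
            "strata_counts": {s: dict(c) for s, c in self.strata_counts.items()},
            "height_mean_cm": dict(self.height_mean_cm),
            "height_sd_cm": dict(self.height_sd_cm),
            "height_range_cm": {s: list(r) for s, r in self.height_range_cm.items()},
            "adiposity_ranges": {
                s: {c: list(r) for c, r in per.items()} for s, per in self.adiposity_ranges.items()
            },
            "loading_table": {k: link_out(v) for k, v in self.loading_table.items()},
            "fat_link": {k: link_out(v) for k, v in self.fat_link.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        unknown = set(data) - set(cls._FIELDS)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")

        def link_in(raw: Mapping, where: str) -> VariableLoading:
            extra = set(raw) - {"intercept", "slope", "noise_sd"}
            if extra:
                raise ConfigError(f"unknown key(s) {sorted(extra)} in {where}")
            return VariableLoading(
                {s: float(v) for s, v in raw["intercept"].items()},
                float(raw["slope"]),
                float(raw["noise_sd"]),
            )

        cfg = cls()
        if "strata_counts" in data:
            cfg.strata_counts = {s: {c: int(n) for c, n in per.items()} for s, per in data["strata_counts"].items()}
        for key in ("height_mean_cm", "height_sd_cm"):
            if key in data:
                setattr(cfg, key, {s: float(v) for s, v in data[key].items()})
        if "height_range_cm" in data:
            cfg.height_range_cm = {s: (float(r[0]), float(r[1])) for s, r in data["height_range_cm"].items()}
        if "adiposity_ranges" in data:
            cfg.adiposity_ranges = {
                s: {c: (float(r[0]), float(r[1])) for c, r in per.items()}
                for s, per in data["adiposity_ranges"].items()
            }
        if "loading_table" in data:
            table = dict(DEFAULT_LOADINGS)
            table.update(
                {k: link_in(v, f"loading_table[{k}]") for k, v in data["loading_table"].items()}
            )
            cfg.loading_table = table
        if "fat_link" in data:
            links = dict(DEFAULT_FAT_LINK)
            links.update({k: link_in(v, f"fat_link[{k}]") for k, v in data["fat_link"].items()})
            cfg.fat_link = links
        if "seed" in data:
            cfg.seed = int(data["seed"])
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError(f"configuration file {path} does not contain a mapping")
        return cls.from_dict(data)
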