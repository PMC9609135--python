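"""Part-level class assignment and whole-body fusion.

Each body part is classified by the nearest labeled training point
(1-NN, Euclidean distance) in that part's Comp1-Comp2 plane; exact
distance ties break toward the higher class. The four part classes are
then fused into the whole-body diagnosis:

1. a matching exception pattern (sex-specific, in table order) wins;
2. otherwise a class held by at least three parts wins (majority);
3. otherwise a 2-2 split resolves to the higher of the two classes;
4. otherwise the duplicated class of a 2-1-1 split wins (plurality).

When all four parts disagree (not covered by the stated rules), the tie
rule is generalized: among the maximal-count classes, the highest wins.

Exception patterns ship as data (a packaged delimited-text table), not
code: the tabulated special groups are not exhaustive and users may
extend them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .errors import DomainError, SchemaError
from .pca import PartPCAModel
from .preprocess import PARTS, normalize_record
from .reference import SEXES, FatClass

_RULE_COLUMNS = ("sex", "chest", "abdomen", "hips", "arms_legs", "outcome")


@dataclass(frozen=True)
class PartClassResult:
    part: str
    assigned_class: FatClass
    nearest_subject_id: str
    distance: float

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise DomainError("distance must be non-negative")


@dataclass(frozen=True)
class ExceptionRule:
    """One tabulated special-case pattern: a class set per part (a single
    letter or a 'B~C' range) and the overriding outcome class."""

    sex: str
    pattern: tuple[frozenset, ...]  # chest, abdomen, hips, arms_legs
    outcome: FatClass

    def matches(self, sex: str, part_classes: Mapping[str, FatClass]) -> bool:
        if sex != self.sex:
            return False
        return all(part_classes[part] in cls_set for part, cls_set in zip(PARTS, self.pattern))


@dataclass
class DiagnosisResult:
    subject_id: str | None
    part_classes: dict[str, FatClass]
    fused_class: FatClass
    rule_applied: str  # exception | majority | tie_higher | plurality
    part_results: dict[str, PartClassResult] = field(default_factory=dict)


def _parse_class_set(token: str) -> frozenset:
    token = token.strip()
    if "~" in token:
        lo_s, hi_s = token.split("~", 1)
        lo, hi = FatClass.from_label(lo_s), FatClass.from_label(hi_s)
        if lo > hi:
            raise SchemaError(f"descending class range: {token!r}")
        return frozenset(FatClass(v) for v in range(int(lo), int(hi) + 1))
    return frozenset({FatClass.from_label(token)})


def parse_exception_rules(frame: pd.DataFrame) -> list[ExceptionRule]:
    missing = [c for c in _RULE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"exception rule table missing column(s): {missing}")
    rules = []
    for _, row in frame.iterrows():
        sex = str(row["sex"]).strip().lower()
        if sex not in SEXES:
            raise SchemaError(f"exception rule with unknown sex {row['sex']!r}")
        rules.append(
            ExceptionRule(
                sex=sex,
                pattern=tuple(_parse_class_set(str(row[part])) for part in PARTS),
                outcome=FatClass.from_label(str(row["outcome"])),
            )
        )
    return rules


def load_exception_rules(path=None) -> list[ExceptionRule]:
    """Read exception rules from a delimited-text file; with no path, the
    packaged default table (the published special-group patterns)."""
    if path is None:
        source = resources.files("adiposcan.data").joinpath("exception_rules.csv")
        with resources.as_file(source) as fp:
            frame = pd.read_csv(fp)
    else:
        frame = pd.read_csv(path)
    return parse_exception_rules(frame)


_DEFAULT_RULES: list[ExceptionRule] | None = None


def default_exception_rules() -> list[ExceptionRule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_exception_rules()
    return _DEFAULT_RULES


def assign_part_class(
    model: PartPCAModel, point: tuple[float, float]
) -> PartClassResult:
    """Class of the Euclidean-nearest labeled training point in the
    Comp1-Comp2 plane; exact distance ties break toward the higher class."""
    if model.scores.shape[0] < 1:
        raise DomainError(f"{model.part}/{model.sex}: model has no training points")
    query = np.asarray(point, dtype=float)
    distances = np.hypot(model.scores[:, 0] - query[0], model.scores[:, 1] - query[1])
    dmin = distances.min()
    tol = 1e-9 * (1.0 + dmin)
    tied = np.flatnonzero(distances <= dmin + tol)
    best = max(tied, key=lambda i: (int(model.labels[i]),))
    return PartClassResult(
        part=model.part,
        assigned_class=model.labels[best],
        nearest_subject_id=model.subject_ids[best],
        distance=float(dmin),
    )


def fuse(
    part_classes: Mapping[str, FatClass],
    sex: str,
    exceptions: Sequence[ExceptionRule] | None = None,
    subject_id: str | None = None,
) -> DiagnosisResult:
    """Fuse the four part classes into the whole-body diagnosis."""
    missing = [p for p in PARTS if p not in part_classes]
    if missing:
        raise SchemaError(f"fuse needs all four parts; missing {missing}")
    if sex not in SEXES:
        raise DomainError(f"sex must be one of {SEXES}, got {sex!r}")
    classes = {p: FatClass(part_classes[p]) for p in PARTS}
    rules = exceptions if exceptions is not None else default_exception_rules()
    for rule in rules:
        if rule.matches(sex, classes):
            return DiagnosisResult(subject_id, classes, rule.outcome, "exception")
    counts: dict[FatClass, int] = {}
    for cls in classes.values():
        counts[cls] = counts.get(cls, 0) + 1
    top = max(counts.values())
    leaders = [cls for cls, n in counts.items() if n == top]
    if len(leaders) == 1:
        fused = leaders[0]
        rule_name = "majority" if top >= 3 else "plurality"
    else:
        fused = max(leaders)
        rule_name = "tie_higher"
    return DiagnosisResult(subject_id, classes, fused, rule_name)


def diagnose_subject(
    models: Mapping[str, PartPCAModel],
    record: SubjectRecord,
    exceptions: Sequence[ExceptionRule] | None = None,
) -> DiagnosisResult:
    """End-to-end diagnosis of one subject: derive lengths, normalize by
    height, project into each part's component plane, assign by nearest
    neighbour, fuse."""
    missing = [p for p in PARTS if p not in models]
    if missing:
        raise SchemaError(f"missing fitted model(s) for part(s) {missing}")
    for part in PARTS:
        if models[part].sex != record.sex:
            raise SchemaError(
                f"model for {part} was fitted on {models[part].sex} subjects, "
                f"record {record.subject_id} is {record.sex}"
            )
    normalized = normalize_record(record)
    part_results = {}
    for part in PARTS:
        point = models[part].project(normalized)
        part_results[part] = assign_part_class(models[part], point)
    result = fuse(
        {p: r.assigned_class for p, r in part_results.items()},
        record.sex,
        exceptions,
        subject_id=record.subject_id,
    )
    result.part_results = part_results
    return result


def diagnose_cohort(
    models_by_sex: Mapping[str, Mapping[str, PartPCAModel]],
    cohort: Iterable[SubjectRecord],
    exceptions: Sequence[ExceptionRule] | None = None,
) -> list[DiagnosisResult]:
    return [diagnose_subject(models_by_sex[rec.sex], rec, exceptions) for rec in cohort]
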