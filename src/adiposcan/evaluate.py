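"""Accuracy evaluation, the published 10-sample validation table, and the
end-to-end pipeline.

Accuracy is the percentage of exact class matches against the DEXA
whole-body class (the reference standard). Two evaluations are offered:

* the packaged 10-sample validation table, reproducing the published
  comparison of BMI / WHtR / WHR / proposal against DEXA;
* synthetic cohorts, where held-out subjects (stratified 80/20 split by
  sex and class) are diagnosed with models fitted on the training split,
  and the comparator indices are graded with configurable cut points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectRecord, generate_cohort
from .config import CohortConfig
from .diagnose import DiagnosisResult, ExceptionRule, diagnose_subject
from .errors import DomainError, SchemaError
from .pca import PartPCAModel, fit_part_pca, two_component_share
from .preprocess import PARTS, build_part_datasets, min_arm_leg_correlation
from .reference import (
    DEFAULT_INDEX_THRESHOLDS,
    SEXES,
    FatClass,
    IndexThresholds,
    bmi,
    fat_class,
    index_class,
    whr,
    whtr,
)


def accuracy(predicted: Sequence[FatClass], truth: Sequence[FatClass]) -> float:
    """100 x (exact class matches) / n."""
    predicted, truth = list(predicted), list(truth)
    if not predicted or not truth:
        raise DomainError("accuracy of empty sequences is undefined")
    if len(predicted) != len(truth):
        raise DomainError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    hits = sum(1 for p, t in zip(predicted, truth) if FatClass(p) == FatClass(t))
    return 100.0 * hits / len(truth)


@dataclass(frozen=True)
class ValidationRow:
    sample_id: str
    dexa_class: FatClass
    bmi_class: FatClass
    whtr_class: FatClass
    whr_class: FatClass
    proposal_class: FatClass


@dataclass(frozen=True)
class ValidationTable:
    rows: tuple[ValidationRow, ...]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise SchemaError("validation table sample ids must be unique")

    def column(self, name: str) -> list[FatClass]:
        return [getattr(r, name) for r in self.rows]

    def accuracies(self) -> dict[str, float]:
        """Exact-match accuracy of each method column against DEXA."""
        truth = self.column("dexa_class")
        return {
            method: accuracy(self.column(f"{method}_class"), truth)
            for method in ("bmi", "whtr", "whr", "proposal")
        }


def load_validation_table(path=None) -> ValidationTable:
    """The packaged 10-sample validation table (DEXA truth plus the class
    each method assigned), cell-for-cell as published."""
    if path is None:
        source = resources.files("adiposcan.data").joinpath("validation_table.csv")
        with resources.as_file(source) as fp:
            frame = pd.read_csv(fp)
    else:
        frame = pd.read_csv(path)
    required = ("sample_id", "dexa_class", "bmi_class", "whtr_class", "whr_class", "proposal_class")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"validation table missing column(s): {missing}")
    rows = tuple(
        ValidationRow(
            sample_id=str(row["sample_id"]),
            **{c: FatClass.from_label(str(row[c])) for c in required[1:]},
        )
        for _, row in frame.iterrows()
    )
    return ValidationTable(rows)


# ---------------------------------------------------------------------------
# synthetic-cohort evaluation


def dexa_class(record: SubjectRecord) -> FatClass:
    """Whole-body reference class from the total DEXA fat percentage."""
    return fat_class(record.fat_pct["total"], record.sex)


def stratified_split(
    cohort: Sequence[SubjectRecord],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Split by (sex, DEXA class) strata; every non-empty stratum
    contributes at least one held-out subject."""
    if not 0.0 < test_fraction < 1.0:
        raise DomainError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, FatClass], list[int]] = {}
    for i, rec in enumerate(cohort):
        strata.setdefault((rec.sex, dexa_class(rec)), []).append(i)
    test_idx: set[int] = set()
    for key in sorted(strata, key=lambda k: (k[0], int(k[1]))):
        idx = np.array(strata[key])
        n_test = max(1, int(round(test_fraction * idx.size)))
        chosen = rng.choice(idx, size=min(n_test, idx.size), replace=False)
        test_idx.update(int(i) for i in chosen)
    train = [rec for i, rec in enumerate(cohort) if i not in test_idx]
    test = [rec for i, rec in enumerate(cohort) if i in test_idx]
    if not train:
        raise DomainError("training split is empty; lower test_fraction")
    return train, test


def fit_models(
    cohort: Sequence[SubjectRecord],
    fv_target: float = 0.8,
    standardize: bool = True,
) -> dict[str, dict[str, PartPCAModel]]:
    """Fit the four part models for every sex present in the cohort."""
    datasets = build_part_datasets(cohort)
    models: dict[str, dict[str, PartPCAModel]] = {}
    for (sex, part), dataset in datasets.items():
        models.setdefault(sex, {})[part] = fit_part_pca(dataset, fv_target, standardize)
    return models


@dataclass
class PipelineReport:
    """All artifacts of one end-to-end run: cohort, fitted models,
    per-subject diagnoses and the accuracy comparison."""

    config: CohortConfig
    n_train: int
    n_test: int
    models: dict[str, dict[str, PartPCAModel]]
    diagnoses: pd.DataFrame
    accuracies: dict[str, float]
    validation_accuracies: dict[str, float]
    structure: dict[str, float] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            "adiposcan pipeline report",
            f"cohort: {self.n_train + self.n_test} subjects "
            f"({self.n_train} train / {self.n_test} held out), seed {self.config.seed}",
            "",
            "fitted part models (Comp1+Comp2 variance share, %):",
        ]
        for sex in SEXES:
            if sex not in self.models:
                continue
            shares = ", ".join(
                f"{part} {two_component_share(self.models[sex][part]):.1f}" for part in PARTS
            )
            lines.append(f"  {sex}: {shares}")
        lines.append(f"  min arm-leg circumference correlation: "
                     f"{self.structure.get('min_arm_leg_correlation', float('nan')):.3f}")
        lines.append("")
        lines.append("accuracy vs DEXA class (%):")
        for key, value in self.accuracies.items():
            lines.append(f"  {key:<22s} {value:6.1f}")
        lines.append("")
        lines.append("published 10-sample validation table (%):")
        for key, value in self.validation_accuracies.items():
            lines.append(f"  {key:<22s} {value:6.1f}")
        return "\n".join(lines) + "\n"


def run_pipeline(
    config: CohortConfig | None = None,
    holdout_fraction: float = 0.2,
    fv_target: float = 0.8,
    standardize: bool = True,
    index_thresholds: IndexThresholds | None = None,
    exceptions: Sequence[ExceptionRule] | None = None,
) -> PipelineReport:
    """Generate a cohort, fit per-part models on the training split,
    diagnose everyone, and compare against the obesity indices.

    Deterministic given the config (the split seed derives from the
    cohort seed).
    """
    config = config if config is not None else CohortConfig()
    cohort = generate_cohort(config)
    train, test = stratified_split(cohort, holdout_fraction, seed=config.seed + 1)
    models = fit_models(train, fv_target, standardize)
    thresholds = index_thresholds if index_thresholds is not None else DEFAULT_INDEX_THRESHOLDS

    rows = []
    for split, subset in (("train", train), ("test", test)):
        for rec in subset:
            result = diagnose_subject(models[rec.sex], rec, exceptions)
            truth = dexa_class(rec)
            row = {
                "subject_id": rec.subject_id,
                "sex": rec.sex,
                "split": split,
                "dexa_class": str(truth),
                "fused_class": str(result.fused_class),
                "rule_applied": result.rule_applied,
                "bmi_class": str(index_class(bmi(rec.height, rec.weight), "bmi", rec.sex, thresholds)),
                "whtr_class": str(
                    index_class(
                        whtr(rec.measurements["waist_circumference"], rec.height),
                        "whtr", rec.sex, thresholds,
                    )
                ),
                "whr_class": str(
                    index_class(
                        whr(
                            rec.measurements["waist_circumference"],
                            rec.measurements["hip_circumference"],
                        ),
                        "whr", rec.sex, thresholds,
                    )
                ),
            }
            row.update({f"{p}_class": str(result.part_classes[p]) for p in PARTS})
            row.update({f"{p}_distance": result.part_results[p].distance for p in PARTS})
            rows.append(row)
    diagnoses = pd.DataFrame(rows)

    def _acc(frame: pd.DataFrame, column: str) -> float:
        return accuracy(
            [FatClass.from_label(c) for c in frame[column]],
            [FatClass.from_label(c) for c in frame["dexa_class"]],
        )

    test_frame = diagnoses[diagnoses["split"] == "test"]
    train_frame = diagnoses[diagnoses["split"] == "train"]
    accuracies = {
        "proposal_holdout": _acc(test_frame, "fused_class"),
        "proposal_insample": _acc(train_frame, "fused_class"),
        "bmi": _acc(diagnoses, "bmi_class"),
        "whtr": _acc(diagnoses, "whtr_class"),
        "whr": _acc(diagnoses, "whr_class"),
    }
    structure = {
        "min_arm_leg_correlation": min_arm_leg_correlation(cohort),
        "min_two_component_share": min(
            two_component_share(models[sex][part]) for sex in models for part in PARTS
        ),
    }
    return PipelineReport(
        config=config,
        n_train=len(train),
        n_test=len(test),
        models=models,
        diagnoses=diagnoses,
        accuracies=accuracies,
        validation_accuracies=load_validation_table().accuracies(),
        structure=structure,
    )
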