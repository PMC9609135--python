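"""Nearest-point class assignment and whole-body fusion rules."""

import itertools

import numpy as np
import pytest

from adiposcan.diagnose import (
    ExceptionRule,
    assign_part_class,
    default_exception_rules,
    diagnose_subject,
    fuse,
    parse_exception_rules,
)
from adiposcan.errors import DomainError, SchemaError
from adiposcan.preprocess import PARTS
from adiposcan.reference import FatClass

A, B, C, D = FatClass.A, FatClass.B, FatClass.C, FatClass.D


def planar_model(points, labels):
    """Tiny model stand-in whose Comp1-Comp2 plane is the identity
    embedding of two synthetic coordinates (synthetic test double)."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    from adiposcan.pca import PartPCAModel

    return PartPCAModel(
        part="chest", sex="male", variable_names=("v0", "v1"),
        mean=np.zeros(2), scale=np.ones(2), loadings=np.eye(2),
        eigenvalues=np.array([1.0, 1.0]), variance_shares=np.array([50.0, 50.0]),
        n_retained=2, scores=points, labels=list(labels),
        subject_ids=[f"S{i}" for i in range(n)], standardized=False,
    )


def parts_map(chest, abdomen, hips, arms_legs):
    return dict(zip(PARTS, (chest, abdomen, hips, arms_legs)))


class TestAssign:
    def test_query_on_training_point(self):
        model = planar_model([(0, 0), (3, 0), (0, 4)], [A, B, C])
        result = assign_part_class(model, (3.0, 0.0))
        assert result.assigned_class == B
        assert result.distance == pytest.approx(0.0)
        assert result.nearest_subject_id == "S1"

    def test_midway_tie_breaks_to_higher_class(self):
        model = planar_model([(-1, 0), (1, 0)], [A, C])
        result = assign_part_class(model, (0.0, 0.0))
        assert result.assigned_class == C

    def test_nearest_wins(self):
        model = planar_model([(-1, 0), (1, 0)], [D, A])
        assert assign_part_class(model, (0.6, 0.0)).assigned_class == A

    def test_holdout_accuracy_beats_chance(self, default_cohort):
        """Per-part 1-NN on a held-out half cohort clears the 25% chance
        level for every part (several seeds)."""
        from adiposcan.evaluate import fit_models, stratified_split
        from adiposcan.preprocess import build_part_datasets, part_label, normalize_record

        for seed in range(5):
            train, test = stratified_split(default_cohort, 0.5, seed=seed)
            models = fit_models(train)
            for part in PARTS:
                hits = total = 0
                for rec in test:
                    model = models[rec.sex][part]
                    point = model.project(normalize_record(rec))
                    predicted = assign_part_class(model, point).assigned_class
                    hits += predicted == part_label(rec, part)
                    total += 1
                assert hits / total > 0.25


class TestFuse:
    def test_majority_worked_example(self):
        result = fuse(parts_map(A, A, A, B), "male")
        assert result.fused_class == A
        assert result.rule_applied == "majority"

    def test_two_two_tie_takes_higher(self):
        result = fuse(parts_map(C, C, B, B), "male")
        assert result.fused_class == C
        assert result.rule_applied == "tie_higher"

    def test_unanimity(self):
        for sex in ("male", "female"):
            result = fuse(parts_map(D, D, D, D), sex)
            assert result.fused_class == D

    def test_plurality_for_two_one_one(self):
        result = fuse(parts_map(C, C, B, A), "female")
        assert result.fused_class == C
        assert result.rule_applied == "plurality"

    def test_all_distinct_resolves_to_highest(self):
        result = fuse(parts_map(A, B, C, D), "female")
        assert result.fused_class == D
        assert result.rule_applied == "tie_higher"

    def test_exception_overrides_majority(self):
        # male (C, D, D, C): plain rules would give D (2-2 tie), the
        # tabulated exception says overweight
        result = fuse(parts_map(C, D, D, C), "male")
        assert result.fused_class == C
        assert result.rule_applied == "exception"

    def test_tabulated_singleton_rows(self):
        assert fuse(parts_map(A, B, B, B), "male").fused_class == B
        assert fuse(parts_map(B, C, B, B), "male").fused_class == B

    def test_range_pattern_expansion(self):
        # female row "B~C, D, D, D -> overweight" covers both chest classes
        for chest in (B, C):
            result = fuse(parts_map(chest, D, D, D), "female")
            assert result.fused_class == C
            assert result.rule_applied == "exception"

    def test_exceptions_are_sex_specific(self):
        # the (C, D, D, C) exception is tabulated for males only
        result = fuse(parts_map(C, D, D, C), "female")
        assert result.rule_applied != "exception"
        assert result.fused_class == D

    def test_missing_part_is_schema_error(self):
        with pytest.raises(SchemaError, match="arms_legs"):
            fuse({"chest": A, "abdomen": A, "hips": A}, "male")

    def test_unknown_sex_is_error(self):
        with pytest.raises(DomainError):
            fuse(parts_map(A, A, A, A), "unknown")

    def test_fused_never_exceeds_maximum_part_class(self):
        """Over all 256 part-class combinations and both sexes, the fused
        class never exceeds the highest part class."""
        for sex in ("male", "female"):
            for combo in itertools.product(FatClass, repeat=4):
                result = fuse(parts_map(*combo), sex)
                assert result.fused_class <= max(combo)

    def test_custom_rules_override_default(self):
        rules = parse_exception_rules(
            __import__("pandas").DataFrame(
                [{"sex": "male", "chest": "A", "abdomen": "A", "hips": "A",
                  "arms_legs": "A", "outcome": "D"}]
            )
        )
        assert fuse(parts_map(A, A, A, A), "male", exceptions=rules).fused_class == D


class TestDefaultRuleTable:
    def test_seven_rows(self):
        rules = default_exception_rules()
        assert len(rules) == 7
        assert sum(r.sex == "male" for r in rules) == 5
        assert sum(r.sex == "female" for r in rules) == 2

    def test_patterns_never_match_unanimous_combinations(self):
        """No exception row captures a unanimous four-part agreement, so
        unanimity always wins."""
        for sex in ("male", "female"):
            for cls in FatClass:
                assert fuse(parts_map(cls, cls, cls, cls), sex).fused_class == cls


class TestDiagnoseSubject:
    def test_training_subject_recovers_own_label(self, default_cohort, fitted_models):
        """A subject diagnosed with models trained on its own cohort and
        whose four part labels agree gets that common class back."""
        from adiposcan.preprocess import part_label

        checked = 0
        for rec in default_cohort:
            labels = {part: part_label(rec, part) for part in PARTS}
            if len(set(labels.values())) != 1:
                continue
            result = diagnose_subject(fitted_models[rec.sex], rec)
            assert result.part_classes == labels
            assert result.fused_class == next(iter(labels.values()))
            checked += 1
        assert checked > 50  # clipping makes most subjects label-unanimous

    def test_noise_free_interior_d_subject(self, noise_free_cohort, fitted_models):
        """A zero-noise subject deep inside the obese latent band is
        diagnosed D by models fitted on a different (noisy) cohort."""
        candidates = [
            r for r in noise_free_cohort
            if r.true_class == D and r.latent_adiposity > 0.9
        ]
        assert candidates
        for rec in candidates[:3]:
            assert diagnose_subject(fitted_models[rec.sex], rec).fused_class == D

    def test_missing_part_variables_is_schema_error(self, default_cohort, fitted_models):
        import dataclasses

        rec = default_cohort[0]
        broken = dataclasses.replace(
            rec, measurements={k: v for k, v in rec.measurements.items() if k != "groin_area"}
        )
        with pytest.raises(SchemaError, match="groin_area"):
            diagnose_subject(fitted_models[rec.sex], broken)

    def test_sex_mismatch_is_schema_error(self, default_cohort, fitted_models):
        rec = next(r for r in default_cohort if r.sex == "female")
        with pytest.raises(SchemaError, match="fitted on"):
            diagnose_subject(fitted_models["male"], rec)
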