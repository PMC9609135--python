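"""Length derivation, height normalization and the four part datasets."""

import dataclasses

import numpy as np
import pytest

from adiposcan.cohort import SubjectRecord
from adiposcan.errors import DomainError, SchemaError
from adiposcan.preprocess import (
    LEG_CIRCUMFERENCE_VARIABLES,
    PART_VARIABLES,
    PARTS,
    arm_leg_correlation,
    build_part_datasets,
    derive_lengths,
    min_arm_leg_correlation,
    normalize_by_height,
)


class TestDeriveLengths:
    def test_arithmetic(self):
        raw = {
            "shoulder_height": 140.0, "chest_height": 120.0,
            "waist_height": 100.0, "hip_height": 85.0,
            "groin_height": 75.0, "knee_height": 45.0,
        }
        out = derive_lengths(raw)
        assert out["chest_length"] == pytest.approx(20.0)
        assert out["waist_length"] == pytest.approx(15.0)
        assert out["hip_length"] == pytest.approx(10.0)
        assert out["thigh_length"] == pytest.approx(40.0)
        for dropped in ("shoulder_height", "chest_height", "waist_height", "hip_height"):
            assert dropped not in out
        assert out["groin_height"] == 75.0  # retained: still an analysis variable

    def test_nonpositive_length_is_error(self):
        raw = {
            "shoulder_height": 140.0, "chest_height": 120.0,
            "waist_height": 85.0, "hip_height": 85.0,  # waist length would be 0
            "groin_height": 75.0, "knee_height": 45.0,
        }
        with pytest.raises(DomainError, match="waist_length"):
            derive_lengths(raw)

    def test_missing_height_is_schema_error(self):
        with pytest.raises(SchemaError, match="shoulder_height"):
            derive_lengths({"chest_height": 120.0})


class TestNormalize:
    def _record(self, height=170.0, **extra):
        return SubjectRecord(
            subject_id="X", sex="male", height=height, weight=68.0,
            measurements={"waist_circumference": 85.0, **extra},
            fat_pct={r: 20.0 for r in ("chest", "abdomen", "hip", "arm", "leg", "total")},
        )

    def test_ratio(self):
        out = normalize_by_height(self._record())
        assert out["waist_circumference"] == pytest.approx(0.5)
        assert out["weight"] == pytest.approx(68.0 / 170.0)
        assert out["height"] == 170.0  # stature stays raw
        assert out.units == "per_cm"

    def test_scale_invariance(self):
        base = normalize_by_height(self._record())
        rec = self._record(height=340.0)
        rec.weight *= 2.0
        rec.measurements = {k: 2.0 * v for k, v in rec.measurements.items()}
        scaled = normalize_by_height(rec)
        assert scaled["waist_circumference"] == pytest.approx(base["waist_circumference"])
        assert scaled["weight"] == pytest.approx(base["weight"])

    def test_zero_height_is_domain_error(self):
        rec = self._record()
        rec.height = 0.0
        with pytest.raises(DomainError):
            normalize_by_height(rec)

    def test_double_normalization_is_rejected(self):
        rec = self._record()
        once = normalize_by_height(rec)
        rec.measurements = once
        with pytest.raises(SchemaError, match="already"):
            normalize_by_height(rec)


class TestPartDatasets:
    def test_eight_datasets_with_study_row_counts(self, part_datasets):
        assert len(part_datasets) == 8
        for part in PARTS:
            assert part_datasets[("male", part)].n_subjects == 87
            assert part_datasets[("female", part)].n_subjects == 73

    @pytest.mark.parametrize(
        "part, n_columns", [("chest", 8), ("abdomen", 11), ("hips", 7), ("arms_legs", 15)]
    )
    def test_column_counts(self, part_datasets, part, n_columns):
        dataset = part_datasets[("male", part)]
        assert len(dataset.variable_names) == n_columns
        assert dataset.matrix.shape[1] == n_columns

    def test_row_conservation(self, default_cohort, part_datasets):
        """Every subject appears exactly once in each of its sex's four
        part datasets."""
        for sex in ("male", "female"):
            expected = sorted(r.subject_id for r in default_cohort if r.sex == sex)
            for part in PARTS:
                assert sorted(part_datasets[(sex, part)].subject_ids) == expected

    def test_labels_match_regional_fat(self, default_cohort, part_datasets):
        dataset = part_datasets[("male", "chest")]
        by_id = {r.subject_id: r for r in default_cohort}
        from adiposcan.reference import fat_class

        for sid, label in zip(dataset.subject_ids, dataset.labels):
            assert label == fat_class(by_id[sid].fat_pct["chest"], "male")

    def test_single_subject_cohort(self, default_cohort):
        datasets = build_part_datasets(default_cohort[:1])
        assert len(datasets) == 4  # one sex present
        for dataset in datasets.values():
            assert dataset.n_subjects == 1

    def test_missing_variable_is_schema_error(self, default_cohort):
        broken = dataclasses.replace(
            default_cohort[0],
            measurements={
                k: v for k, v in default_cohort[0].measurements.items() if k != "chest_area"
            },
        )
        with pytest.raises(SchemaError, match="chest_area"):
            build_part_datasets([broken])

    def test_matrix_values_are_normalized(self, default_cohort, part_datasets):
        rec = default_cohort[0]
        dataset = part_datasets[(rec.sex, "abdomen")]
        row = dataset.matrix[dataset.subject_ids.index(rec.subject_id)]
        j = dataset.variable_names.index("waist_circumference")
        assert row[j] == pytest.approx(rec.measurements["waist_circumference"] / rec.height)


class TestArmLegCorrelation:
    def test_default_cohort_supports_the_merge(self, default_cohort):
        assert min_arm_leg_correlation(default_cohort) >= 0.9

    def test_self_correlation_is_one(self, default_cohort):
        corr = arm_leg_correlation(default_cohort)
        assert corr.loc["arm_circumference", "arm_circumference"] == pytest.approx(1.0)

    def test_independent_noise_has_low_correlation(self):
        """Uncorrelated synthetic columns at n=1000 stay below |r| = 0.2
        (sampling-theory bound, several seeds)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 1000
            cohort = []
            for i in range(n):
                meas = {name: float(rng.normal(50.0, 5.0)) for name in
                        ("arm_circumference",) + LEG_CIRCUMFERENCE_VARIABLES}
                cohort.append(
                    SubjectRecord(
                        subject_id=f"S{i}", sex="male", height=170.0, weight=70.0,
                        measurements=meas,
                        fat_pct={r: 20.0 for r in ("chest", "abdomen", "hip", "arm", "leg", "total")},
                    )
                )
            corr = arm_leg_correlation(cohort)
            off = corr.loc["arm_circumference", list(LEG_CIRCUMFERENCE_VARIABLES)]
            assert (off.abs() < 0.2).all()

    def test_too_few_subjects(self, default_cohort):
        with pytest.raises(DomainError):
            arm_leg_correlation(default_cohort[:2])

    def test_zero_variance_is_error(self):
        cohort = []
        for i in range(5):
            meas = {name: 40.0 for name in ("arm_circumference",) + LEG_CIRCUMFERENCE_VARIABLES}
            cohort.append(
                SubjectRecord(
                    subject_id=f"S{i}", sex="male", height=170.0, weight=70.0,
                    measurements=meas,
                    fat_pct={r: 20.0 for r in ("chest", "abdomen", "hip", "arm", "leg", "total")},
                )
            )
        with pytest.raises(DomainError, match="zero-variance"):
            arm_leg_correlation(cohort)
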