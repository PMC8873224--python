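import math

import numpy as np
import pytest
from scipy import stats

from fundusdr.alignment_progression import ChangeKind, SimilarityTransform, compare_visits
from fundusdr.fundus_model import ImageRecord, Lesion, LesionType
from fundusdr.grading import default_table, grade, summarise
from fundusdr.synthetic_data import (
    InapplicableEventError,
    InfeasibleSynthesisError,
    NoiseModel,
    PlannedEvent,
    PrevalenceConfig,
    ProgressionScript,
    PRESET_COUNTS,
    apply_noise,
    default_geometry,
    demo_detect,
    prevalence_preset,
    render_phantom,
    sample_cohort,
    synthesise_for_level,
    synthesise_pair,
)

GEOM = default_geometry()


class TestPrevalencePresets:
    @pytest.mark.parametrize("name, total", [
        ("kenya", 28680), ("saudi", 10026), ("china", 15000),
    ])
    def test_row_sums(self, name, total):
        assert prevalence_preset(name).total_images == total

    def test_proportions_are_counts_over_row_sum(self):
        for name, (_, counts) in PRESET_COUNTS.items():
            preset = prevalence_preset(name)
            total = sum(counts)
            assert preset.proportions == tuple(c / total for c in counts)
            assert sum(preset.proportions) == pytest.approx(1.0, abs=1e-9)

    def test_kenya_is_icdrs_others_nsc(self):
        assert prevalence_preset("kenya").scheme == "ICDRS"
        assert prevalence_preset("saudi").scheme == "NSC"
        assert prevalence_preset("china").scheme == "NSC"

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PrevalenceConfig(scheme="NSC", levels=("R0", "R1"),
                             proportions=(0.6, 0.6))

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            prevalence_preset("mars")


class TestSynthesiseForLevel:
    def test_level_0_is_empty(self):
        assert synthesise_for_level("ICDRS", "0", False, GEOM, 0).lesions == []

    def test_mild_is_mas_only(self):
        for seed in range(20):
            rec = synthesise_for_level("ICDRS", "1", False, GEOM, seed)
            assert rec.lesions
            assert all(l.type is LesionType.MA for l in rec.lesions)

    @pytest.mark.parametrize("scheme, levels", [
        ("ICDRS", ("0", "1", "2", "3", "4")),
        ("NSC", ("R0", "R1", "R2", "R3")),
    ])
    def test_round_trip_sample(self, scheme, levels):
        table = default_table(scheme)
        for level in levels:
            for seed in range(25):
                rec = synthesise_for_level(scheme, level, False, GEOM, seed)
                assert grade(summarise(rec, 0.0), table).level == level

    def test_never_satisfies_higher_rule(self):
        # direct predicate evaluation, independent of grade()'s first-hit logic
        from fundusdr.grading.core import _eval_condition
        table = default_table("ICDRS")
        for level in ("0", "1", "2", "3"):
            target = table.level_index(level)
            for seed in range(40):
                rec = synthesise_for_level("ICDRS", level, False, GEOM, seed)
                summary = summarise(rec, 0.0)
                for rule in table.rules[:-1]:
                    if table.level_index(rule["level"]) > target:
                        assert not any(_eval_condition(c, summary)
                                       for c in rule["any"])

    def test_maculopathy_plants_macular_exudate(self):
        for seed in range(10):
            rec = synthesise_for_level("NSC", "R1", True, GEOM, seed)
            result = grade(summarise(rec, 0.0), default_table("NSC"))
            assert result.level == "R1" and result.dmo

    def test_maculopathy_infeasible_on_lesion_free_levels(self):
        for scheme, level in (("ICDRS", "0"), ("ICDRS", "1"), ("NSC", "R0")):
            with pytest.raises(InfeasibleSynthesisError):
                synthesise_for_level(scheme, level, True, GEOM, 0)


class TestSampleCohort:
    def test_zero_noise_grading_reproduces_gt(self):
        preset = prevalence_preset("china")
        table = default_table("NSC")
        for member in sample_cohort(preset, 200, NoiseModel.none(), seed=3):
            result = grade(summarise(member.record, 0.0), table)
            assert result.level == member.gt_level
            assert result.dmo == member.gt_maculopathy

    def test_level_fractions_near_preset(self):
        preset = prevalence_preset("china")
        members = sample_cohort(preset, 4000, NoiseModel.none(), seed=5)
        for level, expected in zip(preset.levels, preset.proportions):
            realised = sum(m.gt_level == level for m in members) / len(members)
            assert abs(realised - expected) < 0.02

    def test_same_seed_identical(self):
        preset = prevalence_preset("saudi")
        a = sample_cohort(preset, 50, NoiseModel(miss_prob=0.2), seed=9)
        b = sample_cohort(preset, 50, NoiseModel(miss_prob=0.2), seed=9)
        assert a == b

    def test_maculopathy_rate_honoured(self):
        preset = PrevalenceConfig(scheme="NSC", levels=("R0", "R1"),
                                  proportions=(0.0, 1.0),
                                  maculopathy_rate={"R1": 1.0})
        members = sample_cohort(preset, 30, NoiseModel.none(), seed=1)
        assert all(m.gt_maculopathy for m in members)


class TestNoiseModel:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="miss probability"):
            NoiseModel(miss_prob=1.5)

    def test_miss_counts_are_binomial(self):
        # chi-square goodness of fit of recovered counts vs Binomial(k, 1-m)
        k, m, n = 6, 0.3, 5000
        rng = np.random.default_rng(2)
        base = ImageRecord(
            image_id="b", geometry=GEOM,
            lesions=[Lesion(LesionType.MA, (500.0 + 20 * i, 500.0), 8.0)
                     for i in range(k)])
        noise = NoiseModel(miss_prob=m)
        observed = np.zeros(k + 1)
        for _ in range(n):
            survivors = len(apply_noise(base, noise, rng).lesions)
            observed[survivors] += 1
        expected = stats.binom.pmf(np.arange(k + 1), k, 1 - m) * n
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=k)

    def test_false_alarms_add_lesions(self):
        rng = np.random.default_rng(0)
        base = ImageRecord(image_id="b", geometry=GEOM, lesions=[])
        noise = NoiseModel(false_alarm_rate={LesionType.ARTEFACT: 3.0})
        totals = [len(apply_noise(base, noise, rng).lesions) for _ in range(300)]
        assert np.mean(totals) == pytest.approx(3.0, abs=0.3)
        assert all(l.type is LesionType.ARTEFACT
                   for l in apply_noise(base, noise, rng).lesions)

    def test_confidence_draws(self):
        rng = np.random.default_rng(1)
        base = ImageRecord(image_id="b", geometry=GEOM,
                           lesions=[Lesion(LesionType.MA, (500, 500), 8.0)])
        noisy = apply_noise(base, NoiseModel(confidence_beta=(2, 5)), rng)
        assert 0.0 <= noisy.lesions[0].confidence < 1.0


class TestSynthesisePair:
    def script(self, *events, camera=None):
        return ProgressionScript(events=tuple(events),
                                 camera=camera or SimilarityTransform())

    def test_empty_script_all_stable(self):
        base = synthesise_for_level("ICDRS", "2", False, GEOM, 1)
        follow, gt = synthesise_pair(base, self.script(), NoiseModel.none(), 0)
        report = compare_visits(base, follow)
        assert all(e.kind is ChangeKind.STABLE for e in report.events)
        assert all(e.kind is ChangeKind.STABLE for e in gt)

    def test_new_haemorrhage_recovered(self):
        base = synthesise_for_level("ICDRS", "0", False, GEOM, 1)
        follow, gt = synthesise_pair(
            base, self.script(PlannedEvent(ChangeKind.NEW, LesionType.HAEMORRHAGE, region=2)),
            NoiseModel.none(), 0)
        report = compare_visits(base, follow)
        assert [ (e.kind, e.lesion_type, e.region) for e in report.events ] == \
               [(ChangeKind.NEW, LesionType.HAEMORRHAGE, 2)]
        assert report.events[0].region == gt[0].region == 2

    def test_scripted_events_recovered_exactly(self):
        rng_seeds = range(30)
        for seed in rng_seeds:
            base = synthesise_for_level("ICDRS", "1", False, GEOM, seed + 100)  # always has MAs
            camera = SimilarityTransform(scale=1.1, rotation=0.05, translation=(8.0, -6.0))
            events = [PlannedEvent(ChangeKind.NEW, LesionType.MA, region=3),
                      PlannedEvent(ChangeKind.GROWN, LesionType.MA, area_factor=2.0)]
            follow, gt = synthesise_pair(base, self.script(*events, camera=camera),
                                         NoiseModel.none(), seed)
            report = compare_visits(base, follow)
            got = sorted((e.kind.value, e.lesion_type.value, e.region,
                          e.baseline_lesion_id, e.followup_lesion_id)
                         for e in report.events)
            want = sorted((e.kind.value, e.lesion_type.value, e.region,
                           e.baseline_lesion_id, e.followup_lesion_id)
                          for e in gt)
            assert got == want

    def test_resolved_without_target_rejected(self):
        base = synthesise_for_level("ICDRS", "0", False, GEOM, 0)  # no lesions
        with pytest.raises(InapplicableEventError):
            synthesise_pair(base, self.script(
                PlannedEvent(ChangeKind.RESOLVED, LesionType.MA)), NoiseModel.none(), 0)

    def test_swap_maps_new_to_resolved(self):
        base = synthesise_for_level("ICDRS", "2", False, GEOM, 4)
        follow, _ = synthesise_pair(
            base,
            self.script(PlannedEvent(ChangeKind.NEW, LesionType.HAEMORRHAGE, region=4),
                        PlannedEvent(ChangeKind.GROWN, LesionType.MA, area_factor=1.6)),
            NoiseModel.none(), 0)
        fwd = compare_visits(base, follow)
        rev = compare_visits(follow, base)
        assert fwd.kind_counts[ChangeKind.NEW] == rev.kind_counts[ChangeKind.RESOLVED]
        assert fwd.kind_counts[ChangeKind.RESOLVED] == rev.kind_counts[ChangeKind.NEW]
        assert fwd.kind_counts[ChangeKind.GROWN] == rev.kind_counts[ChangeKind.SHRUNK]


class TestPhantoms:
    def test_empty_record_yields_no_lesions(self, small_geometry):
        record = ImageRecord(image_id="p", geometry=small_geometry)
        detected = demo_detect(render_phantom(record, seed=1))
        assert detected.lesions == []

    def test_landmarks_recovered(self, small_geometry):
        record = ImageRecord(image_id="p", geometry=small_geometry)
        detected = demo_detect(render_phantom(record, seed=1))
        est = detected.geometry
        assert est.disc_centre == pytest.approx(small_geometry.disc_centre, abs=1.0)
        assert est.fovea_centre == pytest.approx(small_geometry.fovea_centre, abs=1.0)
        assert est.disc_diameter == pytest.approx(small_geometry.disc_diameter, rel=0.05)

    def test_five_exudates_recovered(self, small_geometry):
        fx, fy = small_geometry.fovea_centre
        dd = small_geometry.disc_diameter
        lesions = [Lesion(LesionType.EXUDATE,
                          (fx + 1.5 * dd * math.cos(a), fy + 1.5 * dd * math.sin(a)),
                          120.0)
                   for a in (2.0, 2.8, 3.6, 4.4, 5.2)]
        record = ImageRecord(image_id="p", geometry=small_geometry, lesions=lesions)
        detected = demo_detect(render_phantom(record, seed=2))
        found = [l for l in detected.lesions if l.type is LesionType.EXUDATE]
        assert len(found) == 5
        for true in lesions:
            nearest = min(math.dist(true.centroid, f.centroid) for f in found)
            assert nearest < 0.1 * dd

    def test_mild_phantom_round_trips_to_mild(self, small_geometry):
        record = synthesise_for_level("ICDRS", "1", False, small_geometry, 11)
        detected = demo_detect(render_phantom(record, seed=3))
        result = grade(summarise(detected, 0.0), default_table("ICDRS"))
        assert result.level == "1"

    def test_overlapping_landmarks_rejected(self):
        from fundusdr.fundus_model import FundusGeometry
        geom = FundusGeometry(disc_centre=(210.0, 200.0), disc_diameter=100.0,
                              fovea_centre=(200.0, 200.0),
                              image_width=400, image_height=400)
        record = ImageRecord(image_id="p", geometry=geom)
        with pytest.raises(ValueError, match="overlap"):
            render_phantom(record, seed=0)
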