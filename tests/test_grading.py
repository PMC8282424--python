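import numpy as np
import pytest

from gliopipe.grading import (ClassifierConfig, CVReport, _make_report,
                              augment, augment_params, classify_molecular,
                              image_summary_features, make_patches,
                              predict_cascade, split_folds, tabular_features,
                              train_stage1, train_stage2,
                              STAGE1_CONV_LAYERS, STAGE2_RESIDUAL_BLOCKS)
from gliopipe.records import CaseRecord
from gliopipe.synthesis import SyntheticCohortSpec, generate_cohort


class TestMakePatches:
    def test_exact_tiling_1024(self):
        roi = np.zeros((1024, 1024, 3), np.uint8)
        patches = make_patches(roi, 512)
        assert len(patches) == 4
        assert all(p.shape == (512, 512, 3) for p in patches)

    def test_overlap_tiling_1000(self):
        roi = np.arange(1000 * 1000 * 3, dtype=np.uint8).reshape(1000, 1000, 3)
        patches = make_patches(roi, 512)
        assert len(patches) == 4
        # stride 488: second window starts at 488
        assert np.array_equal(patches[1], roi[0:512, 488:1000])
        assert np.array_equal(patches[3], roi[488:1000, 488:1000])

    def test_identity_patch(self):
        roi = np.random.default_rng(0).integers(0, 255, (512, 512, 3)).astype(
            np.uint8
        )
        (patch,) = make_patches(roi, 512)
        assert np.array_equal(patch, roi)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            make_patches(np.zeros((100, 100, 3)), 512)


class TestAugment:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        patch = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
        assert np.array_equal(augment(patch, 99), augment(patch, 99))

    def test_shape_preserved(self):
        patch = np.random.default_rng(2).integers(0, 255, (48, 48, 3)).astype(
            np.uint8
        )
        for seed in range(20):
            assert augment(patch, seed).shape == patch.shape

    def test_rotation_180_twice_is_identity(self):
        # find a seed drawing (rot=180, no flip, scale ~ 1)
        seed = next(
            s for s in range(100000)
            if (lambda k, f, sc: k == 2 and f == 0 and abs(sc - 1) <= 0.01)(
                *augment_params(s)
            )
        )
        patch = np.random.default_rng(3).integers(0, 255, (32, 32, 3)).astype(
            np.uint8
        )
        assert np.array_equal(augment(augment(patch, seed), seed), patch)

    def test_non_square_rotation_errors(self):
        patch = np.zeros((32, 48, 3), np.uint8)
        seed = next(s for s in range(1000) if augment_params(s)[0] % 2 == 1)
        with pytest.raises(ValueError):
            augment(patch, seed)


class TestSplitFolds:
    def test_counting_30_cases(self, small_cohort):
        folds = split_folds(small_cohort, k=5, seed=0)
        for _, test_idx in folds:
            assert len(test_idx) == 6
            grades = [small_cohort[i].grade for i in test_idx]
            assert grades.count("II") == 2
            assert grades.count("III") == 2
            assert grades.count("IV") == 2

    def test_partition_axiom(self, small_cohort):
        folds = split_folds(small_cohort, k=5, seed=0)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(30))
        for train_idx, test_idx in folds:
            assert set(train_idx).isdisjoint(test_idx)

    def test_determinism(self, small_cohort):
        a = split_folds(small_cohort, k=5, seed=3)
        b = split_folds(small_cohort, k=5, seed=3)
        for (ta, sa), (tb, sb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(sa, sb)

    def test_small_class_errors(self, small_cohort):
        # grade III present with only 3 cases < k
        subset = small_cohort[:10] + small_cohort[10:13]
        with pytest.raises(ValueError):
            split_folds(subset, k=5)


class TestConfigAndFeatures:
    def test_no_active_block_errors(self):
        with pytest.raises(ValueError, match="no active feature block"):
            ClassifierConfig(use_intensity=False, use_molecular=False,
                             use_cellularity=False)

    def test_molecular_encoding(self):
        rec = CaseRecord("c1", "II", "OD", "MT", "WT", "CD", "ML",
                         cellularity=0.35)
        vec = tabular_features(rec, ClassifierConfig())
        assert vec[:4].tolist() == [1.0, 0.0, 1.0, 1.0]
        # cellularity is standardized with fixed constants
        assert vec[-1] == pytest.approx((0.35 - 0.25) / 0.1)

    def test_missing_marker_imputed_with_indicator(self):
        rec = CaseRecord("c2", "II", "AA", None, "WT", "NC", "UM",
                         cellularity=0.2)
        vec = rec.molecular_vector
        assert vec[0] == 0.0 and vec[4] == 1.0

    def test_missing_cellularity_errors(self):
        rec = CaseRecord("c3", "II", "AA", "MT", "WT", "NC", "UM")
        with pytest.raises(ValueError, match="c3"):
            tabular_features(rec, ClassifierConfig())


class TestCVReport:
    def test_hand_arithmetic(self):
        rep = _make_report("t", [0.8, 0.9, 1.0, 0.7, 0.6],
                           np.zeros((2, 2), int), ("a", "b"))
        assert rep.mean_accuracy == pytest.approx(0.80)
        assert rep.std_accuracy == pytest.approx(0.1581, abs=1e-4)
        assert rep.summary() == "80.00% ± 15.81%"

    def test_degenerate_perfect(self):
        rep = _make_report("t", [1.0] * 5, np.zeros((2, 2), int), ("a", "b"))
        assert rep.summary() == "100.00% ± 0.00%"

    def test_roundtrip_dict(self):
        rep = _make_report("t", [0.5, 0.7], np.eye(2, dtype=int), ("a", "b"))
        d = rep.to_dict()
        assert d["mean_accuracy"] == pytest.approx(0.6)
        assert np.isclose(np.std(d["per_fold_accuracy"], ddof=1),
                          d["std_accuracy"])


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = SyntheticCohortSpec(n_cases_per_class=(6, 6, 6), roi_size=48, seed=5)
    return generate_cohort(spec)


QUICK = dict(epochs=2, input_size=32, batch_size=6, folds=2)


class TestStageTraining:
    def test_stage1_single_class_errors(self, tiny_cohort):
        lgg_only = [r for r in tiny_cohort if r.grade != "IV"]
        with pytest.raises(ValueError):
            train_stage1(lgg_only, ClassifierConfig(**QUICK))

    def test_stage2_rejects_hgg(self, tiny_cohort):
        with pytest.raises(ValueError):
            train_stage2(tiny_cohort, ClassifierConfig(**QUICK))

    def test_stage2_deeper_than_stage1(self):
        assert STAGE2_RESIDUAL_BLOCKS >= STAGE1_CONV_LAYERS

    def test_training_runs_and_records_loss(self, tiny_cohort):
        model = train_stage1(tiny_cohort, ClassifierConfig(**QUICK, seed=1))
        assert len(model.loss_history) == 2
        p = model.case_probability(tiny_cohort[0])
        assert 0.0 <= p <= 1.0

    def test_cascade_short_circuit_and_tie(self, tiny_cohort):
        cfg = ClassifierConfig(**QUICK)

        class Stub:
            def __init__(self, prob):
                self.prob = prob
                self.config = cfg
                self.calls = 0

            def case_probability(self, record):
                self.calls += 1
                return self.prob

        rec = tiny_cohort[0]
        s1, s2 = Stub(1.0), Stub(0.0)
        assert predict_cascade(rec, s1, s2) == "IV"
        assert s2.calls == 0  # stage 2 never invoked for an HGG verdict
        # exact 0.5 ties break to the higher grade
        assert predict_cascade(rec, Stub(0.4), Stub(0.5)) == "III"
        assert predict_cascade(rec, Stub(0.4), Stub(0.49)) == "II"

    def test_cascade_requires_cellularity_when_fused(self, tiny_cohort):
        cfg = ClassifierConfig(**QUICK)

        class Stub:
            config = cfg

            def case_probability(self, record):
                return 1.0

        rec = tiny_cohort[0]
        bare = CaseRecord(rec.case_id, rec.grade, rec.histology, rec.idh,
                          rec.atrx, rec.codel_1p19q, rec.mgmt,
                          image=rec.image, mask=rec.mask, cellularity=None)
        with pytest.raises(ValueError, match="cellularity"):
            predict_cascade(bare, Stub(), Stub())


def test_label_shuffle_gives_chance_accuracy():
    """Training on permuted grade labels yields chance-level held-out
    accuracy: the nets cannot memorize their way to signal."""
    spec = SyntheticCohortSpec(n_cases_per_class=(25, 25, 50), roi_size=64,
                               seed=31)
    records = generate_cohort(spec)
    rng = np.random.default_rng(32)
    shuffled_grades = [r.grade for r in records]
    rng.shuffle(shuffled_grades)
    shuffled = []
    for rec, g in zip(records, shuffled_grades):
        shuffled.append(CaseRecord(
            rec.case_id, g, "GBM" if g == "IV" else rec.histology,
            rec.idh, rec.atrx, rec.codel_1p19q, rec.mgmt,
            image=rec.image, mask=rec.mask, cellularity=rec.cellularity,
        ))
    idx = rng.permutation(len(shuffled))
    train = [shuffled[i] for i in idx[:80]]
    test = [shuffled[i] for i in idx[80:]]
    model = train_stage1(train, ClassifierConfig(epochs=8, input_size=32,
                                                 seed=33))
    # the original cohort is balanced HGG vs LGG, so chance is 0.5
    acc = np.mean([
        (model.case_probability(r) >= 0.5) == (r.grade == "IV") for r in test
    ])
    assert 0.35 <= acc <= 0.65


class TestClassifyMolecular:
    def test_feature_validation(self, tiny_cohort):
        with pytest.raises(ValueError):
            classify_molecular(tiny_cohort, "idh", features=())
        with pytest.raises(ValueError):
            classify_molecular(tiny_cohort, "idh", features=("bogus",))
        with pytest.raises(ValueError):
            classify_molecular(tiny_cohort, "grade")

    def test_single_class_target_errors(self, tiny_cohort):
        for r in tiny_cohort:
            r.atrx = "WT"
        with pytest.raises(ValueError):
            classify_molecular(tiny_cohort, "atrx", repeats=1)

    def test_report_structure(self, tiny_cohort):
        rep = classify_molecular(tiny_cohort, "idh",
                                 features=("cellularity", "grade"),
                                 repeats=2, seed=0)
        assert rep.task == "molecular:idh"
        assert len(rep.per_fold_accuracy) == 10
        assert rep.confusion_matrix.sum() == 2 * len(tiny_cohort)

    def test_image_summary_features_shape(self, tiny_cohort):
        feats = image_summary_features(tiny_cohort[0])
        assert feats.shape == (8,)
        assert feats[6] >= 1  # nuclei count

    def test_grade_feature_beats_class_prior(self):
        """With IDH strongly grade-linked, grade as a feature beats the
        majority-class rate, and adding histology+grade to the image
        features does not reduce accuracy by more than 2%."""
        priors = {
            "II": {"idh": 0.9, "atrx": 0.5, "codel_1p19q": 0.4, "mgmt": 0.6},
            "III": {"idh": 0.9, "atrx": 0.5, "codel_1p19q": 0.35, "mgmt": 0.6},
            "IV": {"idh": 0.1, "atrx": 0.15, "codel_1p19q": 0.02, "mgmt": 0.45},
        }
        spec = SyntheticCohortSpec(n_cases_per_class=(30, 30, 30),
                                   molecular_priors=priors, roi_size=48,
                                   seed=41)
        records = generate_cohort(spec)
        y = [r.idh == "MT" for r in records]
        majority = max(np.mean(y), 1 - np.mean(y))
        rep_grade = classify_molecular(records, "idh", features=("grade",),
                                       repeats=3, seed=0)
        assert rep_grade.mean_accuracy > majority
        rep_img = classify_molecular(records, "idh",
                                     features=("image", "cellularity"),
                                     repeats=3, seed=0)
        rep_all = classify_molecular(
            records, "idh",
            features=("image", "cellularity", "histology", "grade"),
            repeats=3, seed=0)
        assert rep_all.mean_accuracy >= rep_img.mean_accuracy - 0.02
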