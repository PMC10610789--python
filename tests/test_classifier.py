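import numpy as np
import pytest

from texspec.classifier import (
    ClassifierModel,
    ClassPrototype,
    ConfusionMatrix,
    SamplingConfig,
    classify,
    efficiency,
    evaluate,
    learn,
    mean_spectrum,
    sample_subimages,
    spectrum_distance,
)
from texspec.core import ObservationWindow
from texspec.spectrum import TextureSpectrum, texture_spectrum
from texspec.synth import make_database


def delta_spectrum(k, window=(3, 3)):
    w = ObservationWindow(*window)
    return TextureSpectrum(window=w, probs={k: 1.0}, K=w.K)


@pytest.fixture
def small_db():
    return make_database(4, 128, 128, seed=7)


@pytest.fixture
def small_cfg():
    return SamplingConfig(sub_rows=64, sub_cols=64, n_train=20, n_test=20, seed=7)


class TestSampleSubimages:
    def test_count_shape_and_interior(self, rng):
        img = rng.integers(0, 2, size=(300, 300), dtype=np.uint8)
        cfg = SamplingConfig(sub_rows=150, sub_cols=150, seed=1)
        subs = sample_subimages(img, cfg, 100)
        assert len(subs) == 100
        assert all(s.shape == (150, 150) for s in subs)

    def test_deterministic_for_fixed_seed(self, rng):
        img = rng.integers(0, 2, size=(64, 64), dtype=np.uint8)
        cfg = SamplingConfig(sub_rows=16, sub_cols=16, seed=5)
        first = sample_subimages(img, cfg, 10)
        second = sample_subimages(img, cfg, 10)
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a, b)

    def test_zero_count(self, rng):
        img = rng.integers(0, 2, size=(8, 8), dtype=np.uint8)
        assert sample_subimages(img, SamplingConfig(4, 4), 0) == []

    def test_subimage_too_large(self):
        with pytest.raises(ValueError, match="does not fit"):
            sample_subimages(np.zeros((8, 8), dtype=np.uint8), SamplingConfig(9, 4), 1)


class TestMeanSpectrum:
    def test_mean_of_one(self):
        spec = delta_spectrum(3)
        assert mean_spectrum([spec]).probs == spec.probs

    def test_mean_of_two_deltas(self):
        mean = mean_spectrum([delta_spectrum(0), delta_spectrum(21)])
        assert mean.probs == {0: 0.5, 21: 0.5}

    def test_mismatched_spaces_rejected(self):
        with pytest.raises(ValueError):
            mean_spectrum([delta_spectrum(0, (3, 3)), delta_spectrum(0, (5, 5))])


class TestDistances:
    def test_zero_for_identical(self):
        a = delta_spectrum(5)
        for metric in ("euclidean", "manhattan", "chi2"):
            assert spectrum_distance(a, a, metric) == 0.0

    def test_euclidean_on_disjoint_deltas(self):
        d = spectrum_distance(delta_spectrum(0), delta_spectrum(21))
        assert d == pytest.approx(np.sqrt(2.0))

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            spectrum_distance(delta_spectrum(0), delta_spectrum(1), "cosine")


class TestLearn:
    def test_single_subimage_prototype_is_its_spectrum(self, small_db):
        cfg = SamplingConfig(sub_rows=64, sub_cols=64, n_train=1, n_test=1, seed=3)
        model = learn(small_db, (3, 3), cfg)
        label, img = small_db[0]
        sub = sample_subimages(img, cfg, 1, rng=np.random.default_rng([cfg.seed, 0]))[0]
        assert model.prototypes[0].spectrum.probs == texture_spectrum(sub, (3, 3)).probs

    def test_prototypes_normalized(self, small_db, small_cfg):
        model = learn(small_db, (3, 3), small_cfg)
        for proto in model.prototypes:
            assert abs(sum(proto.spectrum.probs.values()) - 1.0) <= 1e-9

    def test_duplicate_labels_rejected(self, small_db, small_cfg):
        doubled = [("same", small_db[0][1]), ("same", small_db[1][1])]
        with pytest.raises(ValueError, match="duplicate"):
            learn(doubled, (3, 3), small_cfg)

    def test_needs_two_classes(self, small_db, small_cfg):
        with pytest.raises(ValueError):
            learn(small_db[:1], (3, 3), small_cfg)


def _model_from_prototypes(prototypes, window=(3, 3)):
    return ClassifierModel(
        window=ObservationWindow(*window),
        prototypes=prototypes,
        distance="euclidean",
        sampling=SamplingConfig(8, 8, n_train=1, n_test=1, seed=0),
    )


class TestClassify:
    def test_exact_match_has_zero_distance(self):
        # Constant images have delta spectra; a matching test image must land
        # on its own prototype with distance 0.
        protos = [
            ClassPrototype("black", delta_spectrum(0)),
            ClassPrototype("white", delta_spectrum(21)),
        ]
        model = _model_from_prototypes(protos)
        label, distances = classify(np.ones((16, 16), dtype=np.uint8), model)
        assert label == "white"
        assert distances["white"] == 0.0
        assert distances["black"] > 0.0

    def test_tie_broken_by_model_order(self):
        protos = [
            ClassPrototype("first", delta_spectrum(0)),
            ClassPrototype("twin", delta_spectrum(0)),
        ]
        model = _model_from_prototypes(protos)
        label, _ = classify(np.zeros((16, 16), dtype=np.uint8), model)
        assert label == "first"


class TestEvaluateAndEfficiency:
    def test_perfect_on_training_images(self, small_db, small_cfg):
        model = learn(small_db, (5, 5), small_cfg)
        matrix = evaluate(model, small_db)
        np.testing.assert_array_equal(matrix.entries, np.eye(4, dtype=np.int64))
        assert efficiency(matrix) == 100.0

    def test_empty_test_list(self, small_db, small_cfg):
        model = learn(small_db, (3, 3), small_cfg)
        matrix = evaluate(model, [])
        assert matrix.entries.sum() == 0
        assert efficiency(matrix) == 0.0

    def test_unknown_label_rejected(self, small_db, small_cfg):
        model = learn(small_db, (3, 3), small_cfg)
        with pytest.raises(ValueError, match="not a model class"):
            evaluate(model, [("mystery", small_db[0][1])])

    def test_identity_matrix_efficiency(self):
        mc = ConfusionMatrix(labels=[f"c{i}" for i in range(12)],
                             entries=np.eye(12, dtype=np.int64))
        assert efficiency(mc) == 100.0

    def test_zero_diagonal(self):
        entries = np.zeros((3, 3), dtype=np.int64)
        entries[0, 1] = entries[1, 2] = entries[2, 0] = 1
        assert efficiency(ConfusionMatrix(labels=list("abc"), entries=entries)) == 0.0

    def test_fractional_efficiency(self):
        entries = np.zeros((33, 33), dtype=np.int64)
        entries[np.arange(28), np.arange(28)] = 1
        mc = ConfusionMatrix(labels=[f"c{i}" for i in range(33)], entries=entries)
        assert efficiency(mc) == pytest.approx(28 / 33 * 100)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(labels=["a", "b"], entries=np.zeros((3, 3), dtype=int))


class TestProtocolProperties:
    def test_end_to_end_determinism(self, small_db, small_cfg):
        runs = []
        for _ in range(2):
            model = learn(small_db, (3, 3), small_cfg)
            matrix = evaluate(model, small_db)
            runs.append((model, matrix))
        (m1, c1), (m2, c2) = runs
        for p1, p2 in zip(m1.prototypes, m2.prototypes):
            assert p1.spectrum.probs == p2.spectrum.probs
        np.testing.assert_array_equal(c1.entries, c2.entries)

    @pytest.mark.parametrize("seed", range(5))
    def test_self_consistency_at_5x5(self, seed):
        db = make_database(4, 128, 128, seed=seed)
        cfg = SamplingConfig(sub_rows=64, sub_cols=64, n_train=20, n_test=20, seed=seed)
        model = learn(db, (5, 5), cfg)
        assert efficiency(evaluate(model, db)) == 100.0

    def test_efficiency_invariant_under_class_permutation(self, small_db, small_cfg):
        base = efficiency(evaluate(learn(small_db, (3, 3), small_cfg), small_db))
        perm = [small_db[i] for i in (2, 0, 3, 1)]
        shuffled = efficiency(evaluate(learn(perm, (3, 3), small_cfg), perm))
        assert shuffled == base

    @pytest.mark.parametrize("seed", range(3))
    def test_hard_database_degrades_small_windows(self, seed):
        db = make_database(8, 160, 160, seed=seed, hard=True)
        cfg = SamplingConfig(sub_rows=60, sub_cols=60, n_train=20, n_test=20, seed=seed)
        effs = {}
        for window in ((3, 3), (5, 5)):
            model = learn(db, window, cfg)
            effs[window] = efficiency(evaluate(model, db))
        assert effs[(3, 3)] <= effs[(5, 5)]
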