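"""The dissimilarity-space quadratic DAB detector."""

import numpy as np
import pytest

from stainseg.config import PipelineConfig
from stainseg.dab import (
    DabClassifier,
    LabeledPixelSet,
    assemble_training_set,
    cross_validate,
    dab_mask,
    fit_quadratic,
    learning_curve,
    load_classifier,
    predict_classes,
    save_classifier,
    select_prototypes,
    to_dissimilarity,
    train_classifier,
)
from stainseg.exceptions import InsufficientDataError, InvalidInputError, NotFittedError
from stainseg.labels import STAIN_CLASS_ORDER, StainClass, TissueClass
from stainseg.phantom import (
    DEFAULT_STAIN_COLORS,
    PhantomSpec,
    default_training_spec,
    generate_phantom,
    generate_training_regions,
)
from stainseg.preprocess import preprocess_image


def _toy_set(rng, n_per_class=60, spread=0.01):
    """Well-separated 3-class pixel set (means far apart relative to spread)."""
    means = {
        StainClass.HEMATOXYLIN: (0.6, 0.65, 0.85),
        StainClass.DAB: (0.45, 0.3, 0.15),
        StainClass.LUMEN: (0.95, 0.95, 0.95),
    }
    feats, labels = [], []
    for c, mu in means.items():
        feats.append(
            np.clip(rng.normal(mu, spread, size=(n_per_class, 3)), 0, 1)
        )
        labels.append(np.full(n_per_class, int(c)))
    return LabeledPixelSet(np.concatenate(feats), np.concatenate(labels))


class TestAssembleTrainingSet:
    def test_counts_per_class(self, rng):
        img = rng.random((10, 10, 3))
        mask = np.zeros((10, 10), dtype=np.uint8)
        flat = mask.ravel()
        flat[:30] = 1
        flat[30:60] = 2
        flat[60:90] = 3
        out = assemble_training_set([img], [mask])
        assert len(out.labels) == 90
        assert all(v == 30 for v in out.class_counts.values())

    def test_all_unlabeled_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            assemble_training_set(
                [rng.random((5, 5, 3))], [np.zeros((5, 5), dtype=np.uint8)]
            )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            assemble_training_set(
                [rng.random((5, 5, 3))], [np.ones((6, 5), dtype=np.uint8)]
            )

    def test_phantom_class_means_match_generating_colors(self, cfg):
        out = generate_phantom(default_training_spec(3))
        images, masks = generate_training_regions([out], 500, seed=1)
        train = assemble_training_set(
            [preprocess_image(images[0], cfg)], masks
        )
        feats = np.asarray(train.features)
        labels = np.asarray(train.labels)
        dab_mean = feats[labels == int(StainClass.DAB)].mean(axis=0)
        lum_mean = feats[labels == int(StainClass.LUMEN)].mean(axis=0)
        assert np.allclose(
            dab_mean, DEFAULT_STAIN_COLORS[TissueClass.DAB], atol=0.06
        )
        assert np.allclose(
            lum_mean, DEFAULT_STAIN_COLORS[TissueClass.LUMEN], atol=0.06
        )
        # hematoxylin pools stroma and nuclei: its mean lies between them
        hem = feats[labels == int(StainClass.HEMATOXYLIN)].mean(axis=0)
        lo = np.minimum(
            DEFAULT_STAIN_COLORS[TissueClass.NUCLEI],
            DEFAULT_STAIN_COLORS[TissueClass.STROMA],
        )
        hi = np.maximum(
            DEFAULT_STAIN_COLORS[TissueClass.NUCLEI],
            DEFAULT_STAIN_COLORS[TissueClass.STROMA],
        )
        assert np.all(hem > lo - 0.06) and np.all(hem < hi + 0.06)


class TestPrototypes:
    def test_counts_and_determinism(self, rng):
        train = _toy_set(rng)
        p1 = select_prototypes(train, 5, seed=7)
        p2 = select_prototypes(train, 5, seed=7)
        assert p1.prototypes.shape == (15, 3)
        assert np.array_equal(p1.prototypes, p2.prototypes)
        assert np.array_equal(p1.indices, p2.indices)

    def test_exhaustive_sampling_returns_whole_class(self, rng):
        train = _toy_set(rng, n_per_class=8)
        protos = select_prototypes(train, 8, seed=0)
        labels = np.asarray(train.labels)
        for c in STAIN_CLASS_ORDER:
            got = protos.prototypes[protos.source_labels == int(c)]
            want = np.asarray(train.features)[labels == int(c)]
            assert np.array_equal(np.sort(got, axis=0), np.sort(want, axis=0))

    def test_too_many_prototypes_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            select_prototypes(_toy_set(rng, n_per_class=4), 5, seed=0)


class TestDissimilarity:
    def test_zero_and_unit_distances(self, rng):
        train = _toy_set(rng)
        protos = select_prototypes(train, 2, seed=0)
        d = to_dissimilarity(protos.prototypes, protos)
        assert np.allclose(np.diag(d), 0.0)

        one = select_prototypes(train, 1, seed=0)
        one = type(one)(
            prototypes=np.array([[1.0, 0.0, 0.0]]),
            source_labels=np.array([1]),
            seed=0,
        )
        d = to_dissimilarity(np.array([[0.0, 0.0, 0.0]]), one)
        assert np.allclose(d, [[1.0]])

    def test_matches_bruteforce_oracle(self, rng):
        objs = rng.random((8, 3))
        train = _toy_set(rng)
        protos = select_prototypes(train, 2, seed=1)  # 6 prototypes
        protos = type(protos)(
            prototypes=protos.prototypes[:4],
            source_labels=protos.source_labels[:4],
            seed=1,
        )
        got = to_dissimilarity(objs, protos)
        expected = np.empty((8, 4))
        for i in range(8):
            for j in range(4):
                diff = objs[i] - protos.prototypes[j]
                expected[i, j] = np.sqrt(np.sum(diff * diff))
        assert np.allclose(got, expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        train = _toy_set(rng)
        protos = select_prototypes(train, 2, seed=0)
        with pytest.raises(InvalidInputError):
            to_dissimilarity(rng.random((5, 4)), protos)


class TestQuadraticClassifier:
    def test_separated_gaussians_have_zero_resubstitution_error(self, rng):
        # three classes in a 2-D dissimilarity space, means 5 sigma apart
        sigma = 0.1
        means = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])  # >= 5 sigma
        d, labels = [], []
        for c, mu in zip(STAIN_CLASS_ORDER, means):
            d.append(rng.normal(mu, sigma, size=(300, 2)))
            labels.append(np.full(300, int(c)))
        d = np.abs(np.concatenate(d))
        labels = np.concatenate(labels)
        clf = fit_quadratic(d, labels)
        post = clf.posteriors(d)
        pred = np.asarray(clf.class_order)[np.argmax(post, axis=1)]
        assert np.mean(pred != labels) == 0.0
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_equal_covariance_boundary_is_the_midpoint(self, rng):
        # two classes, one-dimensional dissimilarity, identical spread
        a = 0.2 + rng.normal(0, 0.01, 500)
        b = 0.8 + rng.normal(0, 0.01, 500)
        d = np.concatenate([a, b])[:, None]
        labels = np.concatenate([np.full(500, 1), np.full(500, 2)])
        clf = fit_quadratic(d, labels, regularization=1e-4)
        probe = np.array([[0.49], [0.51]])
        post = clf.posteriors(probe)
        pred = np.asarray(clf.class_order)[np.argmax(post, axis=1)]
        assert pred[0] == 1 and pred[1] == 2

    def test_unfitted_classifier_raises(self, rng):
        with pytest.raises(NotFittedError):
            predict_classes(rng.random((4, 3)), DabClassifier())


class TestPredict:
    def test_training_mean_predicted_as_its_class(self, rng, cfg):
        train = _toy_set(rng)
        clf = train_classifier(train, 5, seed=0, cfg=cfg)
        means = {
            StainClass.DAB: (0.45, 0.3, 0.15),
            StainClass.LUMEN: (0.95, 0.95, 0.95),
        }
        for c, mu in means.items():
            pred, post = predict_classes(np.array([mu]), clf)
            assert pred[0] == int(c)
            assert abs(post.sum() - 1.0) < 1e-10

    def test_posteriors_sum_to_one(self, rng, cfg):
        clf = train_classifier(_toy_set(rng), 5, seed=0, cfg=cfg)
        _, post = predict_classes(rng.random((200, 3)), clf)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_phantom_dab_area_recovered(self, cfg, classifier):
        spec = PhantomSpec(seed=31, class_fractions=(0.35, 0.25, 0.20, 0.20))
        out = generate_phantom(spec)
        pre = preprocess_image(out.image, cfg)
        mask = dab_mask(pre, classifier)
        assert abs(mask.mean() - 0.20) <= 0.02


class TestDabMask:
    def test_no_dab_phantom_gives_empty_mask(self, cfg, classifier):
        spec = PhantomSpec(seed=5, class_fractions=(0.45, 0.33, 0.22, 0.0))
        pre = preprocess_image(generate_phantom(spec).image, cfg)
        mask = dab_mask(pre, classifier)
        assert mask.mean() < 0.005

    def test_all_dab_phantom_gives_full_mask(self, cfg, classifier):
        spec = PhantomSpec(seed=6, class_fractions=(0.0, 0.0, 0.0, 1.0))
        pre = preprocess_image(generate_phantom(spec).image, cfg)
        assert dab_mask(pre, classifier).all()

    def test_mask_consistent_with_predictions(self, rng, cfg, classifier):
        img = np.clip(rng.random((12, 12, 3)), 0, 1)
        mask = dab_mask(img, classifier)
        labels, _ = predict_classes(img.reshape(-1, 3), classifier)
        assert np.array_equal(
            mask, (labels == int(StainClass.DAB)).reshape(12, 12)
        )


class TestCrossValidation:
    def test_separable_set_has_zero_error(self, rng, cfg):
        err = cross_validate(_toy_set(rng, n_per_class=100), cfg, folds=10)
        assert err == 0.0

    def test_permuted_labels_give_chance_error(self, rng, cfg):
        train = _toy_set(rng, n_per_class=120)
        perm = LabeledPixelSet(
            train.features, rng.permutation(np.asarray(train.labels))
        )
        err = cross_validate(perm, cfg, folds=10)
        assert abs(err - 2.0 / 3.0) < 0.1

    def test_default_fold_count_is_ten(self):
        import inspect

        assert inspect.signature(cross_validate).parameters["folds"].default == 10

    def test_class_smaller_than_folds_rejected(self, rng, cfg):
        with pytest.raises(InsufficientDataError):
            cross_validate(_toy_set(rng, n_per_class=5), cfg, folds=10)

    def test_no_leakage_sentinel_never_a_prototype(self, rng, cfg):
        """A unique sentinel pixel must never serve as a prototype in the
        fold where it is held out."""
        train = _toy_set(rng, n_per_class=50)
        feats = np.asarray(train.features).copy()
        sentinel = np.array([0.123456, 0.654321, 0.111111])
        feats[0] = sentinel
        train = LabeledPixelSet(feats, train.labels)
        _, fold_results = cross_validate(train, cfg, folds=5, return_folds=True)
        for fr in fold_results:
            if 0 in fr.test_indices:
                assert 0 not in fr.prototype_indices


class TestLearningCurve:
    def test_error_decreases_on_separable_data(self, rng):
        train = _toy_set(rng, n_per_class=150, spread=0.02)
        sizes = [9, 60, 300]
        errs = learning_curve(train, sizes, repeats=3, seed=4)
        assert errs[-1] <= errs[0] + 0.05

    def test_fixed_seed_reproduces_curve(self, rng):
        train = _toy_set(rng, n_per_class=60)
        a = learning_curve(train, [12, 60], repeats=2, seed=9)
        b = learning_curve(train, [12, 60], repeats=2, seed=9)
        assert np.array_equal(a, b)


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, rng, cfg, tmp_path):
        clf = train_classifier(_toy_set(rng), 5, seed=0, cfg=cfg)
        path = tmp_path / "model.json"
        save_classifier(clf, path)
        clf2 = load_classifier(path)
        x = rng.random((50, 3))
        _, p1 = predict_classes(x, clf)
        _, p2 = predict_classes(x, clf2)
        assert np.allclose(p1, p2, atol=1e-12)
        assert clf2.config_fingerprint == cfg.fingerprint()
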