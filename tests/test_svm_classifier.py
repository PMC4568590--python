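"""Training-set assembly, whitened linear SVM, resampling error rates, and
ROC cutoffs."""

import numpy as np
import pytest

from smorf import svm_classifier as svm
from smorf.orf_catalog import ORFRecord
from smorf.io_formats import GenomeInterval
from Bio.Seq import Seq


def _orf(oid, category, n_codons=40):
    seq = "ATG" + "GCA" * (n_codons - 2) + "TAA"
    iv = GenomeInterval("chr1", 0, len(seq), "+")
    o = ORFRecord(id=oid, transcript_ids=["t"], genomic_intervals=[iv],
                  transcript_start=0, transcript_end=len(seq), nt_seq=seq,
                  aa_seq=str(Seq(seq[:-3]).translate()))
    o.category = category
    return o


class TestBuildTrainingSets:
    def _inputs(self):
        catalog = [_orf("pos1", "annotated"), _orf("pos2", "annotated"),
                   _orf("neg1", "ncRNA"), _orf("neg2", "ncRNA"),
                   _orf("long", "annotated", n_codons=150)]
        features = {o.id: np.array([8.0, 3, 1, 1]) for o in catalog}
        coverage = {o.id: 0.9 for o in catalog}
        return catalog, features, coverage

    def test_positive_and_negative_rules(self):
        catalog, features, coverage = self._inputs()
        ts = svm.build_training_sets(
            catalog, features, curated_small_protein_ids={"pos1", "pos2",
                                                          "long"},
            coverage=coverage)
        assert sorted(ts.positives) == ["pos1", "pos2"]  # 'long' > 101 aa
        assert sorted(ts.negatives) == ["neg1", "neg2"]

    def test_negative_score_excluded_from_positives(self):
        catalog, features, coverage = self._inputs()
        features["pos1"] = np.array([-2.0, 3, 1, 1])
        ts = svm.build_training_sets(catalog, features,
                                     {"pos1", "pos2"}, coverage=coverage)
        assert ts.positives == ["pos2"]

    def test_cds_overlapping_ncrna_excluded_from_negatives(self):
        catalog, features, coverage = self._inputs()
        ts = svm.build_training_sets(catalog, features, {"pos1", "pos2"},
                                     coverage=coverage,
                                     cds_overlap_bp={"neg1": 1})
        assert ts.negatives == ["neg2"]

    def test_empty_class_raises(self):
        catalog, features, coverage = self._inputs()
        with pytest.raises(ValueError, match="empty training class"):
            svm.build_training_sets(catalog, features, set(),
                                    coverage=coverage)


def _toy_clouds(rng, n=40, delta=6.0):
    Xp = rng.normal(loc=[delta, delta], scale=1.0, size=(n, 2))
    Xn = rng.normal(loc=[0.0, 0.0], scale=1.0, size=(n, 2))
    return Xp, Xn


class TestFit:
    def test_separable_clouds_no_training_errors(self, rng):
        Xp, Xn = _toy_clouds(rng)
        X = np.vstack([Xp, Xn])
        y = np.array([True] * len(Xp) + [False] * len(Xn))
        model = svm.fit(X, y)
        assert (model.predict(X) == y).all()

    def test_label_flip_mirrors_decision(self, rng):
        Xp, Xn = _toy_clouds(rng)
        X = np.vstack([Xp, Xn])
        y = np.array([True] * len(Xp) + [False] * len(Xn))
        m1 = svm.fit(X, y)
        m2 = svm.fit(X, ~y)
        assert np.allclose(m1.weights, -m2.weights, atol=1e-4)

    def test_duplicated_training_set_gives_identical_model(self, rng):
        Xp, Xn = _toy_clouds(rng)
        X = np.vstack([Xp, Xn])
        y = np.array([True] * len(Xp) + [False] * len(Xn))
        m1 = svm.fit(X, y)
        m2 = svm.fit(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(m1.weights, m2.weights, atol=1e-6)
        assert m1.bias == pytest.approx(m2.bias, abs=1e-6)

    def test_constant_feature_handled_with_unit_scale(self, rng):
        Xp, Xn = _toy_clouds(rng)
        X = np.vstack([Xp, Xn])
        X = np.column_stack([X, np.full(len(X), 7.0)])
        y = np.array([True] * len(Xp) + [False] * len(Xn))
        model = svm.fit(X, y)
        assert model.scale[2] == 1.0

    def test_informative_feature_dominates_weights(self, rng):
        """When only the selection score separates the classes, its weight
        dominates the others."""
        n = 60
        score_p = rng.normal(8, 1, n)
        score_n = rng.normal(-2, 1, n)
        other = rng.normal(0, 1, (2 * n, 3))
        X = np.column_stack([np.concatenate([score_p, score_n]), other])
        y = np.array([True] * n + [False] * n)
        model = svm.fit(X, y)
        assert all(abs(model.weights[0]) > abs(w)
                   for w in model.weights[1:])


class TestCrossValidate:
    def test_well_separated_features_low_error(self, rng):
        Xp, Xn = _toy_clouds(rng, n=100, delta=6.0)
        fnr, fpr = svm.cross_validate(Xp, Xn, runs=30, seed=5)
        assert fnr.mean() <= 0.05
        assert fpr.mean() <= 0.01

    def test_no_signal_gives_total_error_near_one(self, rng):
        Xp = rng.normal(size=(60, 2))
        Xn = rng.normal(size=(60, 2))
        fnr, fpr = svm.cross_validate(Xp, Xn, runs=30, seed=5)
        assert fnr.mean() + fpr.mean() == pytest.approx(1.0, abs=0.25)

    def test_fixed_seed_is_bit_identical(self, rng):
        Xp, Xn = _toy_clouds(rng, n=50)
        a = svm.cross_validate(Xp, Xn, runs=10, seed=9)
        b = svm.cross_validate(Xp, Xn, runs=10, seed=9)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()


class TestRocCutoff:
    def test_separated_scores_exhaustive_scan(self):
        t = svm.roc_min_avg_error_cutoff([9, 12], [1, 2])
        assert t == 5.5

    def test_interleaved_scores_average_error_half(self):
        pos = [1, 3, 5, 7]
        neg = [2, 4, 6, 8]
        t = svm.roc_min_avg_error_cutoff(pos, neg)
        fnr = np.mean([p < t for p in pos])
        fpr = np.mean([n >= t for n in neg])
        assert (fnr + fpr) / 2 == pytest.approx(0.5, abs=0.13)

    def test_tied_singletons_take_smallest_threshold(self):
        assert svm.roc_min_avg_error_cutoff([5], [5]) == 5

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            svm.roc_min_avg_error_cutoff([], [1])

    def test_matches_bruteforce_grid(self, rng):
        pos = rng.normal(5, 2, 30)
        neg = rng.normal(0, 2, 30)
        t = svm.roc_min_avg_error_cutoff(pos, neg)
        best = min((np.mean(pos < c) + np.mean(neg >= c)) / 2
                   for c in np.linspace(-10, 15, 20001))
        got = (np.mean(pos < t) + np.mean(neg >= t)) / 2
        assert got == pytest.approx(best, abs=1e-9)


def test_whitening_reproduces_fit_time_decisions(rng):
    Xp, Xn = _toy_clouds(rng)
    X = np.vstack([Xp, Xn])
    y = np.array([True] * len(Xp) + [False] * len(Xn))
    model = svm.fit(X, y)
    again = model.predict(X)
    assert (again == model.predict(X.copy())).all()
    d = svm.LinearModel.from_dict(model.to_dict())
    assert (d.predict(X) == again).all()
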