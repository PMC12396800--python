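"""Cross-validated family comparison, final boosted model, scoring, and
feature importance."""

import numpy as np
import pytest
import scipy.sparse as sp

from nidphen.corpus import ClinicalNote
from nidphen.featurize import DocTermMatrix, Vocabulary
from nidphen.lexicon import load_demo_lexicon
from nidphen.model import (
    ModelBundle,
    cv_compare,
    feature_importance,
    predict,
    train_final,
)
from nidphen.textprep import load_default_stopwords


def make_dtm(counts, terms=None):
    counts = np.asarray(counts)
    terms = terms or [f"t{j}" for j in range(counts.shape[1])]
    vocab = Vocabulary(tuple(terms), (1,), 1)
    return DocTermMatrix(
        tuple(f"n{i}" for i in range(counts.shape[0])), vocab,
        sp.csr_matrix(counts),
    )


def strong_signal_data(seed=0, n=400, n_patients=120):
    rng = np.random.default_rng(seed)
    patients = rng.integers(0, n_patients, size=n)
    pat_label = rng.random(n_patients) < 0.3
    y = pat_label[patients]
    signal = np.where(y, rng.poisson(4.0, n) + 1, rng.poisson(0.2, n))
    noise = rng.poisson(1.0, (n, 10))
    X = np.column_stack([signal, noise])
    groups = [f"P{p}" for p in patients]
    return make_dtm(X), y, groups


class TestCvCompare:
    def test_dominant_signal_all_families_strong(self):
        X, y, groups = strong_signal_data()
        res = cv_compare(X, y, groups, k=5, seed=0)
        assert (res.table.mean(axis=1) > 0.9).all()
        assert res.winner in res.table.index

    def test_winner_maximizes_mean_auprc(self):
        X, y, groups = strong_signal_data(seed=1)
        res = cv_compare(X, y, groups, k=3, seed=0)
        means = res.table.mean(axis=1)
        assert means[res.winner] == means.max()

    def test_infeasible_folds_rejected(self):
        X, y, groups = strong_signal_data(seed=2, n=30, n_patients=8)
        with pytest.raises(ValueError, match="folds"):
            cv_compare(X, y, groups, k=25, seed=0)

    def test_seed_determinism(self):
        X, y, groups = strong_signal_data(seed=3)
        a = cv_compare(X, y, groups, k=4, seed=5)
        b = cv_compare(X, y, groups, k=4, seed=5)
        assert a.winner == b.winner
        assert a.table.equals(b.table)


@pytest.fixture(scope="module")
def toy_bundle():
    lex = load_demo_lexicon()
    stop = load_default_stopwords()
    X = make_dtm(
        np.array([[3, 0], [4, 1], [5, 0], [0, 2], [0, 1], [1, 3]] * 4),
        terms=["meningitis", "headache"],
    )
    y = [True, True, True, False, False, False] * 4
    return train_final(X, y, lexicon=lex, stopwords=stop, seed=0)


class TestTrainFinal:
    def test_separable_training_auroc_one(self, toy_bundle):
        from nidphen.evaluate import rank_metrics

        X = np.array([[3, 0], [4, 1], [5, 0], [0, 2], [0, 1], [1, 3]] * 4,
                     dtype=float)
        y = [True, True, True, False, False, False] * 4
        scores = toy_bundle.classifier.predict_proba(X)[:, 1]
        assert rank_metrics(scores, y)["auroc"] == 1.0

    def test_class_weight_recorded(self):
        lex = load_demo_lexicon()
        stop = load_default_stopwords()
        n = 200
        y = [True] * 32 + [False] * 168  # 16% positive
        X = make_dtm(np.arange(n).reshape(-1, 1).astype(float))
        bundle = train_final(X, y, lexicon=lex, stopwords=stop, seed=0)
        assert bundle.training_meta["scale_pos_weight"] == pytest.approx(
            168 / 32)  # = 5.25

    def test_single_class_rejected(self):
        lex = load_demo_lexicon()
        with pytest.raises(ValueError):
            train_final(make_dtm(np.ones((5, 1))), [True] * 5,
                        lexicon=lex, stopwords=frozenset())

    def test_refit_same_seed_same_scores(self):
        lex = load_demo_lexicon()
        stop = load_default_stopwords()
        rng = np.random.default_rng(0)
        X = make_dtm(rng.poisson(1.0, (100, 5)))
        y = (rng.random(100) < 0.3).tolist()
        y[0], y[1] = True, False
        probe = rng.poisson(1.0, (10, 5)).astype(float)
        s1 = train_final(X, y, lexicon=lex, stopwords=stop,
                         seed=3).classifier.predict_proba(probe)[:, 1]
        s2 = train_final(X, y, lexicon=lex, stopwords=stop,
                         seed=3).classifier.predict_proba(probe)[:, 1]
        assert (s1 == s2).all()


class TestPredict:
    def test_no_lexicon_match_flagged(self, toy_bundle):
        notes = [
            ClinicalNote("a", "P1", "bacterial meningitis suspected " * 5),
            ClinicalNote("b", "P2", "entirely unrelated content " * 5),
        ]
        out = predict(toy_bundle, notes)
        assert not out.loc[out.note_id == "a", "no_windows"].item()
        assert out.loc[out.note_id == "b", "no_windows"].item()
        assert out["score"].between(0, 1).all()

    def test_duplicate_note_same_score(self, toy_bundle):
        n = ClinicalNote("a", "P1", "severe headache and meningitis " * 4)
        out = predict(toy_bundle, [n, ClinicalNote("b", "P2", n.text)])
        assert out.score.iloc[0] == out.score.iloc[1]

    def test_note_order_invariance(self, toy_bundle):
        notes = [
            ClinicalNote(f"n{i}", f"P{i}", f"meningitis {'headache ' * i}")
            for i in range(4)
        ]
        fwd = predict(toy_bundle, notes).set_index("note_id")["score"]
        rev = predict(toy_bundle, notes[::-1]).set_index("note_id")["score"]
        assert (fwd.sort_index() == rev.sort_index()).all()


class TestFeatureImportance:
    def test_single_informative_feature_dominates(self, toy_bundle):
        table = feature_importance(toy_bundle, top_k=5)
        assert table.iloc[0]["term"] == "meningitis"

    def test_top_k_larger_than_features(self, toy_bundle):
        table = feature_importance(toy_bundle, top_k=100)
        assert len(table) <= 2
        assert (table["gain"].diff().dropna() <= 0).all()


class TestBundlePersistence:
    def test_save_load_round_trip(self, toy_bundle, tmp_path):
        toy_bundle.save(tmp_path / "bundle")
        loaded = ModelBundle.load(tmp_path / "bundle")
        assert loaded.feature_set.terms == toy_bundle.feature_set.terms
        assert loaded.vocabulary.terms == toy_bundle.vocabulary.terms
        assert loaded.threshold == toy_bundle.threshold
        notes = [ClinicalNote("a", "P1", "meningitis with headache " * 3)]
        assert predict(loaded, notes).score.item() == pytest.approx(
            predict(toy_bundle, notes).score.item(), abs=1e-9)
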