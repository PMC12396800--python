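"""Classifier selection, final gradient-boosted model, and scoring.

Three families — L2 logistic regression, random forest, and gradient
boosting (XGBoost) — are compared by mean AUPRC under patient-grouped,
label-stratified k-fold cross-validation (grouping prevents the same
patient informing both sides of a fold). The winner in the study regime,
and the default final model here, is XGBoost with the positive class
upweighted by the negative:positive ratio.

A trained model travels as a :class:`ModelBundle`: booster + vocabulary +
selected feature set + lexicon + stopwords + threshold, persisted as a
directory of plain-text artifacts, so scoring new notes needs nothing but
the bundle.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold
from xgboost import XGBClassifier

from .corpus import ClinicalNote
from .evaluate import rank_metrics
from .featurize import DocTermMatrix, Vocabulary, vectorize
from .lexicon import RegexLexicon, load_lexicon, match_spans
from .select import FeatureSet
from .textprep import extract_windows, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_XGB_PARAMS",
    "CVResult",
    "ModelBundle",
    "cv_compare",
    "train_final",
    "predict",
    "feature_importance",
]

#: Final-model boosting hyperparameters (none are dictated by the method;
#: these are conventional defaults, all overridable via ``params``).
DEFAULT_XGB_PARAMS: dict = {
    "n_estimators": 300,
    "max_depth": 6,
    "learning_rate": 0.1,
    "tree_method": "hist",
    "n_jobs": 1,
    "eval_metric": "logloss",
}

FAMILY_NAMES = ("logistic_regression", "random_forest", "xgboost")


def _make_family(name: str, seed: int, pos_weight: float):
    if name == "logistic_regression":
        return LogisticRegression(class_weight="balanced", max_iter=1000)
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=200, class_weight="balanced",
            random_state=seed, n_jobs=1,
        )
    if name == "xgboost":
        return XGBClassifier(
            **DEFAULT_XGB_PARAMS, scale_pos_weight=pos_weight, random_state=seed
        )
    raise ValueError(f"unknown model family {name!r}")


@dataclass(frozen=True)
class CVResult:
    """Per-family fold AUPRC table and the winning family."""

    table: pd.DataFrame  # index = family, columns = fold_0..fold_{k-1}
    winner: str

    @property
    def mean_auprc(self) -> pd.Series:
        return self.table.mean(axis=1)


def cv_compare(
    X: DocTermMatrix,
    y: Sequence[bool],
    groups: Sequence[str],
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Patient-grouped, label-stratified k-fold comparison by AUPRC.

    The winner maximizes mean fold AUPRC; an exact tie is broken by
    family-name order and logged.
    """
    yarr = np.asarray(y, dtype=bool)
    garr = np.asarray(groups)
    if k < 2:
        raise ValueError("k must be >= 2")
    mat = X.counts.astype(np.float64)
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    try:
        folds = list(splitter.split(mat, yarr, garr))
    except ValueError as exc:
        raise ValueError(
            f"cannot form {k} stratified patient-grouped folds; "
            f"use fewer folds ({exc})"
        ) from exc
    for _, test_idx in folds:
        if yarr[test_idx].all() or not yarr[test_idx].any():
            raise ValueError(
                f"a fold contains a single class; use fewer than {k} folds"
            )
    rows = {}
    for name in FAMILY_NAMES:
        scores = []
        for fold_i, (tr, te) in enumerate(folds):
            ytr = yarr[tr]
            pos_weight = float((~ytr).sum() / ytr.sum())
            clf = _make_family(name, seed, pos_weight)
            clf.fit(mat[tr], ytr)
            prob = clf.predict_proba(mat[te])[:, 1]
            scores.append(rank_metrics(prob, yarr[te])["auprc"])
        rows[name] = scores
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"fold_{i}" for i in range(k)]
    )
    means = table.mean(axis=1)
    best = means.max()
    tied = sorted(means.index[means == best])
    if len(tied) > 1:
        logger.info("cv_compare tie at AUPRC %.4f between %s; picking %s",
                    best, tied, tied[0])
    winner = tied[0]
    logger.info("cv_compare mean AUPRC: %s -> winner %s",
                means.round(4).to_dict(), winner)
    return CVResult(table=table, winner=winner)


@dataclass
class ModelBundle:
    """Everything needed to score raw notes: classifier, feature set,
    vocabulary, lexicon, stopwords, and the decision threshold."""

    classifier: XGBClassifier
    feature_set: FeatureSet
    vocabulary: Vocabulary
    lexicon: RegexLexicon
    stopwords: frozenset[str]
    threshold: float = 0.5
    seed: int = 0
    buffer: int = 100
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")

    def save(self, directory: str | Path) -> None:
        """Persist as a directory of plain-text artifacts."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        # booster-level save: text JSON, loadable by the sklearn wrapper
        self.classifier.get_booster().save_model(d / "booster.json")
        self.vocabulary.save(d / "vocabulary.txt")
        self.feature_set.save(d / "feature_set.json")
        with (d / "lexicon.tsv").open("w", encoding="utf-8") as fh:
            for p in self.lexicon:
                fh.write(f"{p.pattern_id}\t{p.category}\t{p.pattern}\n")
        (d / "stopwords.txt").write_text(
            "\n".join(sorted(self.stopwords)) + "\n", encoding="utf-8"
        )
        (d / "params.json").write_text(
            json.dumps(
                {
                    "threshold": self.threshold,
                    "seed": self.seed,
                    "buffer": self.buffer,
                    "training_meta": self.training_meta,
                    "n_range": list(self.vocabulary.n_range),
                    "min_doc_freq": self.vocabulary.min_doc_freq,
                },
                indent=2,
            ),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        d = Path(directory)
        params = json.loads((d / "params.json").read_text(encoding="utf-8"))
        clf = XGBClassifier()
        clf.load_model(d / "booster.json")
        vocab = Vocabulary.load(
            d / "vocabulary.txt",
            n_range=tuple(params["n_range"]),
            min_doc_freq=params["min_doc_freq"],
        )
        from .textprep import load_stopwords

        return cls(
            classifier=clf,
            feature_set=FeatureSet.load(d / "feature_set.json"),
            vocabulary=vocab,
            lexicon=load_lexicon(d / "lexicon.tsv"),
            stopwords=load_stopwords(d / "stopwords.txt"),
            threshold=params["threshold"],
            seed=params["seed"],
            buffer=params["buffer"],
            training_meta=params["training_meta"],
        )


def train_final(
    X: DocTermMatrix,
    y: Sequence[bool],
    lexicon: RegexLexicon,
    stopwords: frozenset[str],
    params: dict | None = None,
    seed: int = 0,
    threshold: float = 0.5,
    feature_set: FeatureSet | None = None,
    buffer: int = 100,
    training_meta: dict | None = None,
) -> ModelBundle:
    """Fit the final gradient-boosted classifier on the selected features.

    ``X`` must already be restricted to the selected terms (its vocabulary
    is recorded as the scoring vocabulary). The positive class is weighted
    by ``n_neg / n_pos``.
    """
    yarr = np.asarray(y, dtype=bool)
    if yarr.all() or not yarr.any():
        raise ValueError("y must contain both classes")
    if feature_set is None:
        feature_set = FeatureSet(
            X.vocabulary.terms, {t: 1 for t in X.vocabulary.terms}
        )
    if tuple(X.vocabulary.terms) != tuple(feature_set.terms):
        raise ValueError("X columns must equal feature_set.terms, in order")
    pos_weight = float((~yarr).sum() / yarr.sum())
    merged = {**DEFAULT_XGB_PARAMS, **(params or {})}
    clf = XGBClassifier(**merged, scale_pos_weight=pos_weight, random_state=seed)
    clf.fit(X.counts.astype(np.float64), yarr)
    meta = dict(training_meta or {})
    meta.update(
        {
            "n_train": int(yarr.size),
            "n_positive": int(yarr.sum()),
            "scale_pos_weight": pos_weight,
            "params": {k: v for k, v in merged.items()},
        }
    )
    return ModelBundle(
        classifier=clf,
        feature_set=feature_set,
        vocabulary=X.vocabulary,
        lexicon=lexicon,
        stopwords=stopwords,
        threshold=threshold,
        seed=seed,
        buffer=buffer,
        training_meta=meta,
    )


def featurize_notes(
    notes: Sequence[ClinicalNote],
    lexicon: RegexLexicon,
    stopwords: frozenset[str],
    vocab: Vocabulary,
    buffer: int = 100,
) -> tuple[DocTermMatrix, np.ndarray]:
    """Run notes through matching -> windows -> normalization ->
    vectorization with a fixed vocabulary. Returns the matrix and a
    boolean mask of notes with zero lexicon matches."""
    docs = []
    no_windows = np.zeros(len(notes), dtype=bool)
    for i, note in enumerate(notes):
        spans = match_spans(lexicon, note.text)
        windows = extract_windows(note.text, spans, buffer=buffer)
        no_windows[i] = not windows
        docs.append(normalize(windows, stopwords))
    dtm = vectorize(docs, vocab, row_ids=[n.note_id for n in notes])
    return dtm, no_windows


def predict(bundle: ModelBundle, notes: Sequence[ClinicalNote]) -> pd.DataFrame:
    """Score notes; returns note_id, probability score, binary call
    (``score >= threshold``), and a ``no_windows`` flag for notes with no
    lexicon match (scored on an all-zero feature row)."""
    dtm, no_windows = featurize_notes(
        notes, bundle.lexicon, bundle.stopwords, bundle.vocabulary,
        buffer=bundle.buffer,
    )
    scores = bundle.classifier.predict_proba(dtm.counts.astype(np.float64))[:, 1]
    return pd.DataFrame(
        {
            "note_id": [n.note_id for n in notes],
            "score": scores.astype(float),
            "call": scores >= bundle.threshold,
            "no_windows": no_windows,
        }
    )


def feature_importance(bundle: ModelBundle, top_k: int = 20) -> pd.DataFrame:
    """Top terms by average gain per split, descending.

    Terms never used in a split carry zero gain and are omitted; if fewer
    than ``top_k`` terms were used, the full table is returned.
    """
    booster = bundle.classifier.get_booster()
    gains = booster.get_score(importance_type="gain")
    terms = bundle.feature_set.terms
    rows = []
    for fname, gain in gains.items():
        idx = int(fname[1:]) if fname.startswith("f") else terms.index(fname)
        rows.append((terms[idx], float(gain)))
    rows.sort(key=lambda tg: (-tg[1], tg[0]))
    return pd.DataFrame(rows[:top_k], columns=["term", "gain"])
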