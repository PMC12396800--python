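"""The full phenotyping pipeline as a model/results pair.

:class:`NIDPhenotypingModel` is constructed from a labeled note corpus
plus a lexicon, stopword list, and curation list; :meth:`fit` runs every
stage — length filter, ICD flagging, optional balanced sampling,
patient-disjoint split, window extraction, normalization, n-gram
featurization, L1 stability selection, curation, cross-validated family
comparison, final boosted-tree training, hold-out scoring, and bootstrap
evaluation — and returns a :class:`NIDPhenotypingResults` holding the
fitted bundle, the fold table, the evaluation report with 95% CIs, the
ICD baseline, and a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import corpus as corpus_mod
from . import evaluate as eval_mod
from . import model as model_mod
from . import select as select_mod
from .config import PipelineConfig
from .corpus import ClinicalNote, SplitResult
from .featurize import build_vocabulary, vectorize
from .lexicon import RegexLexicon, load_demo_lexicon, load_lexicon, match_spans
from .select import FeatureSet
from .textprep import extract_windows, load_default_stopwords, load_stopwords, normalize

logger = logging.getLogger(__name__)

__all__ = ["NIDPhenotypingModel", "NIDPhenotypingResults"]


class NIDPhenotypingModel:
    """Neuroinfectious-disease note classifier, specified before fitting.

    Parameters
    ----------
    notes
        Labeled corpus (every note needs ``label`` for training).
    lexicon, stopwords, exclusions
        Lexicon, stopword set and curation exclusion set; each defaults
        to the packaged demo artifact.
    config
        A :class:`~nidphen.config.PipelineConfig`; defaults are the
        study-regime constants.
    """

    def __init__(
        self,
        notes: Sequence[ClinicalNote],
        lexicon: RegexLexicon | None = None,
        stopwords: frozenset[str] | None = None,
        exclusions: frozenset[str] | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        self.notes = list(notes)
        self.config = config or PipelineConfig()
        self.lexicon = lexicon if lexicon is not None else self._load_lexicon()
        self.stopwords = (
            stopwords if stopwords is not None else self._load_stopwords()
        )
        self.exclusions = (
            exclusions if exclusions is not None else self._load_exclusions()
        )

    def _load_lexicon(self) -> RegexLexicon:
        if self.config.lexicon:
            return load_lexicon(self.config.lexicon)
        return load_demo_lexicon()

    def _load_stopwords(self) -> frozenset[str]:
        if self.config.stopwords:
            return load_stopwords(self.config.stopwords)
        return load_default_stopwords()

    def _load_exclusions(self) -> frozenset[str]:
        if self.config.exclusions:
            return select_mod.load_exclusion_list(self.config.exclusions)
        from importlib import resources

        ref = resources.files("nidphen.data") / "demo_exclusions.txt"
        with resources.as_file(ref) as path:
            return select_mod.load_exclusion_list(path)

    @classmethod
    def from_files(
        cls,
        corpus_path: str | Path,
        config: PipelineConfig | None = None,
    ) -> "NIDPhenotypingModel":
        """Build from a JSON-Lines corpus; lexicon/stopword/exclusion
        paths are taken from ``config`` (packaged demos when unset)."""
        notes = corpus_mod.read_jsonl(corpus_path)
        return cls(notes, config=config)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "NIDPhenotypingResults":
        cfg = self.config
        seed = cfg.seed
        stage_counts: dict[str, int] = {"input": len(self.notes)}

        notes = corpus_mod.filter_min_length(self.notes, cfg.min_chars)
        stage_counts["after_length_filter"] = len(notes)

        if cfg.code_list:
            codes = corpus_mod.load_code_list(cfg.code_list)
            notes = corpus_mod.assign_icd_flag(notes, codes)

        if cfg.n_total is not None:
            notes = corpus_mod.sample_balanced(
                notes, cfg.n_total, cfg.flag_fraction, seed=seed
            )
            stage_counts["after_sampling"] = len(notes)

        unlabeled = [n.note_id for n in notes if n.label is None]
        if unlabeled:
            raise ValueError(
                f"training requires labels; missing on {unlabeled[:5]}..."
            )

        split = corpus_mod.patient_disjoint_split(
            notes, cfg.train_fraction, seed=seed
        )
        stage_counts["train"] = len(split.train)
        stage_counts["test"] = len(split.test)
        stage_counts["pruned"] = len(split.pruned)

        logger.info("featurizing %d training notes", len(split.train))
        train_docs = []
        for n in split.train:
            spans = match_spans(self.lexicon, n.text)
            windows = extract_windows(n.text, spans, buffer=cfg.buffer)
            train_docs.append(normalize(windows, self.stopwords))
        vocab = build_vocabulary(train_docs, cfg.n_range, cfg.min_doc_freq)
        stage_counts["vocabulary_terms"] = len(vocab)
        X_train = vectorize(
            train_docs, vocab, row_ids=[n.note_id for n in split.train]
        )
        y_train = [bool(n.label) for n in split.train]

        fs = select_mod.l1_select(
            X_train,
            y_train,
            reg_strength=cfg.reg_strength,
            max_iterations=cfg.max_iterations,
            n_rounds=cfg.n_rounds,
            seed=seed,
        )
        stage_counts["selected_terms"] = len(fs.terms)
        fs = select_mod.apply_curation(fs, self.exclusions)
        stage_counts["curated_terms"] = len(fs.terms)
        if not fs.terms:
            raise RuntimeError("feature selection retained no terms")

        X_sel = X_train.restrict(fs.terms)
        cv_result = None
        if cfg.run_cv:
            cv_result = model_mod.cv_compare(
                X_sel,
                y_train,
                groups=[n.patient_id for n in split.train],
                k=cfg.k_folds,
                seed=seed,
            )

        bundle = model_mod.train_final(
            X_sel,
            y_train,
            lexicon=self.lexicon,
            stopwords=self.stopwords,
            seed=seed,
            threshold=cfg.threshold,
            feature_set=fs,
            buffer=cfg.buffer,
            training_meta={
                "cv_winner": cv_result.winner if cv_result else None,
                "cv_mean_auprc": (
                    cv_result.mean_auprc.to_dict() if cv_result else None
                ),
            },
        )

        preds = model_mod.predict(bundle, split.test)
        y_test = [bool(n.label) for n in split.test]
        report = eval_mod.evaluate_scores(
            preds["score"].to_numpy(),
            y_test,
            threshold=cfg.threshold,
            B=cfg.bootstrap_iterations,
            seed=seed,
        )
        icd = eval_mod.icd_baseline(split.test)

        return NIDPhenotypingResults(
            model=self,
            bundle=bundle,
            feature_set=fs,
            cv_result=cv_result,
            split=split,
            test_scores=preds,
            eval_report=report,
            icd_contingency=icd,
            stage_counts=stage_counts,
        )


@dataclass
class NIDPhenotypingResults:
    """Fitted pipeline: estimates, uncertainties, and diagnostics."""

    model: NIDPhenotypingModel
    bundle: model_mod.ModelBundle
    feature_set: FeatureSet
    cv_result: model_mod.CVResult | None
    split: SplitResult
    test_scores: pd.DataFrame
    eval_report: eval_mod.EvalReport
    icd_contingency: eval_mod.Contingency
    stage_counts: dict[str, int] = field(default_factory=dict)

    def predict(self, notes: Sequence[ClinicalNote]) -> pd.DataFrame:
        """Score new notes with the fitted bundle."""
        return model_mod.predict(self.bundle, notes)

    def feature_importance(self, top_k: int = 20) -> pd.DataFrame:
        return model_mod.feature_importance(self.bundle, top_k=top_k)

    def summary(self) -> str:
        """Plain-text run summary: flow accounting, CV table, hold-out
        metrics with bootstrap CIs, and the ICD-flag baseline."""
        lines = ["NID phenotyping run summary", "=" * 40]
        lines.append("Stage counts:")
        for k, v in self.stage_counts.items():
            lines.append(f"  {k:<22}{v:>8}")
        if self.cv_result is not None:
            lines.append("")
            lines.append("5-fold CV mean AUPRC by family "
                         f"(winner: {self.cv_result.winner}):")
            for fam, v in self.cv_result.mean_auprc.items():
                lines.append(f"  {fam:<22}{v:8.3f}")
        lines.append("")
        lines.append(self.eval_report.table())
        c = self.icd_contingency
        lines.append("")
        lines.append(
            "ICD-flag baseline on the test set: "
            f"tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn}"
        )
        if c.sensitivity is not None and c.specificity is not None:
            lines.append(
                f"  sensitivity={c.sensitivity:.3f} "
                f"specificity={c.specificity:.3f}"
            )
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        """Persist all artifacts plus a reproducibility manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.bundle.save(d / "bundle")
        self.feature_set.save(d / "feature_set.json")
        self.eval_report.to_json(d / "eval_report.json")
        self.test_scores.to_csv(d / "test_scores.csv", index=False)
        if self.cv_result is not None:
            self.cv_result.table.to_csv(d / "cv_table.csv")
        (d / "icd_baseline.json").write_text(
            json.dumps(self.icd_contingency.to_dict(), indent=2),
            encoding="utf-8",
        )
        (d / "manifest.json").write_text(
            json.dumps(
                {
                    "config": self.model.config.model_dump(),
                    "config_hash": self.model.config.config_hash(),
                    "seed": self.model.config.seed,
                    "stage_counts": self.stage_counts,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
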