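"""Feature reduction: L1-penalized logistic stability selection plus a
manual-curation exclusion list.

The n-gram pool (easily thousands of terms) is reduced by refitting an
L1-regularized logistic regression — inverse-regularization constant
``reg_strength`` (default 10, larger = weaker penalty), class weights
inversely proportional to class size — on bootstrap resamples of the
training rows, and keeping the terms whose coefficient is nonzero in a
majority of rounds. This is stability selection with majority vote: a
single noisy L1 support is replaced by the consensus over resamples.
A curated exclusion list then removes terms a reviewer judged clinically
irrelevant (place names, vitals boilerplate, and the like).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .featurize import DocTermMatrix

logger = logging.getLogger(__name__)

__all__ = ["FeatureSet", "l1_select", "apply_curation", "load_exclusion_list"]

#: Coefficients below this magnitude are treated as zero (solver slack).
NONZERO_TOL = 1e-8


@dataclass(frozen=True)
class FeatureSet:
    """Selected terms, per-term selection counts, and curated removals."""

    terms: tuple[str, ...]
    selection_counts: dict[str, int]
    excluded_terms: tuple[str, ...] = ()
    n_rounds: int = 1

    def __post_init__(self) -> None:
        if set(self.terms) & set(self.excluded_terms):
            raise ValueError("terms and excluded_terms must be disjoint")
        missing = [t for t in self.terms if t not in self.selection_counts]
        if missing:
            raise ValueError(f"terms without selection counts: {missing[:5]}")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "terms": list(self.terms),
                    "selection_counts": self.selection_counts,
                    "excluded_terms": list(self.excluded_terms),
                    "n_rounds": self.n_rounds,
                },
                indent=2,
            ),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureSet":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            tuple(d["terms"]),
            {k: int(v) for k, v in d["selection_counts"].items()},
            tuple(d["excluded_terms"]),
            int(d.get("n_rounds", 1)),
        )


def _fit_support(X, y, reg_strength: float, max_iterations: int) -> np.ndarray:
    clf = LogisticRegression(
        l1_ratio=1,  # pure L1 penalty
        C=reg_strength,
        solver="liblinear",
        max_iter=max_iterations,
        class_weight="balanced",  # weight_c = n / (2 * n_c)
        random_state=0,
    )
    clf.fit(X, y)
    return np.abs(clf.coef_.ravel()) > NONZERO_TOL


def l1_select(
    X: DocTermMatrix,
    y: Sequence[bool],
    reg_strength: float = 10.0,
    max_iterations: int = 1000,
    n_rounds: int = 10,
    seed: int = 0,
) -> FeatureSet:
    """Stability-select terms by majority vote over ``n_rounds`` bootstrap
    L1 fits.

    With ``n_rounds=1`` this degenerates to the support of a single L1 fit
    on the full sample (no resampling). A term is selected when its
    coefficient magnitude exceeds ``NONZERO_TOL`` in at least
    ``ceil(n_rounds / 2)`` rounds; counts for every term ever nonzero are
    recorded.
    """
    yarr = np.asarray(y, dtype=bool)
    if X.counts.shape[0] != yarr.size:
        raise ValueError("X rows must align with y")
    if yarr.all() or not yarr.any():
        raise ValueError("y must contain both classes")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if reg_strength <= 0:
        raise ValueError("reg_strength must be positive")
    rng = np.random.default_rng(seed)
    n = yarr.size
    counts = np.zeros(len(X.vocabulary), dtype=int)
    mat = X.counts.astype(np.float64)
    for _ in range(n_rounds):
        if n_rounds == 1:
            idx = np.arange(n)
        else:
            for _retry in range(100):
                idx = rng.integers(0, n, size=n)
                if 0 < yarr[idx].sum() < n:
                    break
            else:  # pragma: no cover - would need an extreme imbalance
                raise RuntimeError("could not draw a two-class bootstrap resample")
        counts += _fit_support(mat[idx], yarr[idx], reg_strength, max_iterations)
    need = math.ceil(n_rounds / 2)
    terms = X.vocabulary.terms
    selected = tuple(t for t, c in zip(terms, counts) if c >= need)
    sel_counts = {t: int(c) for t, c in zip(terms, counts) if c > 0}
    logger.info(
        "L1 stability selection: %d/%d terms selected (>=%d of %d rounds)",
        len(selected), len(terms), need, n_rounds,
    )
    return FeatureSet(selected, sel_counts, n_rounds=n_rounds)


def apply_curation(fs: FeatureSet, exclusion_list: Iterable[str]) -> FeatureSet:
    """Remove curated terms (exact match on the space-joined n-gram)."""
    excl = {e.strip().lower() for e in exclusion_list if e.strip()}
    removed = tuple(t for t in fs.terms if t in excl)
    absent = sorted(excl - set(fs.terms))
    if absent:
        logger.warning("curation terms not in feature set (no-op): %s", absent)
    if removed:
        logger.info("curation removed %d terms: %s", len(removed), list(removed))
    return replace(
        fs,
        terms=tuple(t for t in fs.terms if t not in excl),
        excluded_terms=tuple(sorted(set(fs.excluded_terms) | set(removed))),
    )


def load_exclusion_list(path: str | Path) -> frozenset[str]:
    """Plain-text curation list, one space-joined term per line."""
    terms = set()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip().lower()
            if line and not line.startswith("#"):
                terms.add(line)
    return frozenset(terms)
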