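"""Bag-of-words featurization over context windows.

Documents are :class:`~nidphen.textprep.TokenSequence` objects; features
are n-grams with n in {1, 2, 3}, formed strictly within windows — a bigram
never joins the last token of one window to the first of the next, since
merged windows are discontiguous stretches of the original note. Counting
is therefore done directly here (a plain-text vectorizer has no notion of
window boundaries); the result is an ordinary sparse count matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .textprep import TokenSequence

__all__ = [
    "Vocabulary",
    "DocTermMatrix",
    "iter_ngrams",
    "build_vocabulary",
    "vectorize",
]


def iter_ngrams(doc: TokenSequence, n_range: Sequence[int]) -> Iterator[str]:
    """Yield every within-window n-gram of ``doc`` (space-joined),
    in window order, unigrams-to-longer at each position."""
    for win in doc.windows():
        for i in range(len(win)):
            for n in n_range:
                if i + n <= len(win):
                    yield " ".join(win[i : i + n])


@dataclass(frozen=True)
class Vocabulary:
    """An ordered n-gram vocabulary; term order defines column order."""

    terms: tuple[str, ...]
    n_range: tuple[int, ...] = (1, 2, 3)
    min_doc_freq: int = 2

    @property
    def index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.terms) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, n_range=(1, 2, 3), min_doc_freq: int = 2):
        terms = tuple(
            t for t in Path(path).read_text(encoding="utf-8").splitlines() if t
        )
        return cls(terms, tuple(n_range), min_doc_freq)


@dataclass(frozen=True)
class DocTermMatrix:
    """Sparse note-by-term count matrix with row ids and vocabulary."""

    rows: tuple[str, ...]
    vocabulary: Vocabulary
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.rows), len(self.vocabulary)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.rows)}, {len(self.vocabulary)})"
            )

    def restrict(self, terms: Sequence[str]) -> "DocTermMatrix":
        """Column-subset to ``terms`` (in the given order). Terms absent
        from the vocabulary contribute an all-zero column, so a matrix can
        be restricted to a feature set fit on another corpus."""
        idx = self.vocabulary.index
        cols = []
        mat = sp.csc_matrix(self.counts)
        zero = sp.csc_matrix((len(self.rows), 1), dtype=self.counts.dtype)
        for t in terms:
            cols.append(mat[:, [idx[t]]] if t in idx else zero)
        sub = sp.hstack(cols, format="csr") if cols else sp.csr_matrix(
            (len(self.rows), 0), dtype=self.counts.dtype
        )
        vocab = Vocabulary(tuple(terms), self.vocabulary.n_range,
                           self.vocabulary.min_doc_freq)
        return DocTermMatrix(self.rows, vocab, sub)

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.mtx`` plus row/column label sidecars."""
        prefix = Path(prefix)
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(self.counts))
        prefix.with_suffix(".rows.txt").write_text(
            "\n".join(self.rows) + "\n", encoding="utf-8"
        )
        self.vocabulary.save(prefix.with_suffix(".terms.txt"))


def build_vocabulary(
    docs: Sequence[TokenSequence],
    n_range: Sequence[int] = (1, 2, 3),
    min_doc_freq: int = 2,
) -> Vocabulary:
    """Collect every within-window n-gram appearing in at least
    ``min_doc_freq`` documents; terms are sorted lexicographically so the
    column order is deterministic."""
    n_range = tuple(sorted(set(int(n) for n in n_range)))
    if not n_range:
        raise ValueError("n_range must be non-empty")
    if any(n < 1 for n in n_range):
        raise ValueError("n-gram orders must be >= 1")
    if not docs:
        raise ValueError("docs must be non-empty")
    if min_doc_freq < 1:
        raise ValueError("min_doc_freq must be >= 1")
    df: Counter[str] = Counter()
    for doc in docs:
        df.update(set(iter_ngrams(doc, n_range)))
    terms = tuple(sorted(t for t, c in df.items() if c >= min_doc_freq))
    return Vocabulary(terms, n_range, min_doc_freq)


def vectorize(
    docs: Sequence[TokenSequence],
    vocab: Vocabulary,
    row_ids: Sequence[str] | None = None,
) -> DocTermMatrix:
    """Count in-vocabulary within-window n-grams per document.

    Out-of-vocabulary n-grams are ignored; a document with none yields an
    all-zero row (it still occupies a row, preserving alignment with ids).
    """
    if row_ids is None:
        row_ids = tuple(str(i) for i in range(len(docs)))
    if len(row_ids) != len(docs):
        raise ValueError("row_ids must align with docs")
    index = vocab.index
    data: list[int] = []
    indices: list[int] = []
    indptr = [0]
    for doc in docs:
        counts = Counter(
            index[g] for g in iter_ngrams(doc, vocab.n_range) if g in index
        )
        for j in sorted(counts):
            indices.append(j)
            data.append(counts[j])
        indptr.append(len(indices))
    mat = sp.csr_matrix(
        (np.asarray(data, dtype=np.int64), indices, indptr),
        shape=(len(docs), len(vocab)),
    )
    return DocTermMatrix(tuple(str(r) for r in row_ids), vocab, mat)
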