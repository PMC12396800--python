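"""Categorized regular-expression lexicon and note-text matching.

The lexicon is the anchor of the whole pipeline: curated clinical
expressions, grouped into four categories — affirmative neuroinfectious
disease (NID) statements, negated/ruled-out statements, antimicrobial
drugs, and NID-suggestive keywords — are matched against note text, and
only the neighborhoods of the matches survive into featurization.

Lexicon files are tab-separated with columns ``pattern_id``, ``category``,
``pattern``; ``#`` lines are comments. Matching is case-insensitive, since
normalization lowercases text only after window extraction.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "RegexPattern",
    "RegexLexicon",
    "MatchSpan",
    "LexiconError",
    "load_lexicon",
    "load_demo_lexicon",
    "match_spans",
]

#: The four pattern categories, in canonical order.
CATEGORIES = ("positive_nid", "negative_nid", "nid_drug", "nid_likely_keyword")


class LexiconError(ValueError):
    """Raised for malformed or invalid lexicon input."""


@dataclass(frozen=True)
class RegexPattern:
    """One categorized expression.

    The source string must compile under the standard ``re`` dialect;
    compilation (case-insensitive) happens eagerly so that a bad pattern
    fails at load time, naming its ``pattern_id``.
    """

    pattern_id: str
    category: str
    pattern: str
    compiled: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LexiconError(
                f"pattern {self.pattern_id!r}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        try:
            compiled = re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise LexiconError(
                f"pattern {self.pattern_id!r} does not compile: {exc}"
            ) from exc
        object.__setattr__(self, "compiled", compiled)


@dataclass(frozen=True)
class RegexLexicon:
    """An immutable collection of :class:`RegexPattern`, indexed by category."""

    patterns: tuple[RegexPattern, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise LexiconError("empty lexicon")
        ids = [p.pattern_id for p in self.patterns]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise LexiconError(f"duplicate pattern_id(s): {sorted(dupes)}")

    @property
    def by_category(self) -> dict[str, tuple[RegexPattern, ...]]:
        out: dict[str, list[RegexPattern]] = {c: [] for c in CATEGORIES}
        for p in self.patterns:
            out[p.category].append(p)
        return {c: tuple(ps) for c, ps in out.items()}

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterator[RegexPattern]:
        return iter(self.patterns)


@dataclass(frozen=True, order=True)
class MatchSpan:
    """A half-open character interval ``[start, end)`` matched by a pattern."""

    start: int
    end: int
    pattern_id: str
    category: str


def load_lexicon(path: str | Path) -> RegexLexicon:
    """Read a TSV lexicon file and compile every pattern.

    Raises :class:`LexiconError` naming the offending line number for
    malformed rows and the ``pattern_id`` for non-compiling patterns.
    """
    path = Path(path)
    patterns: list[RegexPattern] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise LexiconError(
                    f"{path}:{lineno}: expected 3 tab-separated fields "
                    f"(pattern_id, category, pattern), got {len(parts)}"
                )
            pid, category, pattern = (p.strip() for p in parts)
            if not pid or not pattern:
                raise LexiconError(f"{path}:{lineno}: empty pattern_id or pattern")
            patterns.append(RegexPattern(pid, category, pattern))
    lex = RegexLexicon(tuple(patterns))
    counts = {c: len(ps) for c, ps in lex.by_category.items()}
    logger.info("loaded lexicon %s: %d patterns %s", path.name, len(lex), counts)
    return lex


def load_demo_lexicon() -> RegexLexicon:
    """Load the packaged ~50-pattern demonstration lexicon."""
    ref = resources.files("nidphen.data") / "demo_lexicon.tsv"
    with resources.as_file(ref) as path:
        return load_lexicon(path)


def match_spans(lexicon: RegexLexicon, text: str) -> list[MatchSpan]:
    """All case-insensitive, non-overlapping-per-pattern matches in ``text``.

    Matches from different patterns may overlap; deduplication is the job
    of window merging downstream. Spans are sorted by ``(start, end)``.
    Zero-length matches are discarded.
    """
    spans: list[MatchSpan] = []
    for pat in lexicon:
        for m in pat.compiled.finditer(text):
            if m.end() > m.start():
                spans.append(MatchSpan(m.start(), m.end(), pat.pattern_id, pat.category))
    spans.sort()
    return spans


def categories_present(spans: Iterable[MatchSpan]) -> set[str]:
    """The set of lexicon categories represented among ``spans``."""
    return {s.category for s in spans}
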