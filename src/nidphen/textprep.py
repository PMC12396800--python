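"""Context-window extraction and text normalization.

Rather than featurizing whole notes (which at >=5000 characters are mostly
boilerplate), each note is reduced to the neighborhoods of its lexicon
matches: every match span is widened by a character buffer (default 100)
on each side, and overlapping or touching expansions are merged into
maximal disjoint windows.

Windows are then normalized into a token sequence by, in order:
lowercasing; replacing every non-alphabetic character with a space;
collapsing whitespace; dropping tokens of fewer than three characters;
dropping stopwords; lemmatizing the survivors. Window boundaries are
carried through so that later n-gram formation never crosses two windows
(merged windows are textually discontiguous regions of the note).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from ._lemma import lemmatize
from .lexicon import MatchSpan

__all__ = [
    "ContextWindow",
    "TokenSequence",
    "extract_windows",
    "normalize",
    "load_stopwords",
    "load_default_stopwords",
]

_NON_ALPHA = re.compile(r"[^a-z]+")


@dataclass(frozen=True)
class ContextWindow:
    """A maximal merged region ``[start, end)`` of a note around >=1 match."""

    start: int
    end: int
    text: str
    source_span_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class TokenSequence:
    """Normalized tokens of one note, with window structure preserved.

    ``window_boundaries[i]`` is the index in ``tokens`` where the i-th
    non-empty window begins; windows yielding no tokens are dropped.
    """

    tokens: tuple[str, ...]
    window_boundaries: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.tokens:
            if not self.window_boundaries or self.window_boundaries[0] != 0:
                raise ValueError("first window boundary must be 0")
            if list(self.window_boundaries) != sorted(set(self.window_boundaries)):
                raise ValueError("window boundaries must be strictly increasing")
        elif self.window_boundaries:
            raise ValueError("boundaries without tokens")

    def windows(self) -> Iterator[tuple[str, ...]]:
        """Yield the token run of each window."""
        bounds = list(self.window_boundaries) + [len(self.tokens)]
        for lo, hi in zip(bounds, bounds[1:]):
            yield self.tokens[lo:hi]

    def __len__(self) -> int:
        return len(self.tokens)


def extract_windows(
    text: str, spans: Sequence[MatchSpan], buffer: int = 100
) -> list[ContextWindow]:
    """Expand each span by ``buffer`` characters each side, clamp to the
    note, and merge overlapping or touching expansions into maximal
    disjoint windows sorted by position."""
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    n = len(text)
    intervals = []
    for s in spans:
        if not (0 <= s.start < s.end <= n):
            raise ValueError(f"span [{s.start},{s.end}) outside text of length {n}")
        intervals.append((max(0, s.start - buffer), min(n, s.end + buffer), s.pattern_id))
    intervals.sort()
    windows: list[ContextWindow] = []
    cur_lo = cur_hi = None
    cur_ids: list[str] = []
    for lo, hi, pid in intervals:
        if cur_hi is None or lo > cur_hi:  # touching (lo == cur_hi) merges
            if cur_hi is not None:
                windows.append(
                    ContextWindow(cur_lo, cur_hi, text[cur_lo:cur_hi], tuple(cur_ids))
                )
            cur_lo, cur_hi, cur_ids = lo, hi, [pid]
        else:
            cur_hi = max(cur_hi, hi)
            cur_ids.append(pid)
    if cur_hi is not None:
        windows.append(ContextWindow(cur_lo, cur_hi, text[cur_lo:cur_hi], tuple(cur_ids)))
    return windows


def normalize(
    windows: Sequence[ContextWindow] | Sequence[str],
    stopwords: Iterable[str] = (),
) -> TokenSequence:
    """Apply the six normalization steps to each window and concatenate,
    recording where each window's tokens begin.

    Accepts :class:`ContextWindow` objects or bare strings. Stopword
    removal precedes lemmatization, so the stopword list is matched
    against surface (pre-lemma) token forms; the stopword and length
    filters are re-applied to the lemmas (a lemma such as "other" from
    "others" can itself be a stopword), which makes normalization
    idempotent on its own output.
    """
    stop = frozenset(stopwords)
    tokens: list[str] = []
    boundaries: list[int] = []
    for w in windows:
        raw = w.text if isinstance(w, ContextWindow) else w
        cleaned = _NON_ALPHA.sub(" ", raw.lower())
        win_tokens = [
            lemmatize(t)
            for t in cleaned.split()
            if len(t) >= 3 and t not in stop
        ]
        win_tokens = [t for t in win_tokens if len(t) >= 3 and t not in stop]
        if win_tokens:
            boundaries.append(len(tokens))
            tokens.extend(win_tokens)
    return TokenSequence(tuple(tokens), tuple(boundaries))


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Plain-text stopword list, one word per line."""
    words = set()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip().lower()
            if line and not line.startswith("#"):
                words.add(line)
    return frozenset(words)


def load_default_stopwords() -> frozenset[str]:
    ref = resources.files("nidphen.data") / "stopwords.txt"
    with resources.as_file(ref) as path:
        return load_stopwords(path)
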