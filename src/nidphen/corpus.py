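"""Note corpora: JSON-Lines I/O, length filtering, ICD flagging, balanced
sampling, and patient-disjoint train/test splitting.

A corpus is a sequence of :class:`ClinicalNote`. Billing codes act as a
noisy disease proxy: a note is "ICD-flagged" when any of its codes is in a
configured NID code set. Because patients contribute multiple notes, the
train/test split is note-level and stratified on the ICD flag, after which
any test note sharing a patient with the training set is moved to a
``pruned`` bucket — the same leakage repair as reducing a 600-note hold-out
to the disjoint subset actually evaluated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalNote",
    "SplitResult",
    "read_jsonl",
    "write_jsonl",
    "load_code_list",
    "load_default_code_list",
    "filter_min_length",
    "assign_icd_flag",
    "sample_balanced",
    "patient_disjoint_split",
]


@dataclass(frozen=True)
class ClinicalNote:
    """One clinical note with patient linkage and an optional expert label."""

    note_id: str
    patient_id: str
    text: str
    icd_codes: frozenset[str] = frozenset()
    icd_nid_flag: bool = False
    label: bool | None = None
    source: str = ""

    def to_dict(self) -> dict:
        return {
            "note_id": self.note_id,
            "patient_id": self.patient_id,
            "text": self.text,
            "icd_codes": sorted(self.icd_codes),
            "icd_nid_flag": self.icd_nid_flag,
            "label": self.label,
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicalNote":
        return cls(
            note_id=str(d["note_id"]),
            patient_id=str(d["patient_id"]),
            text=d.get("text", ""),
            icd_codes=frozenset(d.get("icd_codes", ())),
            icd_nid_flag=bool(d.get("icd_nid_flag", False)),
            label=d.get("label"),
            source=d.get("source", ""),
        )


@dataclass(frozen=True)
class SplitResult:
    """A train/test partition with the leakage-pruned notes kept auditable."""

    train: tuple[ClinicalNote, ...]
    test: tuple[ClinicalNote, ...]
    pruned: tuple[ClinicalNote, ...] = ()

    def __post_init__(self) -> None:
        train_pat = {n.patient_id for n in self.train}
        test_pat = {n.patient_id for n in self.test}
        if train_pat & test_pat:
            raise ValueError("train and test share patients")


def read_jsonl(path: str | Path) -> list[ClinicalNote]:
    """Read a JSON-Lines corpus, one note object per line."""
    notes: list[ClinicalNote] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                notes.append(ClinicalNote.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: bad note record: {exc}") from exc
    ids = [n.note_id for n in notes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate note_id values")
    return notes


def write_jsonl(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(json.dumps(n.to_dict()) + "\n")


def _normalize_code(code: str) -> str:
    return "".join(code.split()).upper()


def load_code_list(path: str | Path) -> frozenset[str]:
    """Plain-text NID code list, one ICD-9/ICD-10 code per line."""
    codes = set()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                codes.add(_normalize_code(line))
    if not codes:
        raise ValueError(f"{path}: empty code list")
    return frozenset(codes)


def load_default_code_list() -> frozenset[str]:
    ref = resources.files("nidphen.data") / "nid_icd_codes.txt"
    with resources.as_file(ref) as path:
        return load_code_list(path)


def filter_min_length(
    notes: Sequence[ClinicalNote], min_chars: int = 5000
) -> list[ClinicalNote]:
    """Drop notes shorter than ``min_chars`` characters (raw text length,
    whitespace included); a note of exactly ``min_chars`` is retained."""
    if min_chars < 0:
        raise ValueError("min_chars must be >= 0")
    kept = [n for n in notes if len(n.text) >= min_chars]
    logger.info("length filter: %d/%d notes retained (>=%d chars)",
                len(kept), len(notes), min_chars)
    return kept


def assign_icd_flag(
    notes: Sequence[ClinicalNote], nid_code_set: Iterable[str]
) -> list[ClinicalNote]:
    """Set ``icd_nid_flag`` on every note from its billing codes.

    Codes are compared after whitespace stripping and upper-casing.
    """
    code_set = frozenset(_normalize_code(c) for c in nid_code_set)
    if not code_set:
        raise ValueError("nid_code_set must be non-empty")
    out = []
    for n in notes:
        flag = bool({_normalize_code(c) for c in n.icd_codes} & code_set)
        out.append(dataclasses.replace(n, icd_nid_flag=flag))
    logger.info("ICD flagging: %d/%d notes flagged", sum(n.icd_nid_flag for n in out), len(out))
    return out


def sample_balanced(
    notes: Sequence[ClinicalNote],
    n_total: int,
    flag_fraction: float = 0.5,
    seed: int = 0,
) -> list[ClinicalNote]:
    """Sample ``n_total`` notes without replacement with a fixed fraction of
    ICD-flagged notes (default 50:50). Original corpus order is preserved."""
    if not 0.0 <= flag_fraction <= 1.0:
        raise ValueError("flag_fraction must be in [0, 1]")
    n_flag = round(n_total * flag_fraction)
    n_unflag = n_total - n_flag
    flagged = [i for i, n in enumerate(notes) if n.icd_nid_flag]
    unflagged = [i for i, n in enumerate(notes) if not n.icd_nid_flag]
    if len(flagged) < n_flag:
        raise ValueError(
            f"flagged stratum too small: need {n_flag}, have {len(flagged)}"
        )
    if len(unflagged) < n_unflag:
        raise ValueError(
            f"unflagged stratum too small: need {n_unflag}, have {len(unflagged)}"
        )
    rng = np.random.default_rng(seed)
    take = set(rng.choice(flagged, size=n_flag, replace=False)) | set(
        rng.choice(unflagged, size=n_unflag, replace=False)
    )
    return [n for i, n in enumerate(notes) if i in take]


def patient_disjoint_split(
    notes: Sequence[ClinicalNote],
    train_fraction: float = 0.8,
    stratify_on: str = "icd_nid_flag",
    seed: int = 0,
) -> SplitResult:
    """Stratified note-level split, then prune test notes that share a
    patient with the training set.

    The initial split allocates ``round(train_fraction * n_s)`` notes of
    each stratum to train. Pruning only ever shrinks the test side, so the
    training set is exactly what the fraction dictates while the evaluated
    test set may be smaller; pruned notes are returned for audit.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    strata: dict[object, list[int]] = {}
    for i, n in enumerate(notes):
        strata.setdefault(getattr(n, stratify_on), []).append(i)
    for _, idx in sorted(strata.items(), key=lambda kv: repr(kv[0])):
        perm = rng.permutation(idx)
        k = round(train_fraction * len(idx))
        train_idx.extend(perm[:k])
        test_idx.extend(perm[k:])
    train = tuple(notes[i] for i in sorted(train_idx))
    test0 = [notes[i] for i in sorted(test_idx)]
    train_patients = {n.patient_id for n in train}
    test = tuple(n for n in test0 if n.patient_id not in train_patients)
    pruned = tuple(n for n in test0 if n.patient_id in train_patients)
    logger.info(
        "split: %d train, %d test (%d pruned for patient overlap)",
        len(train), len(test), len(pruned),
    )
    return SplitResult(train=train, test=test, pruned=pruned)
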