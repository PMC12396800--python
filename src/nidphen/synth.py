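"""Seeded synthetic note corpora with the statistical structure of a
lumbar-puncture-enriched hospital cohort.

Real clinical notes are protected; this module generates stand-ins with
the properties every pipeline stage needs to be exercised against:

* patients contribute a variable number of notes (1 plus a truncated
  Poisson), and disease status is assigned at the *patient* level, so
  patient-leakage pruning and grouped cross-validation actually bite;
* note-level prevalence targets the study regime (~16%; ~6% for an
  external-style set);
* notes are padded with neutral clinical boilerplate to >= 5000
  characters, so the length filter and context-window logic matter;
* positive notes embed a Poisson number of affirmative-NID phrases plus
  drug and keyword phrases; negative notes embed negation-category and
  keyword phrases (and occasional empiric-antibiotic mentions), all drawn
  from literal surface realizations of the demo lexicon patterns;
* each note's ICD flag is drawn with configurable sensitivity/specificity
  against ground truth (study regime: 0.97 / 0.59).

The filler-sentence bank is screened against the demo lexicon (a test
enforces zero matches), so every lexicon hit in a generated note is a
deliberately planted phrase. Same seed, same config: byte-identical corpus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .corpus import ClinicalNote
from .lexicon import RegexLexicon, load_demo_lexicon

__all__ = ["SynthConfig", "generate_corpus", "make_fixture", "FILLER_SENTENCES",
           "load_surface_forms", "planted_signal_ngrams",
           "recovered_signal_fraction"]

#: Neutral clinical boilerplate: deliberately free of every demo-lexicon
#: expression (screened by test), covering the humdrum bulk of real notes.
FILLER_SENTENCES: tuple[str, ...] = (
    "The patient was resting comfortably in bed during morning rounds.",
    "Vital signs remained within normal limits overnight.",
    "Blood pressure was well controlled on the home regimen.",
    "The patient ambulated in the hallway with physical therapy twice today.",
    "Diet was advanced to regular as tolerated without difficulty.",
    "Electrolytes were repleted per protocol this morning.",
    "The family meeting was held to discuss goals of care and disposition.",
    "Case manager is arranging home services for discharge.",
    "The patient remained afebrile throughout the shift.",
    "Telemetry showed normal sinus rhythm without ectopy.",
    "Home medications were reconciled on admission with the pharmacist.",
    "The patient reports improved appetite and adequate oral intake.",
    "Skin examination shows no breakdown and intact dressings.",
    "Chest radiograph was clear without focal consolidation.",
    "Renal function remains at baseline with good urine output.",
    "The patient was counseled regarding smoking cessation resources.",
    "Social work consulted for insurance authorization questions.",
    "Incentive spirometry was encouraged at the bedside every hour.",
    "Follow up appointment was scheduled with the primary care office in Boston.",
    "The nursing staff noted a restful night without acute events.",
    "Daily weights and strict intake and output are being recorded.",
    "Glycemic control has been acceptable on the sliding scale.",
    "The abdomen is soft and nontender with normoactive bowel sounds.",
    "Peripheral pulses are intact and extremities are warm bilaterally.",
    "Heart rate and rhythm are regular without murmurs or rubs.",
    "Lungs are clear to auscultation bilaterally with good air movement.",
    "Deep vein thrombosis prophylaxis was continued with compression devices.",
    "The patient verbalized understanding of the discharge instructions.",
    "Occupational therapy recommends a home safety evaluation before discharge.",
    "Lipid panel and thyroid studies were unremarkable this admission.",
    "The surgical site is healing well without drainage or erythema.",
    "The patient tolerated the bedside swallow evaluation without difficulty.",
    "Nutrition consult placed for supplement recommendations.",
    "The echocardiogram showed preserved ejection fraction.",
    "Physical examination is otherwise unchanged from prior documentation.",
    "Pain has been adequately managed with the current regimen.",
    "The patient is oriented and conversant, participating in care decisions.",
    "Ambulatory oxygen saturation remained above ninety four percent.",
    "Bowel regimen was continued with good effect.",
    "Interpreter services were provided for the care discussion.",
)


def load_surface_forms() -> dict[str, list[tuple[str, str]]]:
    """Literal phrase realizations of the demo lexicon, keyed by category.

    Returns ``category -> [(pattern_id, phrase), ...]`` in file order.
    """
    lex = load_demo_lexicon()
    id2cat = {p.pattern_id: p.category for p in lex}
    out: dict[str, list[tuple[str, str]]] = {}
    ref = resources.files("nidphen.data") / "demo_surface_forms.tsv"
    with resources.as_file(ref) as path, open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].lstrip().startswith("#"):
                continue
            pid, phrase = row[0].strip(), row[1].strip()
            pat = next(p for p in lex if p.pattern_id == pid)
            if not pat.compiled.search(phrase):
                raise ValueError(
                    f"surface form for {pid!r} does not match its pattern"
                )
            out.setdefault(id2cat[pid], []).append((pid, phrase))
    return out


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults are the study-regime conditions."""

    n_patients: int = 2469
    notes_per_patient: tuple[float, int] = (1.215, 6)  # (mean, max)
    prevalence: float = 0.16  # patient-level NID probability
    icd_sensitivity: float = 0.97
    icd_specificity: float = 0.59
    signal_strength: float = 4.0  # E[positive phrases] per positive note
    min_chars: int = 5000
    lexicon: RegexLexicon | None = None  # None -> demo lexicon
    seed: int = 0
    source: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("prevalence", "icd_sensitivity", "icd_specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        mean, mx = self.notes_per_patient
        if mean < 1 or mx < 1:
            raise ValueError("notes_per_patient mean and max must be >= 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        longest = max(len(s) for s in FILLER_SENTENCES)
        if self.min_chars < longest:
            raise ValueError(
                f"min_chars={self.min_chars} shorter than the longest "
                f"template sentence ({longest} chars)"
            )


# Per-note phrase-count intensities beyond the configurable signal strength.
_DRUG_RATE_POS = 2.0
_DRUG_RATE_NEG = 0.7  # empiric antibiotics appear in ruled-out work-ups too
_KEYWORD_RATE = 2.0
_NEGATION_RATE = 1.5


def _compose_note(
    rng: np.random.Generator,
    phrases: list[str],
    min_chars: int,
) -> str:
    """Pad phrase sentences with shuffled filler to >= min_chars."""
    sentences = [f"{p}." for p in phrases]
    length = sum(len(s) + 1 for s in sentences)
    target = min_chars + int(rng.integers(0, 2000))
    bank = len(FILLER_SENTENCES)
    while length < target:
        s = FILLER_SENTENCES[int(rng.integers(0, bank))]
        sentences.append(s)
        length += len(s) + 1
    order = rng.permutation(len(sentences))
    return " ".join(sentences[i] for i in order)


def generate_corpus(cfg: SynthConfig) -> list[ClinicalNote]:
    """Generate a labeled, ICD-flagged corpus under ``cfg``.

    Deterministic in ``cfg.seed``: the same config reproduces the corpus
    byte for byte.
    """
    surface = load_surface_forms()
    for cat in ("positive_nid", "negative_nid", "nid_drug", "nid_likely_keyword"):
        if not surface.get(cat):
            raise ValueError(f"no surface forms available for category {cat!r}")
    rng = np.random.default_rng(cfg.seed)
    mean_extra = cfg.notes_per_patient[0] - 1.0
    max_notes = cfg.notes_per_patient[1]

    def draw(cat: str, k: int) -> list[str]:
        pool = surface[cat]
        return [pool[int(i)][1] for i in rng.integers(0, len(pool), size=k)]

    notes: list[ClinicalNote] = []
    for p in range(cfg.n_patients):
        patient_id = f"P{p:05d}"
        positive = bool(rng.random() < cfg.prevalence)
        n_notes = 1 + min(int(rng.poisson(mean_extra)), max_notes - 1)
        for j in range(n_notes):
            phrases: list[str] = []
            if positive:
                phrases += draw("positive_nid", int(rng.poisson(cfg.signal_strength)))
                phrases += draw("nid_drug", int(rng.poisson(_DRUG_RATE_POS)))
            else:
                phrases += draw("negative_nid", int(rng.poisson(_NEGATION_RATE)))
                phrases += draw("nid_drug", int(rng.poisson(_DRUG_RATE_NEG)))
            phrases += draw("nid_likely_keyword", int(rng.poisson(_KEYWORD_RATE)))
            text = _compose_note(rng, phrases, cfg.min_chars)
            if positive:
                flagged = bool(rng.random() < cfg.icd_sensitivity)
            else:
                flagged = bool(rng.random() >= cfg.icd_specificity)
            notes.append(
                ClinicalNote(
                    note_id=f"N{p:05d}-{j}",
                    patient_id=patient_id,
                    text=text,
                    icd_codes=frozenset({"G03.9"}) if flagged else frozenset(),
                    icd_nid_flag=flagged,
                    label=positive,
                    source=cfg.source,
                )
            )
    return notes


def planted_signal_ngrams() -> dict[str, set[str]]:
    """Per affirmative-NID pattern: the n-grams (n <= 3) of its planted core.

    For each positive-category pattern, the pattern is applied to its own
    surface phrase; the matched substring is normalized exactly as the
    pipeline normalizes windows, and all its within-phrase 1/2/3-grams are
    returned. Every planting of the phrase contributes these n-grams to
    the note's features, so they are the textual trace feature selection
    can recover.
    """
    from .featurize import iter_ngrams
    from .textprep import load_default_stopwords, normalize

    stop = load_default_stopwords()
    lex = load_demo_lexicon()
    by_id = {p.pattern_id: p for p in lex}
    out: dict[str, set[str]] = {}
    for pid, phrase in load_surface_forms()["positive_nid"]:
        m = by_id[pid].compiled.search(phrase)
        core = normalize([m.group(0)], stop)
        out[pid] = set(iter_ngrams(core, (1, 2, 3)))
    return out


def recovered_signal_fraction(selected_terms) -> float:
    """Fraction of planted affirmative-NID patterns whose textual trace
    survives feature selection.

    A pattern counts as recovered when at least one n-gram of its
    normalized match core is among ``selected_terms``. Tokens planted by
    one phrase are perfectly collinear columns, so an L1 fit keeps an
    arbitrary representative among them; recovery is therefore assessed
    per planted phrase, not per collinear encoding of it.
    """
    sel = set(selected_terms)
    per_pattern = planted_signal_ngrams()
    hits = sum(1 for grams in per_pattern.values() if grams & sel)
    return hits / len(per_pattern)


# ---------------------------------------------------------------------------
# Hand-built regression fixtures

def _fixture_windows_basic():
    """3 single-span notes with precomputed window offsets (buffer 100)."""
    notes = [
        ClinicalNote("f1", "PA", "x" * 150 + "ventriculitis" + "y" * 140,
                     label=True),
        ClinicalNote("f2", "PB", "headache" + "z" * 100, label=False),
        ClinicalNote("f3", "PC", "w" * 300, label=False),
    ]
    expected = {
        "f1": [(50, 263)],   # span [150,163) +/- 100
        "f2": [(0, 108)],    # span [0,8) clamped left, +100 right
        "f3": [],            # no match
    }
    return notes, {"windows": expected}


def _fixture_ngram_block():
    """One note whose two windows must not yield a cross-window bigram."""
    text = "ventriculitis" + " " + "q" * 300 + " " + "meningismus" + "r" * 20
    notes = [ClinicalNote("g1", "PD", text, label=True)]
    return notes, {"forbidden_bigram": "ventriculitis meningismus",
                   "n_windows": 2}


def _fixture_leakage():
    """6 notes from 2 patients: any note-level split must prune overlap."""
    notes = [
        ClinicalNote(f"h{i}", "PE" if i < 3 else "PF", f"note {i} " + "t" * 30,
                     icd_nid_flag=(i % 2 == 0), label=(i < 3))
        for i in range(6)
    ]
    return notes, {"n_patients": 2}


_FIXTURES = {
    "windows_basic": _fixture_windows_basic,
    "ngram_block": _fixture_ngram_block,
    "leakage": _fixture_leakage,
}


def make_fixture(name: str):
    """Return ``(notes, expected)`` for a registered tiny fixture."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return builder()
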