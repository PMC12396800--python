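"""Dictionary-less rule lemmatizer for clinical bag-of-words features.

A deliberately small noun lemmatizer in the WordNet-morphy style: an
irregular-form table plus ordered suffix rules, with guards that leave
Latinate clinical vocabulary (``meningitis``, ``status``, ``pleocytosis``)
untouched. It maps regular plurals to their singular so that, e.g.,
``seizures`` and ``seizure`` share one feature column. It is idempotent:
``lemmatize(lemmatize(w)) == lemmatize(w)``.
"""

from __future__ import annotations

__all__ = ["lemmatize"]

# Irregular or rule-breaking forms worth fixing in clinical text.
_EXCEPTIONS: dict[str, str] = {
    "men": "man",
    "women": "woman",
    "children": "child",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
    "diagnoses": "diagnosis",
    "prognoses": "prognosis",
    "analyses": "analysis",
    "stenoses": "stenosis",
    "metastases": "metastasis",
    "viruses": "virus",
    "sinuses": "sinus",
    "statuses": "status",
    "abscesses": "abscess",
    "series": "series",
    "species": "species",
}

# Suffixes that look plural but are not ("meningitis", "lupus", "pertussis").
_KEEP_SUFFIXES = ("ss", "us", "is")

_ES_SUFFIXES = ("ches", "shes", "xes", "zes", "sses")


def lemmatize(word: str) -> str:
    """Return the lemma of a lowercase alphabetic token."""
    if word in _EXCEPTIONS:
        return _EXCEPTIONS[word]
    if len(word) <= 3 or word.endswith(_KEEP_SUFFIXES):
        return word
    if word.endswith("ies") and len(word) >= 5:
        return word[:-3] + "y"
    for suf in _ES_SUFFIXES:
        if word.endswith(suf):
            return word[:-2]
    if word.endswith("s"):
        return word[:-1]
    return word
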