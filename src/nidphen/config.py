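"""Validated pipeline configuration.

One YAML file drives a whole run; every numeric knob of every stage has
its study-regime default here, and nothing is hard-coded downstream.
Unknown keys are rejected so a typo cannot silently fall back to a
default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig"]


class PipelineConfig(BaseModel):
    """All knobs of the phenotyping pipeline with study-regime defaults."""

    model_config = ConfigDict(extra="forbid")

    # input paths (None -> packaged demo artifact where one exists)
    corpus: str | None = None
    lexicon: str | None = None
    stopwords: str | None = None
    exclusions: str | None = None
    code_list: str | None = None

    # note selection
    min_chars: int = Field(5000, ge=0)
    n_total: int | None = Field(None, ge=0)  # None -> use all notes
    flag_fraction: float = Field(0.5, ge=0.0, le=1.0)

    # windows + featurization
    buffer: int = Field(100, ge=0)
    ngram_min: int = Field(1, ge=1)
    ngram_max: int = Field(3, ge=1)
    min_doc_freq: int = Field(2, ge=1)

    # feature selection
    reg_strength: float = Field(10.0, gt=0.0)
    max_iterations: int = Field(1000, ge=1)
    n_rounds: int = Field(10, ge=1)

    # split / CV / model / evaluation
    train_fraction: float = Field(0.8, gt=0.0, lt=1.0)
    k_folds: int = Field(5, ge=2)
    threshold: float = Field(0.5, ge=0.0, le=1.0)
    bootstrap_iterations: int = Field(1000, ge=1)
    run_cv: bool = True

    seed: int = 0

    @property
    def n_range(self) -> tuple[int, ...]:
        return tuple(range(self.ngram_min, self.ngram_max + 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Stable digest of the full configuration (manifest key)."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
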