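"""Validated configuration objects and config-file I/O.

All simulation entry points take one of the frozen pydantic models defined
here.  Models reject unknown keys so that a typo in a config file fails
loudly with the offending field named, rather than silently running with a
default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class AbstractParams(_StrictModel):
    """Parameters of the abstract fitness-directed tuning model.

    ``k`` is the magnitude of the directed step and ``eta`` the magnitude of
    the per-gene noise step, both in activity units per step.  Activities are
    floored at ``clamp_min`` (negative transcriptional activity is
    unphysical).
    """

    n_genes: int = Field(default=1000, ge=1)
    k: float = Field(default=0.1, ge=0)
    eta: float = Field(default=0.1, ge=0)
    n_steps: int = Field(default=10_000, ge=1)
    seed: int = 0
    init_low: float = 0.0
    init_high: float = 100.0
    clamp_min: float = 0.0

    @model_validator(mode="after")
    def _check_init_range(self) -> "AbstractParams":
        if not self.init_low < self.init_high:
            raise ValueError(
                f"init_low ({self.init_low}) must be < init_high ({self.init_high})"
            )
        return self


class ThresholdConfig(AbstractParams):
    """Abstract model with one growth-limiting gene gated by a threshold.

    The gene at ``ura3_index`` starts at ``ura3_init`` while every other gene
    starts at its optimum; it receives only the noise term until its activity
    reaches ``threshold`` (modelling a competitive inhibitor that blanks the
    fitness contribution of sub-threshold expression).
    """

    ura3_index: int = Field(default=0, ge=0)
    threshold: float = Field(default=30.0, ge=0)
    ura3_init: float = 25.0
    ura3_optimal: float = 80.0

    @model_validator(mode="after")
    def _check_index(self) -> "ThresholdConfig":
        if self.ura3_index >= self.n_genes:
            raise ValueError(
                f"ura3_index ({self.ura3_index}) out of range for n_genes={self.n_genes}"
            )
        return self


class KineticsPriors(_StrictModel):
    """Physiological priors for per-gene kinetic parameters.

    Transcription events per hour are Gamma(shape, rate); transcript
    half-lives in minutes are Gamma; protein half-lives in hours and log2
    translation rates (s^-1) are scaled Student-t.  Draws outside the
    positive support (half-lives, rates) are rejected and redrawn.
    """

    transcription_shape: float = Field(default=5.0, gt=0)
    transcription_rate: float = Field(default=2.0, gt=0)  # per (transcripts/hour)
    transcript_half_life_shape: float = Field(default=12.0, gt=0)
    transcript_half_life_rate: float = Field(default=0.75, gt=0)  # per minute
    protein_half_life_mean: float = 1.0  # hours
    protein_half_life_sigma: float = Field(default=0.382, gt=0)
    protein_half_life_df: float = Field(default=80.0, gt=0)
    log2_translation_mean: float = -5.0  # log2 s^-1
    log2_translation_sigma: float = Field(default=0.5, gt=0)
    log2_translation_df: float = Field(default=80.0, gt=0)


PhysioMode = Literal["tuning", "random_marks", "fixed_baseline", "known_optimum"]

#: parameters eligible for the twofold robustness sweep
SWEEPABLE_PARAMS = (
    "mu_max",
    "p_tunestep",
    "p_decay",
    "p_random",
    "p_s_mark",
    "m_s",
    "n_window",
)


class PhysioConfig(_StrictModel):
    """Configuration of the chromatin-mark / central-dogma simulator.

    Probabilities are per 1-step (``dt`` seconds) event probabilities.
    ``mu_max`` bounds the signed tuning-mark count; ``m_s`` is the
    log-scale effect of one stabilizing mark; ``n_window`` is the block
    length (steps) over which fitness is averaged when computing the
    fitness change that directs tuning.  ``target_offset`` is the
    multiplicative factor between initial and target transcription rates.
    """

    n_genes: int = Field(default=1, ge=1)
    dt: float = Field(default=1.0, gt=0)  # seconds
    n_steps: int = Field(default=300_000, ge=1)
    mu_max: int = Field(default=20, ge=1)
    p_tunestep: float = Field(default=0.01, ge=0, le=1)
    p_decay: float = Field(default=0.001, ge=0, le=1)
    p_random: float = Field(default=0.001, ge=0, le=1)
    p_s_mark: float = Field(default=0.01, ge=0, le=1)
    m_s: float = 0.05
    n_window: int = Field(default=100, ge=1)
    mode: PhysioMode = "tuning"
    seed: int = 0
    target_offset: float = Field(default=8.0, gt=0)
    tuning_step_max: int = Field(default=4, ge=1)

    def replace(self, **kwargs) -> "PhysioConfig":
        return self.model_copy(update=kwargs)


_CONFIG_KINDS = {
    "abstract": AbstractParams,
    "ura3": ThresholdConfig,
    "physio": PhysioConfig,
    "kinetics_priors": KineticsPriors,
}


def load_config(path: str | Path, kind: str):
    """Load and validate a YAML/JSON config file.

    ``kind`` selects the target model: one of ``abstract``, ``ura3``,
    ``physio``, ``kinetics_priors``.  Raises ``ValueError`` naming every
    offending field on validation failure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        cls = _CONFIG_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown config kind {kind!r}; expected one of {sorted(_CONFIG_KINDS)}")
    try:
        return cls.model_validate(data)
    except Exception as exc:  # pydantic ValidationError already names fields
        raise ValueError(f"invalid {kind} config {path}: {exc}") from exc


def save_config(config: BaseModel, path: str | Path) -> Path:
    """Write a config model to YAML (or JSON by extension); round-trips with load_config."""
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
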