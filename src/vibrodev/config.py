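"""Configuration models for the simulation/analysis pipeline.

Configuration is a nested YAML document validated with pydantic.  The
top-level sections mirror the pipeline stages::

    seed: 20240101
    cohort:
      n_per_group: [45, 34, 22, 41]
      noise_multiplier: 1.0
    observer:
      person_spread: 0.5
      lapse_rate: 0.03
    qc:
      min_switches: 3
      sd_limit: 3.0
    fitting:
      poly_alpha: 0.05
      n_starts: 5

Every knob has a validated default, so an empty file (or no file) is a
complete configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator

from .curves import DEFAULT_AGE_CURVES, GeneratingCurve

__all__ = [
    "ComprehensionModel",
    "ObserverConfig",
    "CohortSpec",
    "QCConfig",
    "FitConfig",
    "PipelineConfig",
    "load_config",
]


class ComprehensionModel(BaseModel):
    """Logistic-in-age probability of understanding a task.

    ``p(age) = 1 / (1 + exp(-(age - age_at_half) / width))`` — monotone
    non-decreasing in age.
    """

    age_at_half: float = Field(description="age (years) at 50% comprehension")
    width: float = Field(gt=0, description="logistic width (years)")

    def probability(self, age: float) -> float:
        import math

        return 1.0 / (1.0 + math.exp(-(age - self.age_at_half) / self.width))


def _default_comprehension() -> dict[str, ComprehensionModel]:
    # Ordered easiest (RT) to hardest (TOJ): young children nearly always
    # manage the detection task, while temporal order judgment is frequently
    # failed below age ~6.
    return {
        "RT": ComprehensionModel(age_at_half=1.0, width=0.8),
        "sqAD": ComprehensionModel(age_at_half=2.0, width=0.8),
        "smAD": ComprehensionModel(age_at_half=2.2, width=0.8),
        "DD": ComprehensionModel(age_at_half=3.0, width=1.0),
        "TOJ": ComprehensionModel(age_at_half=4.5, width=1.0),
    }


class CurveSpec(BaseModel):
    """Serializable stand-in for :class:`~vibrodev.curves.GeneratingCurve`."""

    family: Literal["power", "exponential2", "linear", "quadratic", "cubic"]
    coefficients: dict[str, float]
    outcome_units: str = "ms"

    def build(self) -> GeneratingCurve:
        return GeneratingCurve(self.family, self.coefficients, self.outcome_units)


class ObserverConfig(BaseModel):
    """Parameters of the synthetic observer model."""

    #: log-scale SD of the unit-median lognormal person effect on the four
    #: discrimination-task true thresholds (scaled by ``noise_multiplier``).
    person_spread: float = Field(default=0.9, ge=0)
    #: log-scale SD of the person effect on the reaction-time median; RT
    #: scatter in reference data is much smaller relative to its mean than
    #: the discrimination thresholds', hence the separate knob.
    rt_person_spread: float = Field(default=0.35, ge=0)
    #: probability of a stimulus-independent error; caps the psychometric
    #: ceiling at 1 - lapse_rate/2.
    lapse_rate: float = Field(default=0.03, ge=0, le=0.1)
    #: log-logistic psychometric slope (dimensionless, > 0).
    psychometric_slope: float = Field(default=8.0, gt=0)
    #: median smAD/sqAD threshold ratio (>= 1).
    smad_factor: float = Field(default=1.3, ge=1.0)
    #: couple smAD to sqAD within observer (guarantees smAD >= sqAD).
    couple_smad: bool = True
    #: per-task comprehension (practice-gate) models.
    comprehension: dict[str, ComprehensionModel] = Field(
        default_factory=_default_comprehension
    )
    #: optional per-measure generating-curve overrides.
    curves: dict[str, CurveSpec] = Field(default_factory=dict)

    def curve(self, measure: str) -> GeneratingCurve:
        if measure in self.curves:
            return self.curves[measure].build()
        try:
            return DEFAULT_AGE_CURVES[measure]
        except KeyError:
            raise KeyError(f"no generating curve for measure {measure!r}") from None


class CohortSpec(BaseModel):
    """Recruitment plan: how many observers per age band.

    Bands are the four recruitment groups 3–6, 7–12, 13–17 and 18–23 years
    (implemented as half-open intervals [3,7), [7,13), [13,18), [18,24)).
    """

    n_per_group: tuple[int, int, int, int] = (45, 34, 22, 41)
    age_sampling: Literal["uniform"] | list[float] = "uniform"
    #: optional overrides of the pipeline-level values
    noise_multiplier: Optional[float] = Field(default=None, ge=0)
    seed: Optional[int] = Field(default=None, ge=0)

    @field_validator("n_per_group")
    @classmethod
    def _non_negative(cls, v):
        if any(n < 0 for n in v):
            raise ValueError("group sizes must be >= 0")
        return v


class QCConfig(BaseModel):
    """Objective exclusion rules."""

    #: exclude a discrimination task if the response finger switched fewer
    #: than this many times across the 20 trials.
    min_switches: int = Field(default=3, ge=0)
    #: exclude an outcome more than this many group SDs from the group mean.
    sd_limit: float = Field(default=3.0, gt=0)
    #: apply the SD rule to all tasks, or to RT/RTVar only.
    outlier_scope: Literal["all", "rt_only"] = "all"
    #: optional (non-default) heuristic flagging staircases whose tail trend
    #: moves away from convergence; stands in for a subjective trace review.
    flag_diverging_traces: bool = False


class FitConfig(BaseModel):
    """Trajectory-fitting options."""

    #: significance level for retaining an added polynomial term.
    poly_alpha: float = Field(default=0.05, gt=0, lt=1)
    #: number of multi-start initializations for nonlinear fits.
    n_starts: int = Field(default=5, ge=1)
    #: RMSE denominator: residual degrees of freedom (n - p) or n.
    rmse_denominator: Literal["n_minus_p", "n"] = "n_minus_p"
    #: constrain exponential rates to be <= 0 (decreasing trajectories).
    decreasing_rates: bool = True


class PipelineConfig(BaseModel):
    """Top-level configuration: one global seed plus per-stage sections."""

    seed: int = Field(default=0, ge=0)
    noise_multiplier: float = Field(default=1.0, ge=0)
    cohort: CohortSpec = Field(default_factory=CohortSpec)
    observer: ObserverConfig = Field(default_factory=ObserverConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    fitting: FitConfig = Field(default_factory=FitConfig)

    @property
    def effective_noise_multiplier(self) -> float:
        if self.cohort.noise_multiplier is not None:
            return self.cohort.noise_multiplier
        return self.noise_multiplier

    @property
    def effective_seed(self) -> int:
        if self.cohort.seed is not None:
            return self.cohort.seed
        return self.seed


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML configuration file; ``None`` yields all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return PipelineConfig.model_validate(raw)
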