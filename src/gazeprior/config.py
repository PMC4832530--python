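"""Study configuration: dataclasses with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field

import yaml

from .design import DEFAULT_DEVIATIONS, DEFAULT_OFFSETS, CohortSpec
from .inference import DEFAULT_PRIOR_SCALE
from .psi import DEFAULT_CRITERION

__all__ = [
    "DesignSettings",
    "PsiSettings",
    "AnalysisSettings",
    "StudyConfig",
    "experiment_one_config",
    "experiment_two_config",
]


@dataclass(frozen=True)
class DesignSettings:
    """Constants of the mixed gaze-discrimination design."""

    test_deviations: tuple[float, float] = DEFAULT_DEVIATIONS
    offsets_deg: tuple[float, ...] = DEFAULT_OFFSETS
    reps_per_offset: int = 12


@dataclass(frozen=True)
class PsiSettings:
    """Adaptive-calibration settings: run structure, criterion and grids."""

    n_runs: int = 4
    n_trials: int = 30
    criterion: float = DEFAULT_CRITERION
    baseline_deviation_deg: float = 15.0
    level_min: float = 0.02
    level_max: float = 1.0
    n_levels: int = 25
    n_alpha: int = 31
    alpha_min: float = 0.02
    alpha_max: float = 1.0
    n_beta: int = 15
    beta_min: float = 0.5
    beta_max: float = 16.0
    lapse_rate: float = 0.02
    readout: str = "mean"


@dataclass(frozen=True)
class AnalysisSettings:
    """Inference options: Bayes-factor prior scale/sidedness and grouping."""

    prior_scale: float = DEFAULT_PRIOR_SCALE
    sidedness: str = "two-sided"
    group_assignment: str = "labels"  # or "median_split" on trait_score


@dataclass(frozen=True)
class StudyConfig:
    cohorts: tuple[CohortSpec, ...]
    design: DesignSettings = field(default_factory=DesignSettings)
    psi: PsiSettings = field(default_factory=PsiSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohorts"] = [dataclasses.asdict(c) for c in self.cohorts]
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        cohorts = tuple(CohortSpec(**c) for c in d["cohorts"])
        design = DesignSettings(
            test_deviations=tuple(d.get("design", {}).get("test_deviations", DEFAULT_DEVIATIONS)),
            offsets_deg=tuple(d.get("design", {}).get("offsets_deg", DEFAULT_OFFSETS)),
            reps_per_offset=int(d.get("design", {}).get("reps_per_offset", 12)),
        )
        psi = PsiSettings(**d.get("psi", {}))
        analysis = AnalysisSettings(**d.get("analysis", {}))
        return cls(
            cohorts=cohorts,
            design=design,
            psi=psi,
            analysis=analysis,
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(text))

    def sha256(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def experiment_one_config(seed: int = 0) -> StudyConfig:
    """17 + 17 cohort with trait-score distributions matching a median-split
    low/high trait design (AQ-style means 7.75/23.24)."""
    return StudyConfig(
        cohorts=(
            CohortSpec("low", 17, trait_score_mean=7.75, trait_score_sd=2.57),
            CohortSpec("high", 17, trait_score_mean=23.24, trait_score_sd=4.8),
        ),
        seed=seed,
    )


def experiment_two_config(seed: int = 0) -> StudyConfig:
    """11 + 11 cohort emulating a matched control/clinical comparison."""
    return StudyConfig(
        cohorts=(
            CohortSpec("control", 11, trait_score_mean=12.17, trait_score_sd=4.73),
            CohortSpec("asc", 11, trait_score_mean=40.73, trait_score_sd=5.68),
        ),
        seed=seed,
    )


def flat_prior_cohort(label: str, n: int, **kwargs) -> CohortSpec:
    """A hypo-prior group: flat prior (no direct-gaze expectation)."""
    return CohortSpec(label, n, prior_sd_mean=math.inf, prior_sd_sd=0.0, **kwargs)
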