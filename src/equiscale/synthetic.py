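"""Synthetic country datasets and effectiveness studies.

Coverage by quintile, case-fatality curves and cause-of-death proportions are
not published as machine-readable tables, so the pipeline ships a generator
that produces complete :class:`~equiscale.data_model.CountryDataset`
instances with the assumed statistical structure: U5MR non-decreasing from
wealthiest to poorest, coverage non-increasing (with an optional Egypt-style
non-monotone bump), CFR and cause proportions from the configured models.

The demo scenario pins each country's quintile U5MRs to the published values
and fills the figure-only quantities (coverage, CFR, cause shares) with
plausible synthetic values; those are stand-ins, not published data.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .burden_model import (
    CauseTrendModel,
    CfrModel,
    cause_proportions,
    cfr,
    default_cause_trend_model,
    default_cfr_model,
)
from .data_model import CountryDataset, QuintileProfile
from .effectiveness_model import EffectivenessStudy
from .errors import ConfigError

__all__ = [
    "GeneratorConfig",
    "StudyGeneratorConfig",
    "generate_country",
    "generate_effectiveness_studies",
    "DEMO_COUNTRIES",
    "demo_config",
    "demo_dataset",
    "demo_datasets",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for :func:`generate_country`.

    U5MR and coverage are specified either as explicit five-value targets or
    as Q1/Q5 endpoints interpolated linearly across quintiles.  Noise scales
    are multiplicative (U5MR) and additive (coverage); monotone structure is
    restored after noise unless ``coverage_bump`` is non-zero.
    """

    country: str = "synthetic"
    seed: int = 0
    u5mr_q1: float = 50.0
    u5mr_q5: float = 150.0
    u5mr_targets: tuple[float, ...] | None = None
    u5mr_noise: float = 0.0
    coverage_q1: float = 0.6
    coverage_q5: float = 0.2
    coverage_targets: tuple[float, ...] | None = None
    #: additive bump applied to Q2 and Q3 coverage (Egypt-style pattern)
    coverage_bump: float = 0.0
    coverage_noise: float = 0.0
    births_total: float = 1_000_000.0
    cfr_model: CfrModel = field(default_factory=default_cfr_model)
    cause_model: CauseTrendModel = field(default_factory=default_cause_trend_model)
    overall_u5mr: float | None = None

    def __post_init__(self):
        if self.u5mr_targets is not None and len(self.u5mr_targets) != 5:
            raise ConfigError("u5mr_targets must have exactly 5 values")
        if self.coverage_targets is not None and len(self.coverage_targets) != 5:
            raise ConfigError("coverage_targets must have exactly 5 values")
        if self.births_total < 0:
            raise ConfigError("births_total must be >= 0")
        if min(self.u5mr_q1, self.u5mr_q5) < 0 or (
            self.u5mr_targets is not None and min(self.u5mr_targets) < 0
        ):
            raise ConfigError("u5mr values must be >= 0")
        cov = (
            self.coverage_targets
            if self.coverage_targets is not None
            else (self.coverage_q1, self.coverage_q5)
        )
        bumped = max(cov) + max(self.coverage_bump, 0.0)
        if min(cov) < 0 or bumped > 1:
            raise ConfigError(
                "coverage targets (including bump) must lie in [0, 1]"
            )


def generate_country(config: GeneratorConfig) -> CountryDataset:
    """Generate a complete, validated five-quintile country dataset.

    Deterministic given (seed, config): the same inputs always yield a
    bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)

    if config.u5mr_targets is not None:
        u5mr = np.array(config.u5mr_targets, dtype=float)
    else:
        u5mr = np.linspace(config.u5mr_q1, config.u5mr_q5, 5)
    if config.u5mr_noise > 0:
        u5mr = u5mr * (1.0 + config.u5mr_noise * rng.standard_normal(5))
        u5mr = np.sort(np.clip(u5mr, 0.0, None))  # keep Q1 <= ... <= Q5

    if config.coverage_targets is not None:
        coverage = np.array(config.coverage_targets, dtype=float)
    else:
        coverage = np.linspace(config.coverage_q1, config.coverage_q5, 5)
    if config.coverage_bump:
        coverage = coverage + np.array(
            [0.0, config.coverage_bump, config.coverage_bump, 0.0, 0.0]
        )
    if config.coverage_noise > 0:
        coverage = coverage + config.coverage_noise * rng.standard_normal(5)
        coverage = np.clip(coverage, 0.0, 1.0)
        if not config.coverage_bump:
            coverage = np.sort(coverage)[::-1]  # restore non-increasing
    coverage = np.clip(coverage, 0.0, 1.0)

    births = config.births_total / 5.0
    quintiles = tuple(
        QuintileProfile(
            country=config.country,
            quintile=i + 1,
            u5mr=float(u5mr[i]),
            coverage=float(coverage[i]),
            births=births,
            cfr=cfr(config.cfr_model, float(u5mr[i])),
            cause_proportions=cause_proportions(
                config.cause_model, float(u5mr[i])
            ),
        )
        for i in range(5)
    )
    return CountryDataset(
        country=config.country,
        quintiles=quintiles,
        overall_u5mr=config.overall_u5mr,
    )


@dataclass(frozen=True)
class StudyGeneratorConfig:
    """Configuration for :func:`generate_effectiveness_studies`.

    The true data-generating line is ``effectiveness = 100 + slope * u5mr``
    plus Gaussian noise, clamped to [0, 100]; ``slope`` is retained here for
    parameter-recovery tests.
    """

    seed: int = 0
    n_studies: int = 9
    slope: float = -0.45
    noise_sd: float = 0.0
    u5mr_min: float = 40.0
    u5mr_max: float = 160.0

    def __post_init__(self):
        if self.n_studies < 1:
            raise ConfigError("n_studies must be >= 1")
        if not (0 <= self.u5mr_min <= self.u5mr_max):
            raise ConfigError("need 0 <= u5mr_min <= u5mr_max")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def generate_effectiveness_studies(
    config: StudyGeneratorConfig,
) -> list[EffectivenessStudy]:
    """Simulate effectiveness studies from a known anchored line."""
    rng = np.random.default_rng(config.seed)
    u5mr = rng.uniform(config.u5mr_min, config.u5mr_max, config.n_studies)
    eff = 100.0 + config.slope * u5mr
    if config.noise_sd > 0:
        eff = eff + config.noise_sd * rng.standard_normal(config.n_studies)
    eff = np.clip(eff, 0.0, 100.0)
    return [
        EffectivenessStudy(
            location=f"synthetic-{i + 1}",
            year=1990 + i,
            u5mr=float(u5mr[i]),
            effectiveness=float(eff[i]),
        )
        for i in range(config.n_studies)
    ]


# ---------------------------------------------------------------------------
# Demo scenario: five exemplar-like countries
# ---------------------------------------------------------------------------

# Quintile U5MRs are the published values; coverage, births and the CFR /
# cause-trend models are synthetic stand-ins for figure-only inputs.
_DEMO = {
    "Nigeria": {
        "u5mr_targets": (87.0, 129.0, 165.0, 212.0, 219.0),
        "overall_u5mr": 189.0,
        "coverage_targets": (0.45, 0.38, 0.30, 0.21, 0.15),
        "births_total": 6_000_000.0,
    },
    "Egypt": {
        "u5mr_targets": (18.9, 27.2, 32.2, 36.1, 49.0),
        "overall_u5mr": 36.0,
        # Non-monotone pattern: Q2/Q3 above Q1, dip in Q4/Q5;
        # Q1 - Q5 difference is 7.6 percentage points.
        "coverage_targets": (0.60, 0.65, 0.64, 0.57, 0.524),
        "births_total": 1_900_000.0,
    },
    "Bangladesh": {
        "u5mr_targets": (43.0, 62.0, 83.0, 85.0, 86.0),
        "overall_u5mr": 61.0,
        # near-flat tail mirroring the near-flat Q3-Q5 mortality gradient
        "coverage_targets": (0.37, 0.33, 0.29, 0.27, 0.26),
        "births_total": 3_100_000.0,
    },
    "Cambodia": {
        "u5mr_targets": (30.0, 49.0, 68.0, 83.0, 90.0),
        "overall_u5mr": 54.0,
        "coverage_targets": (0.55, 0.44, 0.35, 0.26, 0.20),
        "births_total": 370_000.0,
    },
    "Peru": {
        "u5mr_targets": (9.0, 24.0, 24.0, 33.0, 59.0),
        "overall_u5mr": 27.0,
        "coverage_targets": (0.58, 0.52, 0.46, 0.40, 0.35),
        "births_total": 600_000.0,
    },
}

DEMO_COUNTRIES = tuple(_DEMO)


def demo_config(country: str, seed: int = 0) -> GeneratorConfig:
    """Noise-free generator config for one demo country."""
    if country not in _DEMO:
        raise ConfigError(
            f"unknown demo country {country!r}; choose from {DEMO_COUNTRIES}"
        )
    return GeneratorConfig(country=country, seed=seed, **_DEMO[country])


def demo_dataset(country: str) -> CountryDataset:
    """Fully populated demo dataset for one country (deterministic)."""
    return generate_country(demo_config(country))


def demo_datasets() -> dict[str, CountryDataset]:
    """All five demo countries."""
    return {c: demo_dataset(c) for c in DEMO_COUNTRIES}
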