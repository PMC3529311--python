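"""Burden conversion: U5MR -> deaths -> pneumonia deaths -> episodes.

Quintile deaths are ``u5mr/1000 * births``.  Cause-of-death proportions come
from a logit-linear trend model renormalized by softmax, so they form a
simplex at every U5MR; the pneumonia share times total deaths gives pneumonia
deaths, and dividing by a modelled case-fatality rate (CFR) gives episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .data_model import CountryDataset
from .errors import DomainError

__all__ = [
    "CfrModel",
    "CauseTrendModel",
    "DEFAULT_CAUSES",
    "quintile_deaths",
    "cause_proportions",
    "pneumonia_episodes",
    "cfr",
    "default_cause_trend_model",
    "default_cfr_model",
    "burden_table",
]

#: Fixed cause list used by the default trend model.
DEFAULT_CAUSES = (
    "pneumonia",
    "diarrhoea",
    "malaria",
    "preterm",
    "asphyxia",
    "congenital",
    "injury",
    "other",
)


@dataclass(frozen=True)
class CfrModel:
    """Case-fatality rate as a function of U5MR, clamped to (0, cfr_max].

    ``linear``: a + b*u5mr.  ``logistic``: cfr_max / (1 + exp(-(a + b*u5mr))).
    ``b >= 0`` is required so the CFR is non-decreasing in U5MR; ``cfr_min``
    keeps the clamped value strictly positive.
    """

    form: Literal["linear", "logistic"]
    a: float
    b: float
    cfr_max: float = 0.5
    cfr_min: float = 1e-6

    def __post_init__(self):
        if self.form not in ("linear", "logistic"):
            raise DomainError(f"unknown CFR form {self.form!r}")
        if self.b < 0:
            raise DomainError("CFR slope must be >= 0 (non-decreasing in u5mr)")
        if not (0 < self.cfr_min < self.cfr_max <= 1):
            raise DomainError("need 0 < cfr_min < cfr_max <= 1")

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "a": self.a,
            "b": self.b,
            "cfr_max": self.cfr_max,
            "cfr_min": self.cfr_min,
        }


@dataclass(frozen=True)
class CauseTrendModel:
    """Per-cause logit-linear trends in U5MR, softmax-renormalized.

    ``trends`` maps cause label -> (intercept, slope) on the log-odds scale;
    the proportion of cause c at a given u5mr is
    softmax over causes of (intercept_c + slope_c * u5mr).
    """

    trends: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        if not self.trends:
            raise DomainError("at least one cause trend required")
        object.__setattr__(self, "trends", dict(self.trends))

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(self.trends)

    def to_dict(self) -> dict:
        return {c: list(ab) for c, ab in self.trends.items()}


def quintile_deaths(u5mr: float, births: float) -> float:
    """Under-five deaths in a stratum: ``u5mr / 1000 * births``."""
    if u5mr < 0 or births < 0:
        raise DomainError("u5mr and births must be >= 0")
    return u5mr / 1000.0 * births


def cause_proportions(model: CauseTrendModel, u5mr: float) -> dict[str, float]:
    """Cause-of-death simplex at the given U5MR (sums to 1 within 1e-9)."""
    if u5mr < 0:
        raise DomainError(f"u5mr must be >= 0, got {u5mr!r}")
    causes = model.causes
    logits = np.array(
        [model.trends[c][0] + model.trends[c][1] * u5mr for c in causes]
    )
    logits -= logits.max()  # numerical stability
    weights = np.exp(logits)
    probs = weights / weights.sum()
    return dict(zip(causes, probs.tolist()))


def pneumonia_episodes(pneumonia_deaths: float, cfr_value: float) -> float:
    """Episodes implied by deaths and a case-fatality rate: deaths / CFR."""
    if cfr_value <= 0:
        raise DomainError(f"cfr must be > 0, got {cfr_value!r}")
    if pneumonia_deaths < 0:
        raise DomainError("pneumonia_deaths must be >= 0")
    return pneumonia_deaths / cfr_value


def cfr(model: CfrModel, u5mr: float) -> float:
    """Case-fatality rate at the given U5MR, clamped to [cfr_min, cfr_max]."""
    if u5mr < 0:
        raise DomainError(f"u5mr must be >= 0, got {u5mr!r}")
    if model.form == "linear":
        value = model.a + model.b * u5mr
    else:
        value = model.cfr_max / (1.0 + np.exp(-(model.a + model.b * u5mr)))
    return float(np.clip(value, model.cfr_min, model.cfr_max))


# ---------------------------------------------------------------------------
# Shipped defaults (synthetic stand-ins for unpublished inputs)
# ---------------------------------------------------------------------------

# Target cause shares at U5MR 100 and per-cause logit slopes.  Slopes are
# positive for the infectious causes (their share of deaths grows with
# background mortality) and negative for congenital/preterm/injury.
_SHARES_AT_100 = {
    "pneumonia": 0.18,
    "diarrhoea": 0.12,
    "malaria": 0.10,
    "preterm": 0.16,
    "asphyxia": 0.12,
    "congenital": 0.08,
    "injury": 0.05,
    "other": 0.19,
}
_LOGIT_SLOPES = {
    "pneumonia": 0.004,
    "diarrhoea": 0.003,
    "malaria": 0.005,
    "preterm": -0.003,
    "asphyxia": 0.0,
    "congenital": -0.006,
    "injury": -0.004,
    "other": 0.0,
}


def default_cause_trend_model() -> CauseTrendModel:
    """Default synthetic cause-trend model.

    Calibrated so the simplex at U5MR 100 equals the shipped target shares
    and infectious shares rise while congenital/preterm/injury shares fall
    as U5MR increases.
    """
    trends = {
        c: (float(np.log(_SHARES_AT_100[c]) - _LOGIT_SLOPES[c] * 100.0),
            _LOGIT_SLOPES[c])
        for c in DEFAULT_CAUSES
    }
    return CauseTrendModel(trends=trends)


def default_cfr_model() -> CfrModel:
    """Default synthetic CFR curve: logistic in U5MR.

    Rises steeply (near-exponentially over the observed U5MR range) so that
    the far higher case fatality in the poorest strata offsets their higher
    unit cost and lower effectiveness, and the highest-mortality stratum can
    have fewer episodes per death than the next one.
    """
    return CfrModel(form="logistic", a=-7.5, b=0.03, cfr_max=0.3)


def burden_table(
    dataset: CountryDataset,
    cause_model: CauseTrendModel | None = None,
    cfr_model: CfrModel | None = None,
    pneumonia_cause: str = "pneumonia",
) -> pd.DataFrame:
    """Per-quintile burden for one country.

    For each quintile: total under-five deaths, pneumonia deaths (via the
    quintile's own cause proportions if set, else ``cause_model``), the CFR
    (quintile's own if set, else ``cfr_model``) and pneumonia episodes.

    Returns a DataFrame with columns country, quintile, u5mr, births,
    deaths, pneumonia_share, pneumonia_deaths, cfr, episodes.
    """
    rows = []
    for q in dataset.quintiles:
        if q.births is None:
            raise DomainError(
                f"births unset for {dataset.country} Q{q.quintile}"
            )
        deaths = quintile_deaths(q.u5mr, q.births)
        if q.cause_proportions is not None:
            share = q.cause_proportions.get(pneumonia_cause, 0.0)
        elif cause_model is not None:
            share = cause_proportions(cause_model, q.u5mr)[pneumonia_cause]
        else:
            raise DomainError(
                f"no cause proportions for {dataset.country} Q{q.quintile} "
                "and no cause model supplied"
            )
        if q.cfr is not None:
            cfr_value = q.cfr
        elif cfr_model is not None:
            cfr_value = cfr(cfr_model, q.u5mr)
        else:
            raise DomainError(
                f"no CFR for {dataset.country} Q{q.quintile} and no CFR "
                "model supplied"
            )
        pneu_deaths = deaths * share
        rows.append(
            {
                "country": dataset.country,
                "quintile": q.quintile,
                "u5mr": q.u5mr,
                "births": q.births,
                "deaths": deaths,
                "pneumonia_share": share,
                "pneumonia_deaths": pneu_deaths,
                "cfr": cfr_value,
                "episodes": pneumonia_episodes(pneu_deaths, cfr_value),
            }
        )
    return pd.DataFrame(rows)
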