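"""Intervention effectiveness vs U5MR and the potential impact fraction.

Effectiveness of community case management declines with the background
under-five mortality rate.  It is modelled as a straight line in U5MR fitted
to historical study results, by default constrained through the
(u5mr 0, effectiveness 100%) anchor.  Quintile estimates are then moved
upward by a configurable fraction (default 50%) of the remaining gap to
100%, and converted into a potential impact fraction (PIF) for a coverage
change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .data_model import reference_effectiveness_table
from .errors import DomainError, SingularFitError

__all__ = [
    "EffectivenessStudy",
    "EffectivenessModel",
    "fit_effectiveness",
    "reference_studies",
    "reference_effectiveness_model",
    "raw_effectiveness",
    "adjust_effectiveness",
    "pif",
    "ANCHOR",
]

#: The fixed anchor: at U5MR 0, effectiveness is 100%.
ANCHOR = (0.0, 100.0)

Form = Literal["anchored-line", "ols-line"]


@dataclass(frozen=True)
class EffectivenessStudy:
    """One historical effectiveness observation."""

    location: str
    year: int
    u5mr: float
    effectiveness: float  # percent

    def __post_init__(self):
        if self.u5mr < 0:
            raise DomainError(f"u5mr must be >= 0, got {self.u5mr!r}")
        if not (0.0 <= self.effectiveness <= 100.0):
            raise DomainError(
                f"effectiveness must lie in [0, 100], got {self.effectiveness!r}"
            )


@dataclass(frozen=True)
class EffectivenessModel:
    """Fitted effectiveness-vs-U5MR line.

    ``anchored-line``: effectiveness = 100 + slope * u5mr (through the
    anchor; intercept fixed at 100).  ``ols-line``: unconstrained
    intercept + slope * u5mr.  Raw predictions are clamped to [0, 100];
    ``adjustment`` is the fraction of the remaining gap to 100% recovered
    when adjusting upward.
    """

    form: Form
    intercept: float
    slope: float
    adjustment: float = 0.5
    slope_stderr: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.adjustment <= 1.0):
            raise DomainError(
                f"adjustment must lie in [0, 1], got {self.adjustment!r}"
            )

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "intercept": self.intercept,
            "slope": self.slope,
            "adjustment": self.adjustment,
            "slope_stderr": self.slope_stderr,
        }


def fit_effectiveness(
    studies: Sequence[EffectivenessStudy],
    form: Form = "anchored-line",
    adjustment: float = 0.5,
) -> EffectivenessModel:
    """Fit the effectiveness trendline.

    ``anchored-line`` regresses (effectiveness - 100) on u5mr through the
    origin: slope = sum x*(y-100) / sum x^2.  ``ols-line`` is plain OLS of
    effectiveness on u5mr over the given studies (include the anchor as a
    study row if it should influence the fit).

    A positive fitted slope (effectiveness rising with mortality) triggers a
    warning.
    """
    if len(studies) == 0:
        raise SingularFitError("empty study list")
    x = np.array([s.u5mr for s in studies], dtype=float)
    y = np.array([s.effectiveness for s in studies], dtype=float)

    if form == "anchored-line":
        sxx = float(np.sum(x**2))
        if sxx == 0:
            raise SingularFitError("all studies at u5mr 0; slope undefined")
        slope = float(np.sum(x * (y - 100.0)) / sxx)
        intercept = 100.0
        resid = y - (100.0 + slope * x)
        dof = len(x) - 1
        sigma = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
        slope_se = sigma / np.sqrt(sxx)
    elif form == "ols-line":
        if len(x) < 2 or np.ptp(x) == 0:
            raise SingularFitError("need >= 2 distinct u5mr values for OLS")
        xbar, ybar = x.mean(), y.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
        intercept = float(ybar - slope * xbar)
        resid = y - (intercept + slope * x)
        dof = len(x) - 2
        sigma = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
        slope_se = sigma / np.sqrt(sxx)
    else:
        raise DomainError(f"unknown form {form!r}")

    if slope > 0:
        warnings.warn(
            f"fitted slope {slope:.6g} is positive: effectiveness rising "
            "with U5MR is unexpected",
            stacklevel=2,
        )
    return EffectivenessModel(
        form=form,
        intercept=intercept,
        slope=slope,
        adjustment=adjustment,
        slope_stderr=float(slope_se),
    )


def reference_studies() -> list[EffectivenessStudy]:
    """The ten bundled study rows (nine historical trials plus the anchor)."""
    table = reference_effectiveness_table()
    return [
        EffectivenessStudy(
            location=row["location"],
            year=int(row["year"]),
            u5mr=float(row["u5mr"]),
            effectiveness=float(row["effectiveness"]),
        )
        for _, row in table.iterrows()
    ]


def reference_effectiveness_model(
    form: Form = "anchored-line", adjustment: float = 0.5
) -> EffectivenessModel:
    """Effectiveness model fitted to the bundled study table."""
    return fit_effectiveness(reference_studies(), form=form, adjustment=adjustment)


def raw_effectiveness(model: EffectivenessModel, u5mr: float) -> float:
    """Model line evaluated at ``u5mr``, clamped to [0, 100] percent."""
    if u5mr < 0:
        raise DomainError(f"u5mr must be >= 0, got {u5mr!r}")
    return float(np.clip(model.intercept + model.slope * u5mr, 0.0, 100.0))


def adjust_effectiveness(raw: float, adjustment: float = 0.5) -> float:
    """Move ``raw`` upward by ``adjustment`` of the remaining gap to 100%."""
    if not (0.0 <= raw <= 100.0):
        raise DomainError(f"raw effectiveness must lie in [0, 100], got {raw!r}")
    if not (0.0 <= adjustment <= 1.0):
        raise DomainError(f"adjustment must lie in [0, 1], got {adjustment!r}")
    return raw + adjustment * (100.0 - raw)


def quintile_effectiveness(model: EffectivenessModel, u5mr: float) -> float:
    """Adjusted effectiveness (percent) for a stratum: raw line value,
    clamped, then gap-adjusted with the model's ``adjustment``."""
    return adjust_effectiveness(raw_effectiveness(model, u5mr), model.adjustment)


def pif(e_adj: float, c0: float, c1: float) -> float:
    """Potential impact fraction of raising coverage from ``c0`` to ``c1``.

    The fraction of currently observed pneumonia deaths in a stratum averted
    by the coverage increase, given adjusted effectiveness ``e_adj``
    (percent):

        pif = e * (c1 - c0) / (1 - c0 * e),   e = e_adj / 100.

    Observed deaths already reflect coverage ``c0``: among E episodes with
    untreated death risk d, observed deaths are E*d*(1 - c0*e), and the
    additional (c1 - c0) covered fraction averts E*d*e*(c1 - c0).

    Raises
    ------
    DomainError
        If coverages are outside [0, 1], ``c1 < c0``, or ``e_adj`` outside
        [0, 100]; also if ``c0 * e >= 1`` (degenerate denominator).
    """
    if not (0.0 <= e_adj <= 100.0):
        raise DomainError(f"e_adj must lie in [0, 100], got {e_adj!r}")
    if not (0.0 <= c0 <= 1.0 and 0.0 <= c1 <= 1.0):
        raise DomainError(f"coverages must lie in [0, 1], got {c0!r}, {c1!r}")
    if c1 < c0:
        raise DomainError(f"c1 ({c1!r}) must be >= c0 ({c0!r})")
    e = e_adj / 100.0
    denom = 1.0 - c0 * e
    if denom <= 0.0:
        raise DomainError(
            f"degenerate denominator: c0*e = {c0 * e!r} >= 1"
        )
    return e * (c1 - c0) / denom
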