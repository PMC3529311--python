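"""Linear non-antibiotic cost law and per-child / per-quintile costs.

The unit cost of community case management is split into a constant direct
antibiotic cost (US$ 0.27 per child treated everywhere) and a non-antibiotic
component that rises linearly with the stratum's U5MR.  The line is
calibrated by ordinary least squares against (u5mr, cost) pairs; the bundled
reference table supplies 30 such pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import ANTIBIOTIC_COST, reference_cost_table
from .errors import DomainError, SingularFitError

__all__ = [
    "CostModel",
    "fit_nonantibiotic_cost",
    "reference_cost_model",
    "cost_per_child",
    "quintile_scaleup_cost",
]


@dataclass(frozen=True)
class CostModel:
    """Calibrated unit-cost law: US$ per child treated as a function of U5MR.

    ``nonantibiotic(u5mr) = intercept + slope * u5mr``; the total adds the
    constant ``antibiotic_cost``.
    """

    intercept: float
    slope: float
    antibiotic_cost: float = ANTIBIOTIC_COST
    #: Fit diagnostics: residuals, their standard deviation, and parameter
    #: standard errors (None for models not obtained by fitting).
    residuals: tuple[float, ...] | None = None
    sigma: float | None = None
    stderr: tuple[float, float] | None = None

    def __post_init__(self):
        if self.antibiotic_cost < 0:
            raise DomainError("antibiotic_cost must be >= 0")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "antibiotic_cost": self.antibiotic_cost,
            "sigma": self.sigma,
            "stderr": list(self.stderr) if self.stderr else None,
            "residuals": list(self.residuals) if self.residuals else None,
        }


def fit_nonantibiotic_cost(
    pairs: Sequence[tuple[float, float]],
    antibiotic_cost: float = ANTIBIOTIC_COST,
) -> CostModel:
    """Fit the non-antibiotic cost line by ordinary least squares.

    Parameters
    ----------
    pairs :
        (u5mr, non-antibiotic cost US$) observations; at least two distinct
        u5mr values are required.

    Returns
    -------
    CostModel
        With residual diagnostics attached.  A non-positive fitted slope
        violates the cost-rises-with-mortality invariant and triggers a
        warning (the model is still returned for inspection).

    Raises
    ------
    SingularFitError
        If fewer than two pairs are given or all u5mr values coincide.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise SingularFitError("need at least two (u5mr, cost) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise SingularFitError("all u5mr values identical; line is singular")

    # Closed-form simple linear regression.
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)

    resid = y - (intercept + slope * x)
    n = len(x)
    dof = n - 2
    sigma = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    se_slope = sigma / np.sqrt(sxx)
    se_intercept = sigma * np.sqrt(1.0 / n + xbar**2 / sxx)

    if slope <= 0:
        warnings.warn(
            f"fitted slope {slope:.6g} is not positive: unit cost does not "
            "rise with U5MR, check input pairs",
            stacklevel=2,
        )
    return CostModel(
        intercept=intercept,
        slope=slope,
        antibiotic_cost=antibiotic_cost,
        residuals=tuple(resid.tolist()),
        sigma=sigma,
        stderr=(float(se_intercept), float(se_slope)),
    )


def reference_cost_model() -> CostModel:
    """Cost model calibrated on the 30 bundled (u5mr, cost) reference pairs."""
    table = reference_cost_table()
    pairs = list(zip(table["u5mr"], table["nonantibiotic_cost"]))
    return fit_nonantibiotic_cost(pairs)


def cost_per_child(model: CostModel, u5mr: float) -> float:
    """Total CCM cost (US$) per child treated in a stratum with given U5MR.

    ``antibiotic_cost + intercept + slope * u5mr``, floored at zero.
    """
    if u5mr < 0:
        raise DomainError(f"u5mr must be >= 0, got {u5mr!r}")
    return max(0.0, model.antibiotic_cost + model.intercept + model.slope * u5mr)


def quintile_scaleup_cost(
    cost_per_child_usd: float, episodes: float, delta_coverage: float
) -> float:
    """Cost of raising coverage by ``delta_coverage`` in one quintile.

    ``cost_per_child * episodes * delta_coverage``: the unit cost times the
    number of newly treated pneumonia episodes.
    """
    if episodes < 0:
        raise DomainError(f"episodes must be >= 0, got {episodes!r}")
    if not (0.0 <= delta_coverage <= 1.0):
        raise DomainError(
            f"delta_coverage must lie in [0, 1], got {delta_coverage!r}"
        )
    return cost_per_child_usd * episodes * delta_coverage
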