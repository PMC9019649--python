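"""Polynomial trend fits for annual score series.

Years are centered at their mean before powers are formed, so coefficients
are invariant to shifting the year origin.  The reported "trend" coefficient
is the highest-order term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .scoring import AnnualPanel

__all__ = ["TrendFit", "polynomial_trend"]


@dataclass
class TrendFit:
    degree: int
    coefficients: np.ndarray  # intercept first, then powers 1..degree
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    year_center: float

    @property
    def trend_coefficient(self) -> float:
        """Highest-order coefficient (the reported trend beta)."""
        return float(self.coefficients[-1])

    @property
    def trend_p_value(self) -> float:
        return float(self.p_values[-1])

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coefficients": self.coefficients.tolist(),
            "std_errors": self.std_errors.tolist(),
            "t_values": self.t_values.tolist(),
            "p_values": self.p_values.tolist(),
            "r_squared": self.r_squared,
            "year_center": self.year_center,
            "trend_coefficient": self.trend_coefficient,
            "trend_p_value": self.trend_p_value,
        }


def polynomial_trend(
    panel: AnnualPanel, outcome: str = "sas", degree: int = 2
) -> TrendFit:
    """OLS of the outcome on centered year powers (year - mean(year))^k.

    Requires at least ``degree + 2`` years (one residual degree of freedom).
    Years with a missing outcome are dropped before fitting.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    y = panel.column(outcome)
    years = panel.years.astype(float)
    keep = ~np.isnan(y)
    y, years = y[keep], years[keep]
    n = len(y)
    if n < degree + 2:
        raise ValueError(
            f"polynomial trend of degree {degree} needs >= {degree + 2} years, got {n}"
        )
    center = years.mean()
    centered = years - center
    design = np.column_stack([centered**k for k in range(degree + 1)])
    fit = sm.OLS(y, design).fit()
    return TrendFit(
        degree=degree,
        coefficients=np.asarray(fit.params),
        std_errors=np.asarray(fit.bse),
        t_values=np.asarray(fit.tvalues),
        p_values=np.asarray(fit.pvalues),
        r_squared=float(fit.rsquared),
        year_center=float(center),
    )
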