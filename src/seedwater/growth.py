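"""Growth-vs-applied-volume response models and the H/D seedling-quality ratio.

Final height (cm) and collar diameter (mm) respond approximately linearly to
the cumulative water volume applied across deficit treatments; over time
within one treatment the trajectory may need a quadratic term. Both are
ordinary polynomial least-squares fits; slopes carry units of response per
litre (cm/L or mm/L). No model selection is performed: a quadratic fit is
reported as requested even when its quadratic coefficient is tiny.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm

from .core import DomainError, FitError

__all__ = ["GrowthFit", "HDRatio", "fit_response", "predict", "hd_ratio"]

Kind = Literal["linear", "quadratic"]

#: H/D values at or above this are flagged as outside the quality range
HD_LIMIT = 8.0


@dataclass(frozen=True)
class GrowthFit:
    """A polynomial response fit: value = intercept + slope*V (+ quad*V^2)."""

    kind: str
    response: str
    intercept: float
    slope: float
    quad: float | None
    r_squared: float
    n: int
    p_slope: float

    @property
    def coefficients(self) -> tuple[float, ...]:
        if self.kind == "quadratic":
            return (self.intercept, self.slope, self.quad if self.quad is not None else 0.0)
        return (self.intercept, self.slope)


class HDRatio(NamedTuple):
    """Height/diameter quality index (cm/mm) with its out-of-range flag."""

    value: float
    exceeds_limit: bool


def fit_response(
    points: Sequence[tuple[float, float]],
    kind: Kind = "linear",
    response: str = "height",
) -> GrowthFit:
    """Ordinary least-squares polynomial fit of a growth value on volume (L).

    Requires at least 2 distinct volumes for a linear fit and 3 for a
    quadratic one; an all-equal-volume design raises :class:`FitError`.
    ``p_slope`` is the classical two-sided t-test p-value of the linear
    coefficient (NaN when the residual degrees of freedom are zero).
    """
    if kind not in ("linear", "quadratic"):
        raise ValueError(f"kind must be 'linear' or 'quadratic', got {kind!r}")
    v = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    n_distinct = np.unique(v).size
    need = 2 if kind == "linear" else 3
    if n_distinct < need:
        raise FitError(
            f"{kind} fit needs >= {need} distinct volumes, got {n_distinct}"
        )

    cols = [np.ones_like(v), v] + ([v**2] if kind == "quadratic" else [])
    X = np.column_stack(cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        model = sm.OLS(y, X).fit()
        r2_raw = model.rsquared
    params = model.params
    dof = len(points) - X.shape[1]
    p_slope = float(model.pvalues[1]) if dof > 0 else float("nan")
    if not np.isfinite(r2_raw):
        # constant response: zero total variance; the fit is exact iff ssr ~ 0
        r2_raw = 1.0 if model.ssr <= 1e-24 else 0.0
    # exact fits can return r^2 = 1 + eps; clamp into the unit interval
    r2 = float(min(max(r2_raw, 0.0), 1.0))
    return GrowthFit(
        kind=kind, response=response,
        intercept=float(params[0]), slope=float(params[1]),
        quad=float(params[2]) if kind == "quadratic" else None,
        r_squared=r2, n=len(points), p_slope=p_slope,
    )


def predict(fit: GrowthFit, volume: float) -> float:
    """Evaluate the fitted polynomial at a volume (L)."""
    out = fit.intercept + fit.slope * volume
    if fit.kind == "quadratic" and fit.quad is not None:
        out += fit.quad * volume * volume
    return out


def hd_ratio(height: float, diameter: float) -> HDRatio:
    """Height (cm) over collar diameter (mm), the seedling-quality index.

    Values below 8.0 indicate a well-proportioned seedling; the flag is set
    at and above that bound (the boundary itself is non-compliant).
    """
    if diameter <= 0:
        raise DomainError(f"diameter must be > 0, got {diameter}")
    if height < 0:
        raise DomainError(f"height must be >= 0, got {height}")
    value = height / diameter
    return HDRatio(value=value, exceeds_limit=value >= HD_LIMIT)
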