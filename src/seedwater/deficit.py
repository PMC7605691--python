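"""Growth plant factor (Gpf): deficit sensitivity of seedling growth.

The Gpf transfers the FAO yield-response-factor (Ky) concept to seedling
growth variables. For a growth variable Va (height, cm, or diameter, mm)
observed under treatments that applied cumulative volumes Vola, with Volm
the full-replacement (V4) volume, the model is a straight line through the
origin in deficit coordinates::

    1 - Va/Vm = Gpf * (1 - Vola/Volm)

Vm, the asymptotic no-deficit value of the variable, is not observed: it is
chosen so that the ordinary least-squares intercept of y = 1 - Va/Vm on
x = 1 - Vola/Volm is exactly zero, and Gpf is the slope at that Vm. The
original procedure solved this iteratively (spreadsheet solver); here the
intercept condition has a closed form. Writing x-bar for the mean deficit,
S_xx for the centred sum of squares of x and S_xVa for the centred
cross-product of x with Va, the OLS intercept as a function of Vm is

    a(Vm) = 1 - Vm* / Vm,   with   Vm* = mean(Va) - x-bar * S_xVa / S_xx,

a strictly increasing function of Vm with the unique root Vm*, whence

    Gpf = -S_xVa / (Vm* * S_xx).

``method="closed_form"`` evaluates this directly (the default);
``method="root_find"`` brackets a(Vm) and solves it numerically with Brent's
method, mirroring the iterative procedure and serving as a cross-check.

Interpretation follows the Ky convention: Gpf < 1 means the relative growth
loss is smaller than the relative water deficit ("low sensitivity").

Note that Vm* may resolve slightly below the largest observed Va (giving a
small negative deficit y for the wettest treatment); this is expected
whenever the wettest treatment over-performs the fitted line and is allowed
by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .core import ConvergenceError, DomainError, FitError, PhaseDataset

__all__ = [
    "DeficitResponseFit",
    "deficit_points",
    "estimate_gpf",
    "classify_sensitivity",
    "gpf_table",
]

Method = Literal["closed_form", "root_find"]

#: absolute tolerance on the intercept at the reported solution
INTERCEPT_TOL = 1e-10
#: bracket for the numerical root search, as multiples of max(Va)
ROOT_BRACKET = (0.5, 50.0)
_MAX_ITER = 200


@dataclass(frozen=True)
class DeficitResponseFit:
    """An estimated (Gpf, Vm) pair for one species x growth variable."""

    species: str
    response: str              # "height" or "diameter"
    gpf: float                 # dimensionless slope in deficit coordinates
    vm: float                  # asymptotic variable value (cm or mm)
    intercept_at_solution: float
    n_treatments: int
    method: str
    iterations: int = 0        # root_find only; 0 for closed_form

    @property
    def sensitivity(self) -> str:
        return classify_sensitivity(self.gpf)


def deficit_points(
    values: Sequence[tuple[float, float]], volm: float, vm: float
) -> list[tuple[float, float]]:
    """Map (Vola, Va) pairs into deficit coordinates (x, y).

    x = 1 - Vola/Volm is the relative water deficit (0 for the wettest
    treatment); y = 1 - Va/Vm is the relative growth reduction, which may be
    negative when Va exceeds the candidate Vm. Input order is preserved.
    """
    if volm <= 0:
        raise DomainError(f"volm must be > 0, got {volm}")
    if vm <= 0:
        raise DomainError(f"vm must be > 0, got {vm}")
    pts = []
    for vola, va in values:
        if vola > volm * (1 + 1e-12):
            raise DomainError(f"applied volume {vola} exceeds maximum {volm}")
        pts.append((1.0 - vola / volm, 1.0 - va / vm))
    return pts


def _deficit_stats(values: Sequence[tuple[float, float]], volm: float):
    """Deficit x, observed Va, and the centred moments driving the fit."""
    x = np.array([1.0 - vola / volm for vola, _ in values], dtype=float)
    va = np.array([va for _, va in values], dtype=float)
    xbar = x.mean()
    dx = x - xbar
    s_xx = float(dx @ dx)
    s_xva = float(dx @ (va - va.mean()))
    return x, va, xbar, s_xx, s_xva


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Plain OLS (slope, intercept) of y on x."""
    dx = x - x.mean()
    slope = float(dx @ (y - y.mean())) / float(dx @ dx)
    return slope, float(y.mean() - slope * x.mean())


def estimate_gpf(
    values: Sequence[tuple[float, float]],
    volm: float,
    method: Method = "closed_form",
    species: str = "",
    response: str = "height",
) -> DeficitResponseFit:
    """Estimate (Gpf, Vm) from per-treatment (applied volume, growth value) pairs.

    Parameters
    ----------
    values
        One (Vola, Va) pair per treatment; at least 3 treatments with
        distinct applied volumes, all Va > 0.
    volm
        Full-replacement volume (L); every Vola must be <= volm.
    method
        ``"closed_form"`` (default) evaluates the analytic root of the
        intercept condition; ``"root_find"`` solves it with Brent's method
        on a bracketed interval, mirroring the original iterative search.
    """
    if len(values) < 3:
        raise FitError("at least 3 treatments are required to estimate Gpf")
    if any(va <= 0 for _, va in values):
        raise FitError("all growth values must be positive")
    if volm <= 0:
        raise DomainError(f"volm must be > 0, got {volm}")
    for vola, _ in values:
        if vola > volm * (1 + 1e-12):
            raise DomainError(f"applied volume {vola} exceeds maximum {volm}")

    x, va, xbar, s_xx, s_xva = _deficit_stats(values, volm)
    if s_xx <= 0:
        raise FitError("degenerate design: all treatments applied the same volume")

    vm_star = float(va.mean() - xbar * s_xva / s_xx)

    if method == "closed_form":
        if vm_star <= 0:
            raise ConvergenceError(
                f"intercept condition has no positive root (vm*={vm_star:.4g})"
            )
        vm, iterations = vm_star, 0
    elif method == "root_find":
        vm, iterations = _root_find_vm(x, va)
    else:
        raise ValueError(f"unknown method {method!r}")

    slope, intercept = _ols_line(x, 1.0 - va / vm)
    if abs(intercept) > 1e-8:
        raise ConvergenceError(
            f"residual intercept {intercept:.3e} exceeds tolerance at vm={vm:.6g}"
        )
    return DeficitResponseFit(
        species=species, response=response, gpf=slope, vm=vm,
        intercept_at_solution=intercept, n_treatments=len(values),
        method=method, iterations=iterations,
    )


def _root_find_vm(x: np.ndarray, va: np.ndarray) -> tuple[float, int]:
    """Solve a(Vm) = 0 by Brent's method on [0.5, 50] x max(Va)."""

    def intercept(vm: float) -> float:
        _, a = _ols_line(x, 1.0 - va / vm)
        return a

    lo = ROOT_BRACKET[0] * float(va.max())
    hi = ROOT_BRACKET[1] * float(va.max())
    a_lo, a_hi = intercept(lo), intercept(hi)
    if a_lo == 0.0:
        return lo, 0
    if a_lo * a_hi > 0:
        raise ConvergenceError(
            f"intercept does not change sign on bracket [{lo:.4g}, {hi:.4g}]"
        )
    vm, res = brentq(intercept, lo, hi, xtol=1e-12, rtol=4 * np.finfo(float).eps,
                     maxiter=_MAX_ITER, full_output=True)
    if not res.converged:
        raise ConvergenceError("Brent iteration did not converge")
    return float(vm), int(res.iterations)


def classify_sensitivity(gpf: float, tol: float = 1e-9) -> str:
    """Ky-style interpretation of a Gpf value.

    Below 1 the relative growth loss is smaller than the relative water
    deficit ("low sensitivity"); above 1 it is larger ("high sensitivity").
    """
    if not np.isfinite(gpf):
        raise DomainError(f"gpf must be finite, got {gpf}")
    if gpf < 1.0 - tol:
        return "low sensitivity"
    if gpf > 1.0 + tol:
        return "high sensitivity"
    return "proportional"


def gpf_table(
    ds: PhaseDataset,
    phase: str = "tube",
    method: Method = "closed_form",
    use_replicates: bool = False,
) -> list[DeficitResponseFit]:
    """Estimate Gpf for every species and both growth variables in a dataset.

    By default each treatment contributes its replicate-mean final size
    (four points per fit, matching how the published figures were built).
    ``use_replicates=True`` fits on individual replicate observations
    instead; this is experimental — the published estimates cannot be
    checked at replicate level because the raw data was never released.
    """
    fits: list[DeficitResponseFit] = []
    final = ds.final_sizes(phase)
    for sp, g in final.groupby("species", sort=True):
        volm = float(g["total_volume_l"].max())
        for response, col in (("height", "height_cm"), ("diameter", "diameter_mm")):
            if use_replicates:
                values = _replicate_values(ds, phase, str(sp), col)
            else:
                values = list(zip(g["total_volume_l"], g[col]))
            fits.append(estimate_gpf(values, volm, method=method,
                                     species=str(sp), response=response))
    return fits


def _replicate_values(
    ds: PhaseDataset, phase: str, species: str, col: str
) -> list[tuple[float, float]]:
    df = ds.to_frame()
    df = df[(df["phase"] == phase) & (df["species"] == species)]
    out: list[tuple[float, float]] = []
    for trt, g in df.groupby("treatment"):
        last = g[g["day"] == g["day"].max()]
        spec = ds.treatments[(species, phase, str(trt))]
        out.extend((spec.total_volume, float(v)) for v in last[col])
    return out
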