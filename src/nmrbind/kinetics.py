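"""Degradation kinetics and half-life estimation.

Slow aqueous degradation (e.g. retro-Mannich loss of an aminomethyl
substituent, pseudo-unimolecular in water) is modelled first-order by
default:

    f(t) = A0 * exp(-k * t),    t_half = ln 2 / k

with the intact fraction tracked by NMR integrals or HPLC areas normalized
to the t = 0 point.  A zero-order variant (``f = A0 - k*t``,
``t_half = A0 / (2k)``) is provided for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import lmfit
import numpy as np

__all__ = [
    "DecaySeries",
    "KineticsResult",
    "predict_remaining_fraction",
    "fit_decay",
]

Normalization = Literal["fixed_1", "fitted_A0"]


@dataclass(frozen=True)
class DecaySeries:
    """Intact-fraction time course; times in days, strictly increasing."""

    compound_id: str
    time_days: np.ndarray
    intact_fraction: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_days, dtype=float)
        f = np.asarray(self.intact_fraction, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("time and fraction must be aligned 1-D arrays")
        if t.size < 3:
            raise ValueError(">= 3 time points required")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("fractions must be finite")
        object.__setattr__(self, "time_days", t)
        object.__setattr__(self, "intact_fraction", f)

    def normalized(self) -> "DecaySeries":
        """Rescale so the first point is 1 (for raw integrals/areas)."""
        f0 = self.intact_fraction[0]
        if f0 <= 0:
            raise ValueError("cannot normalize: first point is <= 0")
        return DecaySeries(self.compound_id, self.time_days,
                           self.intact_fraction / f0)


@dataclass(frozen=True)
class KineticsResult:
    compound_id: str
    k_per_day: float
    t_half_days: float
    rss: float
    normalization: Normalization
    order: int = 1


def predict_remaining_fraction(k: float, t, order: int = 1, A0: float = 1.0):
    """Remaining intact fraction at time t (days) for rate k (day^-1)."""
    t = np.asarray(t, dtype=float)
    if k < 0 or np.any(t < 0):
        raise ValueError("k and t must be >= 0")
    out = A0 * np.exp(-k * t) if order == 1 else A0 - k * t
    return out if out.ndim else float(out)


def fit_decay(series: DecaySeries,
              normalization: Normalization = "fixed_1",
              order: int = 1) -> KineticsResult:
    """Least-squares decay fit and half-life.

    ``normalization='fixed_1'`` pins the initial amplitude at 1 (data
    already normalized); ``'fitted_A0'`` frees it.  First-order by default;
    ``order=0`` fits a linear loss instead.  A negative fitted rate is
    clipped to 0 with a warning (t_half = inf); a flat series is an error.
    """
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    t, f = series.time_days, series.intact_fraction
    if np.ptp(f) == 0.0:
        raise ValueError("no decay detectable: series is constant")

    params = lmfit.Parameters()
    # crude slope-based start; exact for noiseless first-order data at t_half
    k0 = max(1e-6, -np.polyfit(t, np.log(np.clip(f, 1e-12, None)), 1)[0]) \
        if order == 1 else max(1e-6, -np.polyfit(t, f, 1)[0])
    params.add("k", value=k0)
    params.add("A0", value=float(f[0]), vary=(normalization == "fitted_A0"))
    if normalization == "fixed_1":
        params["A0"].value = 1.0

    def residual(p):
        k, a0 = p["k"].value, p["A0"].value
        pred = a0 * np.exp(-k * t) if order == 1 else a0 - k * t
        return pred - f

    res = lmfit.minimize(params=params, fcn=residual, method="least_squares")
    k = float(res.params["k"].value)
    if k < 0:
        warnings.warn("fitted rate was negative; clipped to 0", stacklevel=2)
        k = 0.0
    if k == 0.0:
        t_half = float("inf")
    elif order == 1:
        t_half = float(np.log(2.0) / k)
    else:
        t_half = float(res.params["A0"].value / (2.0 * k))
    return KineticsResult(compound_id=series.compound_id, k_per_day=k,
                          t_half_days=t_half, rss=float(res.chisqr),
                          normalization=normalization, order=order)
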