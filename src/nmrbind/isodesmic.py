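"""Indefinite (isodesmic) self-association from NMR dilution series.

Planar aromatic drugs stack in water. Under the isodesmic model every
stacking step ``L_n + L <-> L_{n+1}`` shares a single equilibrium constant
``Ka`` (mM^-1), so the whole oligomer ladder is controlled by one number.
Under fast exchange a proton's observed chemical shift is the population
average over all stack environments, and its displacement from the monomer
shift follows a closed-form isotherm in the total concentration ``L0``:

    ddelta_obs = delta_mon - delta_obs
               = ddelta_max * Ka * L0 * (2 / (1 + sqrt(1 + 4*Ka*L0)))**2

which is algebraically identical to ``ddelta_max * Ka * [L]`` with ``[L]``
the free-monomer concentration.  Fitting this isotherm per proton over a
dilution series yields ``Ka``, the monomer shift ``delta_mon`` and the
limiting stacking shift ``ddelta_max``.

Sign convention: ``ddelta_obs = delta_mon - delta_obs`` — protons that move
upfield (to low frequency) on stacking, the common case for ring-current
shielding, have positive ``ddelta_max``; a proton pushed the other way is
represented by a negative ``ddelta_max`` rather than excluded.

Units are fixed: concentrations in mM, Ka in mM^-1, shifts in ppm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import lmfit
import numpy as np

__all__ = [
    "ProtonShiftSeries",
    "DilutionExperiment",
    "ProtonSelfAssociation",
    "SelfAssociationFit",
    "DomainError",
    "FitError",
    "monomer_concentration",
    "oligomer_distribution",
    "predict_dilution_shift",
    "fit_isodesmic",
]

#: Default bounds/start for the association constant, mM^-1.
KA_BOUNDS = (0.0, 1.0e3)
KA_START = 1.0

#: Jittered restarts attempted when a fit fails to converge.
N_RESTARTS = 3

#: 1H frequency (MHz) used when converting ppm to Hz; instrument-specific.
DEFAULT_SPECTROMETER_MHZ = 499.8


class DomainError(ValueError):
    """Input outside the physical domain of a model (negative Ka, etc.)."""


class FitError(RuntimeError):
    """A nonlinear fit failed to converge after bounded restarts."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtonShiftSeries:
    """One proton's chemical-shift trace across a concentration grid.

    Points are sorted by concentration on construction; concentrations must
    be strictly positive and distinct, shifts finite.
    """

    proton_label: str
    concentrations_mM: np.ndarray
    shifts_ppm: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations_mM, dtype=float)
        shift = np.asarray(self.shifts_ppm, dtype=float)
        if conc.ndim != 1 or conc.shape != shift.shape:
            raise ValueError("concentrations and shifts must be 1-D and aligned")
        if conc.size == 0:
            raise ValueError(f"{self.proton_label}: empty series")
        if not np.all(np.isfinite(conc)) or not np.all(np.isfinite(shift)):
            raise ValueError(f"{self.proton_label}: non-finite values")
        if np.any(conc <= 0):
            raise ValueError(f"{self.proton_label}: concentrations must be > 0")
        order = np.argsort(conc)
        conc, shift = conc[order], shift[order]
        if np.any(np.diff(conc) <= 0):
            raise ValueError(f"{self.proton_label}: duplicate concentrations")
        object.__setattr__(self, "concentrations_mM", conc)
        object.__setattr__(self, "shifts_ppm", shift)

    def __len__(self) -> int:
        return self.concentrations_mM.size


@dataclass(frozen=True)
class DilutionExperiment:
    """Per-proton shift series sharing one concentration grid."""

    compound_id: str
    series: tuple[ProtonShiftSeries, ...]
    temperature_C: float = 10.0
    pH: float = 6.4

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("at least one proton series is required")
        object.__setattr__(self, "series", tuple(self.series))
        n = len(self.series[0])
        if any(len(s) != n for s in self.series):
            raise ValueError("all series must share one concentration grid")

    @property
    def proton_labels(self) -> tuple[str, ...]:
        return tuple(s.proton_label for s in self.series)


@dataclass(frozen=True)
class ProtonSelfAssociation:
    """Single-proton isodesmic fit result."""

    proton_label: str
    Ka_mM_inv: float
    delta_mon_ppm: float
    delta_max_ppm: float
    rss_ppm2: float


@dataclass(frozen=True)
class SelfAssociationFit:
    """Pooled self-association result.

    In ``per_proton_average`` mode ``Ka_mean``/``Ka_sd`` are the arithmetic
    mean and sample standard deviation of the independent per-proton Ka
    values (excluded protons left out); in ``global`` mode a single shared
    Ka was fitted and ``Ka_sd`` is its asymptotic standard error (NaN if
    unavailable).
    """

    compound_id: str
    per_proton: tuple[ProtonSelfAssociation, ...]
    Ka_mean_mM_inv: float
    Ka_sd_mM_inv: float
    mode: Literal["per_proton_average", "global"]
    excluded: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _check_domain(Ka: float, L0) -> None:
    L0 = np.asarray(L0, dtype=float)
    if not np.isfinite(Ka) or Ka < 0:
        raise DomainError(f"Ka must be finite and >= 0, got {Ka}")
    if not np.all(np.isfinite(L0)) or np.any(L0 <= 0):
        raise DomainError("total concentration must be finite and > 0")


def monomer_concentration(Ka: float, L0):
    """Free-monomer concentration [L] under the isodesmic mass balance.

    Inverts ``L0 = [L] / (1 - Ka*[L])**2`` in closed form:
    ``[L] = L0 * (2 / (1 + sqrt(1 + 4*Ka*L0)))**2``.  At ``Ka = 0`` this
    returns ``L0`` exactly.  Accepts scalar or array ``L0``.
    """
    _check_domain(Ka, L0)
    L0 = np.asarray(L0, dtype=float)
    out = L0 * (2.0 / (1.0 + np.sqrt(1.0 + 4.0 * Ka * L0))) ** 2
    return out if out.ndim else float(out)


def oligomer_distribution(Ka: float, L0: float, n_max: int) -> np.ndarray:
    """Concentrations of n-mers ``[L_n] = Ka**(n-1) * [L]**n`` for n=1..n_max.

    The mass balance ``sum(n * [L_n])`` converges to ``L0`` as
    ``n_max -> inf`` (geometric series with ratio ``Ka*[L] < 1``).
    """
    if n_max < 1:
        raise DomainError("n_max must be >= 1")
    mono = monomer_concentration(Ka, L0)
    x = Ka * mono
    if x >= 1.0:
        raise RuntimeError("internal error: Ka*[L] >= 1 violates the isodesmic bound")
    n = np.arange(1, n_max + 1)
    with np.errstate(divide="ignore"):
        # [L_n] = x**(n-1) * mono; exact zeros for Ka = 0 beyond the monomer
        return mono * x ** (n - 1)


def predict_dilution_shift(Ka: float, L0, delta_max: float):
    """Shift displacement ``ddelta_obs = delta_mon - delta_obs`` at ``L0``.

    ``ddelta_obs = delta_max * Ka*L0 * (2/(1 + sqrt(1 + 4*Ka*L0)))**2``,
    equal to ``delta_max * Ka * [L]``; bounded by ``|delta_max|`` and zero
    in the monomer limit.
    """
    _check_domain(Ka, L0)
    L0 = np.asarray(L0, dtype=float)
    q = Ka * L0
    out = delta_max * q * (2.0 / (1.0 + np.sqrt(1.0 + 4.0 * q))) ** 2
    return out if out.ndim else float(out)


def observed_dilution_shift(Ka: float, L0, delta_mon: float, delta_max: float):
    """Observed shift ``delta_obs = delta_mon - ddelta_obs(L0)`` in ppm."""
    return delta_mon - predict_dilution_shift(Ka, L0, delta_max)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _series_start(series: ProtonShiftSeries) -> tuple[float, float]:
    """Initial (delta_mon, delta_max): shift at lowest concentration, and the
    signed swing from most-dilute to most-concentrated point."""
    d0 = float(series.shifts_ppm[0])
    swing = float(series.shifts_ppm[0] - series.shifts_ppm[-1])
    if swing == 0.0:
        swing = 1e-3
    return d0, swing


def _fit_one_proton(series: ProtonShiftSeries,
                    weights: np.ndarray | None,
                    rng: np.random.Generator) -> ProtonSelfAssociation:
    conc, obs = series.concentrations_mM, series.shifts_ppm
    d0, swing = _series_start(series)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        pred = observed_dilution_shift(params["Ka"].value, conc,
                                       params["delta_mon"].value,
                                       params["delta_max"].value)
        r = pred - obs
        return r if weights is None else r * weights

    best = None
    for attempt in range(1 + N_RESTARTS):
        params = lmfit.Parameters()
        ka0 = KA_START if attempt == 0 else float(10.0 ** rng.uniform(-1.5, 1.5))
        dm0 = swing if attempt == 0 else swing * float(rng.uniform(0.3, 3.0))
        params.add("Ka", value=ka0, min=KA_BOUNDS[0], max=KA_BOUNDS[1])
        params.add("delta_mon", value=d0)
        params.add("delta_max", value=dm0)
        try:
            res = lmfit.minimize(residual, params, method="least_squares")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
        if best is not None and attempt == 0:
            break
    if best is None:
        raise FitError(f"isodesmic fit did not converge for proton "
                       f"{series.proton_label!r}")
    p = best.params
    return ProtonSelfAssociation(
        proton_label=series.proton_label,
        Ka_mM_inv=float(p["Ka"].value),
        delta_mon_ppm=float(p["delta_mon"].value),
        delta_max_ppm=float(p["delta_max"].value),
        rss_ppm2=float(best.chisqr),
    )


def fit_isodesmic(
    exp: DilutionExperiment,
    mode: Literal["per_proton_average", "global"] = "per_proton_average",
    *,
    noise_floor_ppm: float = 0.0,
    exclude: Sequence[str] = (),
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> SelfAssociationFit:
    """Fit the isodesmic isotherm to every proton of a dilution experiment.

    Parameters
    ----------
    exp
        Dilution experiment; each series needs >= 4 points spanning at
        least one decade of concentration.
    mode
        ``per_proton_average`` (default): independent (Ka, delta_mon,
        delta_max) per proton, pooled as mean +/- SD of the per-proton Ka.
        ``global``: one shared Ka with per-proton shift parameters.
    noise_floor_ppm
        Protons whose total observed swing is below this floor are fitted
        but flagged and left out of the pooled mean (their isotherm carries
        no Ka information).
    exclude
        Proton labels to drop entirely before fitting.
    weights
        Optional per-point weights (1/sigma) applied to all series.
    seed
        Seed for the jittered multi-start fallback.
    """
    series = [s for s in exp.series if s.proton_label not in set(exclude)]
    if not series:
        raise ValueError("no series left after exclusions")
    for s in series:
        if len(s) < 4:
            raise ValueError(f"{s.proton_label}: >= 4 points required")
        span = s.concentrations_mM[-1] / s.concentrations_mM[0]
        if span < 10.0:
            raise ValueError(
                f"{s.proton_label}: concentration grid spans {span:.2f}x; "
                "at least one decade is required to constrain Ka")
    rng = np.random.default_rng(seed)

    flagged = tuple(
        s.proton_label for s in series
        if abs(float(s.shifts_ppm[0] - s.shifts_ppm[-1])) < noise_floor_ppm
    )
    if flagged:
        warnings.warn(
            f"shift swing below noise floor, excluded from pooled Ka: "
            f"{', '.join(flagged)}", stacklevel=2)

    if mode == "per_proton_average":
        per = tuple(_fit_one_proton(s, weights, rng) for s in series)
        pooled = [p.Ka_mM_inv for p in per if p.proton_label not in flagged]
        if not pooled:
            raise FitError("every proton fell below the noise floor")
        ka_mean = float(np.mean(pooled))
        ka_sd = float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0
    elif mode == "global":
        per, ka_mean, ka_sd = _fit_global(series, flagged, weights, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return SelfAssociationFit(
        compound_id=exp.compound_id, per_proton=per,
        Ka_mean_mM_inv=ka_mean, Ka_sd_mM_inv=ka_sd,
        mode=mode, excluded=flagged,
    )


def _fit_global(series, flagged, weights, rng):
    """One shared Ka across protons; per-proton (delta_mon, delta_max)."""
    fitted = [s for s in series if s.proton_label not in flagged]
    if not fitted:
        raise FitError("every proton fell below the noise floor")

    def residual(params: lmfit.Parameters) -> np.ndarray:
        ka = params["Ka"].value
        parts = []
        for i, s in enumerate(fitted):
            pred = observed_dilution_shift(
                ka, s.concentrations_mM,
                params[f"dmon_{i}"].value, params[f"dmax_{i}"].value)
            r = pred - s.shifts_ppm
            parts.append(r if weights is None else r * weights)
        return np.concatenate(parts)

    best = None
    for attempt in range(1 + N_RESTARTS):
        params = lmfit.Parameters()
        ka0 = KA_START if attempt == 0 else float(10.0 ** rng.uniform(-1.5, 1.5))
        params.add("Ka", value=ka0, min=KA_BOUNDS[0], max=KA_BOUNDS[1])
        for i, s in enumerate(fitted):
            d0, swing = _series_start(s)
            params.add(f"dmon_{i}", value=d0)
            params.add(f"dmax_{i}", value=swing)
        try:
            res = lmfit.minimize(residual, params, method="least_squares")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
        if best is not None and attempt == 0:
            break
    if best is None:
        raise FitError("global isodesmic fit did not converge")

    ka = float(best.params["Ka"].value)
    stderr = best.params["Ka"].stderr
    per = []
    for i, s in enumerate(fitted):
        pred = observed_dilution_shift(
            ka, s.concentrations_mM,
            best.params[f"dmon_{i}"].value, best.params[f"dmax_{i}"].value)
        per.append(ProtonSelfAssociation(
            proton_label=s.proton_label, Ka_mM_inv=ka,
            delta_mon_ppm=float(best.params[f"dmon_{i}"].value),
            delta_max_ppm=float(best.params[f"dmax_{i}"].value),
            rss_ppm2=float(np.sum((pred - s.shifts_ppm) ** 2)),
        ))
    return tuple(per), ka, (float(stderr) if stderr is not None else float("nan"))
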