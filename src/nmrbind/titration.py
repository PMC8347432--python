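"""1:1 DNA-duplex / ligand binding from chemical-shift titrations.

A ligand L in fast exchange between its free state and a 1:1 complex with a
DNA duplex shows a population-averaged shift.  With

    Ka = [DNA.L] / ([DNA][L])          (mM^-1, duplex counted as duplexes)

the shift change of a ligand proton at each titration point is

    ddelta = delta_obs - delta_L
           = ddelta_complex * Ka*[DNA] / (1 + Ka*[DNA])

where ``delta_L`` is the ligand shift without DNA and ``ddelta_complex`` is
the limiting shift change in the complex.  Two conventions for ``[DNA]``
are exposed: the exact equilibrium free-duplex concentration from the 1:1
quadratic (``free_exact``, default) or the total duplex concentration
(``total_approx``), the common approximation when titrant is in excess.

Sign convention here follows the titration literature: ``ddelta = delta_obs
- delta_L``, so upfield (stacking) shifts give negative ``ddelta_complex``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import lmfit
import numpy as np

from .isodesmic import (
    KA_BOUNDS,
    KA_START,
    N_RESTARTS,
    DomainError,
    FitError,
    SelfAssociationFit,
    observed_dilution_shift,
)

__all__ = [
    "TitrationExperiment",
    "ProtonBinding",
    "BindingFit",
    "free_dna_concentration",
    "complex_concentration",
    "bound_ligand_fraction",
    "predict_titration_shift",
    "fit_binding_titration",
]

DnaMode = Literal["free_exact", "total_approx"]

#: Below this bound-ligand fraction anywhere in the titration, Ka and
#: ddelta_complex are nearly collinear and the fit is flagged.
MIN_SATURATION = 0.20


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationExperiment:
    """Per-proton ligand shifts along a DNA titration.

    ``C_L_mM`` and ``C_DNA_mM`` are total ligand and total duplex
    concentrations per point; ``series`` maps proton label -> observed
    shifts aligned with the points.  ``baseline_shift`` carries delta_L per
    proton; if absent, the first point must have C_DNA = 0 and defines it.
    """

    compound_id: str
    duplex_id: str
    C_L_mM: np.ndarray
    C_DNA_mM: np.ndarray
    series: Mapping[str, np.ndarray]
    baseline_shift: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        cl = np.asarray(self.C_L_mM, dtype=float)
        cd = np.asarray(self.C_DNA_mM, dtype=float)
        if cl.shape != cd.shape or cl.ndim != 1 or cl.size == 0:
            raise ValueError("C_L and C_DNA must be aligned 1-D arrays")
        if np.any(cl <= 0) or np.any(cd < 0):
            raise ValueError("C_L must be > 0 and C_DNA >= 0")
        if np.any(np.diff(cd) < 0):
            raise ValueError("C_DNA must be non-decreasing over the titration")
        ser = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        if not ser:
            raise ValueError("at least one proton series is required")
        for label, shifts in ser.items():
            if shifts.shape != cl.shape:
                raise ValueError(f"{label}: series length != number of points")
            if not np.all(np.isfinite(shifts)):
                raise ValueError(f"{label}: non-finite shifts")
        object.__setattr__(self, "C_L_mM", cl)
        object.__setattr__(self, "C_DNA_mM", cd)
        object.__setattr__(self, "series", ser)

    def delta_L(self, label: str) -> float:
        """Baseline ligand shift for a proton (explicit, or the C_DNA=0 point)."""
        if self.baseline_shift is not None and label in self.baseline_shift:
            return float(self.baseline_shift[label])
        if self.C_DNA_mM[0] == 0.0:
            return float(self.series[label][0])
        raise ValueError(
            f"{label}: no baseline shift and no C_DNA = 0 point to define it")

    @property
    def n_points(self) -> int:
        return self.C_L_mM.size


@dataclass(frozen=True)
class ProtonBinding:
    proton_label: str
    Ka_mM_inv: float
    delta_complex_ppm: float
    rss_ppm2: float


@dataclass(frozen=True)
class BindingFit:
    """Pooled 1:1 binding result (mean +/- SD over per-proton Ka)."""

    compound_id: str
    duplex_id: str
    per_proton: tuple[ProtonBinding, ...]
    Ka_mean_mM_inv: float
    Ka_sd_mM_inv: float
    dna_mode: DnaMode
    excluded: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Equilibrium algebra
# ---------------------------------------------------------------------------

def free_dna_concentration(Ka: float, C_DNA, C_L):
    """Equilibrium free-duplex concentration for 1:1 binding.

    The unique non-negative root of
    ``Ka*d**2 + (1 + Ka*C_L - Ka*C_DNA)*d - C_DNA = 0``, evaluated in a
    numerically stable form.  At ``Ka = 0`` returns ``C_DNA``.
    """
    C_DNA = np.asarray(C_DNA, dtype=float)
    C_L = np.asarray(C_L, dtype=float)
    if not np.isfinite(Ka) or Ka < 0:
        raise DomainError(f"Ka must be finite and >= 0, got {Ka}")
    if np.any(C_DNA < 0) or np.any(C_L < 0):
        raise DomainError("concentrations must be >= 0")
    if Ka == 0.0:
        out = C_DNA + 0.0 * C_L
        return out if out.ndim else float(out)
    b = 1.0 + Ka * (C_L - C_DNA)
    disc = np.sqrt(b * b + 4.0 * Ka * C_DNA)
    # root via the stable branch: d = 2*C_DNA / (b + sqrt(...)) avoids
    # cancellation when b > 0; equals (-b + disc) / (2 Ka)
    out = 2.0 * C_DNA / (b + disc)
    return out if out.ndim else float(out)


def complex_concentration(Ka: float, C_DNA, C_L):
    """[DNA.L] = C_DNA - [DNA]_free; shared by titration and DOSY models."""
    return np.asarray(C_DNA, dtype=float) - free_dna_concentration(Ka, C_DNA, C_L)


def bound_ligand_fraction(Ka: float, C_DNA, C_L, dna_mode: DnaMode = "free_exact"):
    """Fraction of ligand bound, ``Ka*[DNA] / (1 + Ka*[DNA])``."""
    if dna_mode == "free_exact":
        d = free_dna_concentration(Ka, C_DNA, C_L)
    elif dna_mode == "total_approx":
        d = np.asarray(C_DNA, dtype=float)
    else:
        raise ValueError(f"unknown dna_mode {dna_mode!r}")
    return Ka * d / (1.0 + Ka * d)


def predict_titration_shift(Ka: float, C_DNA, C_L, delta_complex_shift: float,
                            dna_mode: DnaMode = "free_exact"):
    """Shift change ``ddelta = ddelta_complex * Ka*[DNA]/(1 + Ka*[DNA])``."""
    return delta_complex_shift * bound_ligand_fraction(Ka, C_DNA, C_L, dna_mode)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _predicted_observed(params, exp, label, dna_mode, baseline_model):
    """Observed-shift prediction at the experiment's titration points."""
    ka, dc = params["Ka"].value, params["delta_complex"].value
    fb = bound_ligand_fraction(ka, exp.C_DNA_mM, exp.C_L_mM, dna_mode)
    if baseline_model is None:
        return exp.delta_L(label) + fb * dc
    # Self-association correction: the free-ligand pool shrinks as ligand
    # is drawn into the complex, so its stacking-averaged shift drifts back
    # toward delta_mon.  delta_complex is then referenced to delta_mon.
    ka_s, dmon, dmax_s = baseline_model
    bound = fb * exp.C_L_mM
    free_pool = np.maximum(exp.C_L_mM - bound, 1e-12)
    delta_free = observed_dilution_shift(ka_s, free_pool, dmon, dmax_s)
    return (1.0 - fb) * delta_free + fb * (dmon + dc)


def _baseline_params(correction: SelfAssociationFit, label: str):
    for p in correction.per_proton:
        if p.proton_label == label:
            return p.Ka_mM_inv, p.delta_mon_ppm, p.delta_max_ppm
    raise ValueError(f"no self-association parameters for proton {label!r}")


def fit_binding_titration(
    exp: TitrationExperiment,
    dna_mode: DnaMode = "free_exact",
    *,
    noise_floor_ppm: float = 0.0,
    baseline_correction: SelfAssociationFit | None = None,
    seed: int = 0,
) -> BindingFit:
    """Per-proton nonlinear least squares for (Ka, ddelta_complex).

    Parameters
    ----------
    exp
        Titration with >= 4 points and a defined baseline per proton.
    dna_mode
        ``free_exact`` (equilibrium free duplex via the quadratic, default)
        or ``total_approx`` (total duplex in the isotherm).
    noise_floor_ppm
        Protons with fitted ``|ddelta_complex|`` under 3x this floor are
        flagged and excluded from the pooled mean.
    baseline_correction
        Optional isodesmic fit of the free ligand; when given, the free
        ligand's baseline shift is re-evaluated at each point from the
        monomer pool left after complexation (corrects the bias that
        self-associating protons show with a fixed baseline).
    """
    if exp.n_points < 4:
        raise ValueError(">= 4 titration points required")
    rng = np.random.default_rng(seed)
    per: list[ProtonBinding] = []
    for label, obs in exp.series.items():
        bl = (_baseline_params(baseline_correction, label)
              if baseline_correction is not None else None)

        def residual(params, _label=label, _obs=obs, _bl=bl):
            return _predicted_observed(params, exp, _label, dna_mode, _bl) - _obs

        swing = float(obs[-1] - obs[0])
        best = None
        for attempt in range(1 + N_RESTARTS):
            params = lmfit.Parameters()
            ka0 = KA_START if attempt == 0 else float(10.0 ** rng.uniform(-1.5, 1.5))
            dc0 = swing if swing != 0.0 else -1e-3
            if attempt:
                dc0 *= float(rng.uniform(0.3, 3.0))
            params.add("Ka", value=ka0, min=KA_BOUNDS[0], max=KA_BOUNDS[1])
            params.add("delta_complex", value=dc0)
            try:
                res = lmfit.minimize(residual, params, method="least_squares")
            except Exception:
                continue
            if res.success and (best is None or res.chisqr < best.chisqr):
                best = res
            if best is not None and attempt == 0:
                break
        if best is None:
            raise FitError(f"titration fit did not converge for proton {label!r}")
        ka = float(best.params["Ka"].value)
        sat = float(np.max(bound_ligand_fraction(
            ka, exp.C_DNA_mM, exp.C_L_mM, dna_mode)))
        if sat < MIN_SATURATION:
            warnings.warn(f"{label}: saturation reaches only {sat:.0%}; "
                          "Ka poorly constrained", stacklevel=2)
        per.append(ProtonBinding(
            proton_label=label, Ka_mM_inv=ka,
            delta_complex_ppm=float(best.params["delta_complex"].value),
            rss_ppm2=float(best.chisqr)))

    flagged = tuple(p.proton_label for p in per
                    if abs(p.delta_complex_ppm) < 3.0 * noise_floor_ppm)
    pooled = [p.Ka_mM_inv for p in per if p.proton_label not in flagged]
    if not pooled:
        raise FitError("every proton fell below the noise floor")
    return BindingFit(
        compound_id=exp.compound_id, duplex_id=exp.duplex_id,
        per_proton=tuple(per),
        Ka_mean_mM_inv=float(np.mean(pooled)),
        Ka_sd_mM_inv=float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0,
        dna_mode=dna_mode, excluded=flagged,
    )
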