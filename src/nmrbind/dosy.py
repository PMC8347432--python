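"""Binding constants from fast-exchange-averaged diffusion (DOSY).

Under fast exchange the observed diffusion coefficient of each species in
a ligand/duplex mixture is the mole-fraction-weighted average of its free
and complexed values:

    D_obs_L   = MF_L * D_L + (1 - MF_L) * D_complex
    D_obs_DNA = MF_DNA * D_DNA + (1 - MF_DNA) * D_complex

Because the duplex dwarfs the ligand hydrodynamically, the complex diffuses
like the duplex, and ``D_complex ~= D_obs_DNA`` closes the system: MF_L
falls out of a linear interpolation, the complex concentration follows from
the ligand mass balance, and

    Ka = [DNA.L] / ((C_DNA - [DNA.L]) * (C_L - [DNA.L]))

is a closed-form estimate — the exact inverse of the forward model here,
which is the module's internal consistency oracle.

The free-ligand reference ``D_L`` must be measured at a matched free-ligand
concentration: a self-associating ligand's diffusion is itself
concentration dependent, so the record carries it explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isodesmic import DomainError
from .titration import complex_concentration

__all__ = [
    "DiffusionRecord",
    "DosyBindingResult",
    "mole_fraction_free",
    "ka_from_diffusion",
    "predict_observed_diffusion",
    "monte_carlo_ka",
]

#: |MF_L| may stray outside [0, 1] by at most this before it is an error.
MF_CLIP_TOL = 0.02

#: Complex within this relative margin of a total concentration counts as
#: saturated (Ka unbounded).
SATURATION_TOL = 1e-9


@dataclass(frozen=True)
class DiffusionRecord:
    """One mixture's observed and reference diffusion coefficients.

    All D in m^2 s^-1; concentrations in mM (duplex counted as duplexes).
    ``D_L_free`` is the ligand-alone value at a matched concentration;
    ``D_DNA_free`` the duplex-alone value.
    """

    sample_id: str
    C_L_mM: float
    C_DNA_mM: float
    D_obs_L: float
    D_obs_DNA: float
    D_L_free: float
    D_DNA_free: float

    def __post_init__(self) -> None:
        for name in ("D_obs_L", "D_obs_DNA", "D_L_free", "D_DNA_free"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{self.sample_id}: {name} must be > 0")
        if self.C_L_mM < 0 or self.C_DNA_mM < 0:
            raise ValueError(f"{self.sample_id}: concentrations must be >= 0")
        if self.D_DNA_free >= self.D_L_free:
            raise ValueError(
                f"{self.sample_id}: duplex must diffuse slower than ligand "
                f"(D_DNA_free < D_L_free)")


@dataclass(frozen=True)
class DosyBindingResult:
    sample_id: str
    mf_L_free: float
    complex_mM: float
    Ka_mM_inv: float
    #: Records that D_complex was taken as the observed duplex diffusion.
    assumption_flag: str = "D_complex ~= D_obs_DNA"


def mole_fraction_free(D_obs_L: float, D_L_free: float, D_complex: float) -> float:
    """Free-ligand mole fraction by linear interpolation between references.

    ``MF_L = (D_obs_L - D_complex) / (D_L_free - D_complex)``.  Values
    outside [0, 1] by less than ``MF_CLIP_TOL`` are clipped with a warning;
    farther out is an error (inconsistent references).
    """
    denom = D_L_free - D_complex
    if denom == 0.0:
        raise DomainError("free and complexed diffusion indistinguishable")
    mf = (D_obs_L - D_complex) / denom
    if mf < -MF_CLIP_TOL or mf > 1.0 + MF_CLIP_TOL:
        raise DomainError(
            f"MF_L = {mf:.4f} outside [0, 1]: observed ligand diffusion is "
            "not bracketed by the free and complexed references")
    if mf < 0.0 or mf > 1.0:
        import warnings
        warnings.warn(f"MF_L = {mf:.4f} clipped into [0, 1]", stacklevel=2)
        mf = min(max(mf, 0.0), 1.0)
    return float(mf)


def ka_from_diffusion(rec: DiffusionRecord) -> DosyBindingResult:
    """Closed-form Ka from one diffusion record.

    Sets ``D_complex := D_obs_DNA``, interpolates ``MF_L``, forms
    ``[DNA.L] = (1 - MF_L) * C_L`` and evaluates the 1:1 mass-action
    quotient against both total concentrations.
    """
    if rec.C_L_mM <= 0 or rec.C_DNA_mM <= 0:
        raise DomainError(f"{rec.sample_id}: both totals must be > 0")
    mf = mole_fraction_free(rec.D_obs_L, rec.D_L_free, rec.D_obs_DNA)
    complex_mM = (1.0 - mf) * rec.C_L_mM
    free_dna = rec.C_DNA_mM - complex_mM
    free_lig = rec.C_L_mM - complex_mM
    if (free_dna <= SATURATION_TOL * rec.C_DNA_mM
            or free_lig <= SATURATION_TOL * rec.C_L_mM):
        raise DomainError(f"{rec.sample_id}: saturated — Ka unbounded")
    ka = complex_mM / (free_dna * free_lig)
    return DosyBindingResult(sample_id=rec.sample_id, mf_L_free=mf,
                             complex_mM=float(complex_mM), Ka_mM_inv=float(ka))


def predict_observed_diffusion(Ka: float, C_L: float, C_DNA: float,
                               D_L_free: float, D_DNA_free: float
                               ) -> tuple[float, float]:
    """Forward model: observed (D_obs_L, D_obs_DNA) for a given Ka.

    The complex concentration comes from the shared 1:1 quadratic; the
    complex is assumed to diffuse at the free-duplex rate, so the observed
    duplex diffusion equals ``D_DNA_free`` and the ligand diffusion
    interpolates with its free mole fraction.
    """
    if not np.isfinite(Ka) or Ka < 0:
        raise DomainError(f"Ka must be finite and >= 0, got {Ka}")
    if C_L <= 0 or C_DNA <= 0:
        raise DomainError("concentrations must be > 0")
    complex_mM = float(complex_concentration(Ka, C_DNA, C_L))
    mf_L = 1.0 - complex_mM / C_L
    D_complex = D_DNA_free
    d_obs_l = mf_L * D_L_free + (1.0 - mf_L) * D_complex
    mf_dna = 1.0 - complex_mM / C_DNA
    d_obs_dna = mf_dna * D_DNA_free + (1.0 - mf_dna) * D_complex
    return float(d_obs_l), float(d_obs_dna)


def monte_carlo_ka(rec: DiffusionRecord, sigma_rel: float, n: int = 1000,
                   seed: int = 0) -> np.ndarray:
    """Ka distribution under relative Gaussian perturbation of all D values.

    Draws that land outside the admissible MF_L band are discarded; the
    returned array holds the surviving Ka samples (median ~ true Ka for
    small sigma).
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        f = rng.normal(1.0, sigma_rel, size=4)
        try:
            pert = DiffusionRecord(
                sample_id=rec.sample_id, C_L_mM=rec.C_L_mM,
                C_DNA_mM=rec.C_DNA_mM,
                D_obs_L=rec.D_obs_L * f[0], D_obs_DNA=rec.D_obs_DNA * f[1],
                D_L_free=rec.D_L_free * f[2], D_DNA_free=rec.D_DNA_free * f[3])
            out.append(ka_from_diffusion(pert).Ka_mM_inv)
        except (DomainError, ValueError):
            continue
    return np.asarray(out)
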