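"""Basic isotherm figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

from .isodesmic import DilutionExperiment, SelfAssociationFit, observed_dilution_shift
from .titration import BindingFit, TitrationExperiment, bound_ligand_fraction


def plot_dilution_isotherms(exp: DilutionExperiment,
                            fit: SelfAssociationFit | None = None, ax=None):
    """Observed shifts vs log concentration, with fitted curves if given."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in exp.series:
        pts = ax.semilogx(s.concentrations_mM, s.shifts_ppm, "o",
                          label=s.proton_label)
        if fit is not None:
            p = next((q for q in fit.per_proton
                      if q.proton_label == s.proton_label), None)
            if p is not None:
                grid = np.geomspace(s.concentrations_mM[0],
                                    s.concentrations_mM[-1], 100)
                ax.semilogx(grid, observed_dilution_shift(
                    p.Ka_mM_inv, grid, p.delta_mon_ppm, p.delta_max_ppm),
                    "-", color=pts[0].get_color())
    ax.set_xlabel("total concentration (mM)")
    ax.set_ylabel("observed shift (ppm)")
    ax.legend(fontsize="small")
    return ax


def plot_titration_isotherms(exp: TitrationExperiment,
                             fit: BindingFit | None = None, ax=None):
    """Shift change vs duplex concentration per proton."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, shifts in exp.series.items():
        dd = shifts - exp.delta_L(label)
        pts = ax.plot(exp.C_DNA_mM, dd, "o", label=label)
        if fit is not None:
            p = next((q for q in fit.per_proton if q.proton_label == label),
                     None)
            if p is not None:
                grid = np.linspace(exp.C_DNA_mM[0], exp.C_DNA_mM[-1], 100)
                cl = np.full_like(grid, float(exp.C_L_mM[0]))
                fb = bound_ligand_fraction(p.Ka_mM_inv, grid, cl, fit.dna_mode)
                ax.plot(grid, p.delta_complex_ppm * fb, "-",
                        color=pts[0].get_color())
    ax.set_xlabel("total duplex (mM)")
    ax.set_ylabel("shift change (ppm)")
    ax.legend(fontsize="small")
    return ax
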