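"""CSV schemas, validated readers/writers, run manifests, and the
end-to-end study runner.

All tables are plain RFC-4180 CSV with a mandatory header, decimal point,
UTF-8.  Concentrations are always mM with the duplex counted as duplexes
(not strands); shifts in ppm; diffusion coefficients in m^2 s^-1; times in
days.  Write-then-read is an identity for every schema.

Schemas
-------
dilution   proton,conc_mM,shift_ppm
titration  proton,C_L_mM,C_DNA_mM,shift_ppm     (C_DNA=0 rows define delta_L)
dosy       sample_id,C_L_mM,C_DNA_mM,D_obs_L,D_obs_DNA,D_L_free,D_DNA_free
decay      time_days,intact_fraction
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dosy import DiffusionRecord, ka_from_diffusion
from .isodesmic import DilutionExperiment, ProtonShiftSeries, SelfAssociationFit, fit_isodesmic
from .kinetics import DecaySeries, KineticsResult, fit_decay
from .simulate import SimulationConfig, simulate_decay, simulate_dilution, simulate_dosy, simulate_titration
from .titration import BindingFit, TitrationExperiment, fit_binding_titration

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "write_fit_report",
    "RunManifest",
    "run_study",
]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


SCHEMAS = {
    "dilution": ["proton", "conc_mM", "shift_ppm"],
    "titration": ["proton", "C_L_mM", "C_DNA_mM", "shift_ppm"],
    "dosy": ["sample_id", "C_L_mM", "C_DNA_mM", "D_obs_L", "D_obs_DNA",
             "D_L_free", "D_DNA_free"],
    "decay": ["time_days", "intact_fraction"],
}


def _load_frame(path, schema_id: str) -> pd.DataFrame:
    if schema_id not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_id!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SCHEMAS[schema_id] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    numeric = [c for c in SCHEMAS[schema_id] if c not in ("proton", "sample_id")]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        if len(bad):
            raise SchemaError(
                f"{path.name}: non-numeric value in column {col!r}, "
                f"row {int(bad[0]) + 2}")  # +2: header + 1-based
        df[col] = converted
    return df


def read_table(path, schema_id: str):
    """Read and validate a CSV into the matching experiment object.

    Rows are normalized (sorted by concentration/time); duplicate keys are
    rejected; unit violations (negative concentrations, fractions outside
    [0, 1]) raise :class:`SchemaError` naming the offending row/column.
    """
    df = _load_frame(path, schema_id)
    name = Path(path).name
    try:
        if schema_id == "dilution":
            series = tuple(
                ProtonShiftSeries(str(label),
                                  grp["conc_mM"].to_numpy(),
                                  grp["shift_ppm"].to_numpy())
                for label, grp in df.groupby("proton", sort=True))
            return DilutionExperiment(compound_id=Path(path).stem, series=series)
        if schema_id == "titration":
            first = df[df["proton"] == df["proton"].iloc[0]]
            key = first.sort_values("C_DNA_mM")
            c_l = key["C_L_mM"].to_numpy()
            c_dna = key["C_DNA_mM"].to_numpy()
            series = {}
            for label, grp in df.groupby("proton", sort=True):
                grp = grp.sort_values("C_DNA_mM")
                if not (np.array_equal(grp["C_DNA_mM"].to_numpy(), c_dna)
                        and np.array_equal(grp["C_L_mM"].to_numpy(), c_l)):
                    raise SchemaError(
                        f"{name}: proton {label!r} not aligned with the "
                        "shared titration points")
                series[str(label)] = grp["shift_ppm"].to_numpy()
            return TitrationExperiment(
                compound_id=Path(path).stem, duplex_id="duplex",
                C_L_mM=c_l, C_DNA_mM=c_dna, series=series)
        if schema_id == "dosy":
            if df["sample_id"].duplicated().any():
                dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
                raise SchemaError(f"{name}: duplicate sample_id {dup!r}")
            return [DiffusionRecord(sample_id=str(r.sample_id),
                                    C_L_mM=r.C_L_mM, C_DNA_mM=r.C_DNA_mM,
                                    D_obs_L=r.D_obs_L, D_obs_DNA=r.D_obs_DNA,
                                    D_L_free=r.D_L_free, D_DNA_free=r.D_DNA_free)
                    for r in df.itertuples()]
        # decay
        df = df.sort_values("time_days")
        return DecaySeries(compound_id=Path(path).stem,
                           time_days=df["time_days"].to_numpy(),
                           intact_fraction=df["intact_fraction"].to_numpy())
    except SchemaError:
        raise
    except ValueError as exc:
        raise SchemaError(f"{name}: {exc}") from exc


def write_table(obj, path) -> None:
    """Write an experiment object back to its schema's CSV."""
    path = Path(path)
    if isinstance(obj, DilutionExperiment):
        rows = [{"proton": s.proton_label, "conc_mM": c, "shift_ppm": d}
                for s in obj.series
                for c, d in zip(s.concentrations_mM, s.shifts_ppm)]
    elif isinstance(obj, TitrationExperiment):
        rows = [{"proton": label, "C_L_mM": cl, "C_DNA_mM": cd, "shift_ppm": d}
                for label, shifts in obj.series.items()
                for cl, cd, d in zip(obj.C_L_mM, obj.C_DNA_mM, shifts)]
    elif isinstance(obj, DecaySeries):
        rows = [{"time_days": t, "intact_fraction": f}
                for t, f in zip(obj.time_days, obj.intact_fraction)]
    elif isinstance(obj, (list, tuple)) and all(
            isinstance(r, DiffusionRecord) for r in obj):
        rows = [asdict(r) for r in obj]
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    # %.17g survives the write-then-read round trip bit-exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_fit_report(fit, path) -> None:
    """Fit report CSV: per-proton/sample rows plus a pooled-summary row."""
    path = Path(path)
    if isinstance(fit, SelfAssociationFit):
        df = pd.DataFrame([{"proton": p.proton_label, "Ka_mM_inv": p.Ka_mM_inv,
                            "delta_mon_ppm": p.delta_mon_ppm,
                            "delta_max_ppm": p.delta_max_ppm,
                            "rss": p.rss_ppm2} for p in fit.per_proton])
        summary = (f"# Ka_mean = {fit.Ka_mean_mM_inv:.4f} +/- "
                   f"{fit.Ka_sd_mM_inv:.4f} mM^-1 (mode={fit.mode})")
    elif isinstance(fit, BindingFit):
        df = pd.DataFrame([{"proton": p.proton_label, "Ka_mM_inv": p.Ka_mM_inv,
                            "delta_complex_ppm": p.delta_complex_ppm,
                            "rss": p.rss_ppm2} for p in fit.per_proton])
        summary = (f"# Ka_mean = {fit.Ka_mean_mM_inv:.4f} +/- "
                   f"{fit.Ka_sd_mM_inv:.4f} mM^-1 (dna_mode={fit.dna_mode})")
    elif isinstance(fit, (list, tuple)):  # DOSY results
        df = pd.DataFrame([{"sample_id": r.sample_id, "mf_L_free": r.mf_L_free,
                            "complex_mM": r.complex_mM,
                            "Ka_mM_inv": r.Ka_mM_inv} for r in fit])
        summary = f"# Ka_mean = {df['Ka_mM_inv'].mean():.4f} mM^-1"
    elif isinstance(fit, KineticsResult):
        df = pd.DataFrame([{"k_per_day": fit.k_per_day,
                            "t_half_days": fit.t_half_days, "rss": fit.rss}])
        summary = f"# t_half = {fit.t_half_days:.2f} days (order={fit.order})"
    else:
        raise TypeError(f"cannot report {type(fit).__name__}")
    with open(path, "w", encoding="utf-8") as fh:
        df.to_csv(fh, index=False)
        fh.write(summary + "\n")


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted next to every fit/simulate output."""

    command: str
    input_paths: tuple[str, ...]
    config_digest: str
    seed: int | None
    package_version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, input_paths=(), config=None,
               seed: int | None = None) -> "RunManifest":
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(command=command,
                   input_paths=tuple(str(p) for p in input_paths),
                   config_digest=hashlib.sha256(blob).hexdigest()[:16],
                   seed=seed, package_version=__version__,
                   timestamp=datetime.now(timezone.utc).isoformat())

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n",
                              encoding="utf-8")


# ---------------------------------------------------------------------------
# Study runner
# ---------------------------------------------------------------------------

def run_study(config: dict, outdir, seed: int = 0) -> dict:
    """Run the configured analyses end to end and cross-check constants.

    ``config['analyses']`` maps analysis name (dilution / titration / dosy
    / decay) to either ``{"input": <csv path>}`` or ``{"synthetic":
    {...SimulationConfig fields...}}``.  Reports land in ``outdir``; the
    returned summary includes the titration-vs-diffusion Ka comparison and
    flags a discrepancy beyond twice the titration SD.
    """
    analyses = config.get("analyses")
    if not analyses:
        raise ValueError("empty study config: no analyses requested")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simulators = {"dilution": simulate_dilution, "titration": simulate_titration,
                  "dosy": simulate_dosy, "decay": simulate_decay}
    summary: dict = {"reports": {}}
    inputs = []
    for name, entry in analyses.items():
        if name not in simulators:
            raise ValueError(f"unknown analysis {name!r}")
        if "input" in entry:
            obj = read_table(entry["input"], name)
            inputs.append(entry["input"])
        elif "synthetic" in entry:
            syn = dict(entry["synthetic"])
            syn.setdefault("model", name)
            syn.setdefault("seed", seed)
            obj = simulators[name](SimulationConfig(**syn))
        else:
            raise ValueError(f"analysis {name!r} needs 'input' or 'synthetic'")
        if name == "dilution":
            fit = fit_isodesmic(obj, entry.get("mode", "per_proton_average"))
            summary["Ka_self_mM_inv"] = fit.Ka_mean_mM_inv
            summary["Ka_self_sd"] = fit.Ka_sd_mM_inv
        elif name == "titration":
            fit = fit_binding_titration(obj, entry.get("dna_mode", "free_exact"))
            summary["Ka_titration_mM_inv"] = fit.Ka_mean_mM_inv
            summary["Ka_titration_sd"] = fit.Ka_sd_mM_inv
        elif name == "dosy":
            fit = [ka_from_diffusion(r) for r in obj]
            summary["Ka_dosy_mM_inv"] = float(
                np.mean([r.Ka_mM_inv for r in fit]))
        else:
            fit = fit_decay(obj, entry.get("normalization", "fixed_1"))
            summary["t_half_days"] = fit.t_half_days
        report = outdir / f"{name}_report.csv"
        write_fit_report(fit, report)
        summary["reports"][name] = str(report)

    if "Ka_titration_mM_inv" in summary and "Ka_dosy_mM_inv" in summary:
        diff = abs(summary["Ka_titration_mM_inv"] - summary["Ka_dosy_mM_inv"])
        sd = summary.get("Ka_titration_sd") or 0.0
        summary["Ka_titration_vs_dosy_abs_diff"] = diff
        summary["methods_consistent"] = bool(diff <= 2.0 * sd) if sd else None
    RunManifest.create("study run", inputs, config, seed).write(
        outdir / "manifest.json")
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    return summary
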