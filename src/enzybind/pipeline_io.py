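"""File formats, run configuration, report assembly and orchestration.

CSV dialects (comma-separated, UTF-8, mandatory header, decimal point):

* plate CSV — long format, columns ``sample_id, inhibitor_conc_mg_ml,
  replicate, role, absorbance`` with role in {A, a, B, b};
* kinetics CSV — ``substrate_conc_mg_ml, enzyme_conc_mg_ml,
  inhibitor_conc_mg_ml, velocity_per_min``;
* spectra — one two-column CSV (``wavelength_nm, intensity``) per
  titration point plus a manifest CSV mapping files to
  ``(Q_mol_per_L, temperature_K)``;
* binding CSV — ``sample, T_K, Ka_L_per_mol`` with an optional reported
  ``dG_kJ_per_mol`` column that, when present, is cross-checked against
  ``-RT ln Ka``.

Column names carry explicit unit suffixes so mg/mL vs mol/L confusion
cannot be committed silently.

:func:`run_pipeline` chains inhibition -> kinetics -> quenching ->
thermodynamics over whichever inputs a :class:`RunConfig` provides,
skipping and flagging absent stages, and serialises a :class:`StudyReport`
whose JSON is byte-stable across reruns (floats rounded to a fixed number
of significant digits, keys sorted).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import inhibition, kinetics, quenching, thermodynamics
from .errors import EnzybindError
from .inhibition import PlateAssay
from .kinetics import VelocitySeries
from .quenching import TitrationSeries

log = logging.getLogger("enzybind")

_FLOAT_SIG_DIGITS = 9


# ---------------------------------------------------------------- readers

def read_plate_csv(path: str | Path) -> PlateAssay:
    """Read a long-format plate CSV and pivot the four roles into columns."""
    df = pd.read_csv(path)
    required = {"inhibitor_conc_mg_ml", "replicate", "role", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise EnzybindError(f"plate CSV missing columns: {sorted(missing)}")
    bad = set(df["role"]) - {"A", "a", "B", "b"}
    if bad:
        raise EnzybindError(f"plate CSV has unknown roles: {sorted(bad)}")
    wide = df.pivot_table(
        index=["inhibitor_conc_mg_ml", "replicate"],
        columns="role",
        values="absorbance",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    return PlateAssay(data=wide)


def write_plate_csv(assay: PlateAssay, path: str | Path, sample_id: str = "sample") -> None:
    rows = []
    for _, r in assay.data.iterrows():
        for role in ("A", "a", "B", "b"):
            rows.append(
                {
                    "sample_id": sample_id,
                    "inhibitor_conc_mg_ml": r["inhibitor_conc_mg_ml"],
                    "replicate": int(r["replicate"]),
                    "role": role,
                    "absorbance": r[role],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_kinetics_csv(path: str | Path) -> VelocitySeries:
    return VelocitySeries(data=pd.read_csv(path))


def write_kinetics_csv(vs: VelocitySeries, path: str | Path) -> None:
    vs.data.to_csv(path, index=False)


def write_titration_dir(
    series_by_T: dict[float, TitrationSeries], outdir: str | Path
) -> Path:
    """Write one spectrum CSV per titration point plus ``manifest.csv``;
    returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for T, series in sorted(series_by_T.items()):
        for i, q in enumerate(series.Q):
            fname = f"spectrum_T{T:g}K_{i:02d}.csv"
            pd.DataFrame(
                {"wavelength_nm": series.wavelengths, "intensity": series.intensities[i]}
            ).to_csv(outdir / fname, index=False)
            manifest.append(
                {
                    "file": fname,
                    "Q_mol_per_L": q,
                    "temperature_K": T,
                    "enzyme_molar_conc": series.enzyme_molar_conc,
                }
            )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(manifest).to_csv(manifest_path, index=False)
    return manifest_path


def read_titration_manifest(manifest_path: str | Path) -> dict[float, TitrationSeries]:
    """Assemble per-temperature titration series from a spectra manifest."""
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    required = {"file", "Q_mol_per_L", "temperature_K"}
    missing = required - set(man.columns)
    if missing:
        raise EnzybindError(f"manifest missing columns: {sorted(missing)}")
    out = {}
    for T, grp in man.groupby("temperature_K"):
        grp = grp.sort_values("Q_mol_per_L")
        wavelengths = None
        spectra = []
        for _, row in grp.iterrows():
            spec = pd.read_csv(manifest_path.parent / row["file"])
            wl = spec["wavelength_nm"].to_numpy(dtype=float)
            if wavelengths is None:
                wavelengths = wl
            elif not np.array_equal(wavelengths, wl):
                raise EnzybindError(f"wavelength grids differ within {T} K series")
            spectra.append(spec["intensity"].to_numpy(dtype=float))
        enz = (
            float(grp["enzyme_molar_conc"].iloc[0])
            if "enzyme_molar_conc" in grp.columns
            else float("nan")
        )
        out[float(T)] = TitrationSeries(
            temperature=float(T),
            Q=grp["Q_mol_per_L"].to_numpy(dtype=float),
            wavelengths=wavelengths,
            intensities=np.vstack(spectra),
            enzyme_molar_conc=enz,
        )
    return out


def read_binding_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "T_K", "Ka_L_per_mol"}
    missing = required - set(df.columns)
    if missing:
        raise EnzybindError(f"binding CSV missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------- config / report

class Tolerances(BaseModel):
    vmax_equality: float = 0.05  # relative, competitive-verdict Vmax constancy
    intercept_zero: float = 0.05  # relative, type-plot origin test
    dh_band_kj: float = thermodynamics.DEFAULT_DH_TOL
    ds_band: float = thermodynamics.DEFAULT_DS_TOL
    probit_clamp_pct: tuple[float, float] = (0.5, 99.5)
    gibbs_consistency_kj: float = 0.2


class RunConfig(BaseModel):
    plate_csv: Optional[str] = None
    kinetics_csv: Optional[str] = None
    type_plot_csv: Optional[str] = None
    spectra_manifest: Optional[str] = None
    binding_csv: Optional[str] = None
    tau0: float = quenching.DEFAULT_TAU0
    tolerances: Tolerances = Field(default_factory=Tolerances)
    seed: int = 0
    out_dir: Optional[str] = None

    def validate_paths(self) -> None:
        for name in (
            "plate_csv",
            "kinetics_csv",
            "type_plot_csv",
            "spectra_manifest",
            "binding_csv",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise EnzybindError(f"{name} does not exist: {p}")


class IC50Row(BaseModel):
    ic50_mg_ml: float
    ci95_low_mg_ml: float
    ci95_high_mg_ml: float
    probit_slope: float
    r2: float


class KineticRow(BaseModel):
    Vmax_per_min: float
    Km_mg_ml: float
    Ki_mg_ml: Optional[float] = None
    verdict: str
    reversibility: Optional[str] = None


class QuenchRow(BaseModel):
    temperature_K: float
    Ksv_L_per_mol: float
    Kq_L_per_mol_s: float
    Ka_L_per_mol: float
    n_sites: float
    mechanism: str
    peak_shift_nm: float


class ThermoRow(BaseModel):
    temperature_K: float
    dG_kJ_per_mol: float
    dH_kJ_per_mol: float
    dS_J_per_mol_K: float
    forces: str


class StudyReport(BaseModel):
    """Assembled study tables; every numeric field name carries its units
    and ``consistency_flags`` is always present, possibly empty."""

    ic50_table: Optional[IC50Row] = None
    kinetic_table: Optional[KineticRow] = None
    quench_table: list[QuenchRow] = Field(default_factory=list)
    thermo_table: list[ThermoRow] = Field(default_factory=list)
    consistency_flags: list[str] = Field(default_factory=list)


def study_report_schema() -> dict:
    """The published JSON schema every serialised report validates against."""
    return StudyReport.model_json_schema()


def _round_floats(obj):
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return None
        if obj == 0:
            return 0.0
        return float(f"{obj:.{_FLOAT_SIG_DIGITS}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v) for v in obj]
    return obj


def report_to_json(report: StudyReport) -> str:
    """Deterministic serialisation: fixed float precision, sorted keys."""
    return json.dumps(_round_floats(report.model_dump()), sort_keys=True, indent=2)


def report_to_text(report: StudyReport) -> str:
    lines = ["enzybind study report", "=" * 22]
    if report.ic50_table:
        t = report.ic50_table
        lines += [
            "",
            "Dose-response (probit)",
            f"  IC50 = {t.ic50_mg_ml:.3g} mg/mL "
            f"(95% CI {t.ci95_low_mg_ml:.3g}-{t.ci95_high_mg_ml:.3g}), "
            f"slope {t.probit_slope:.3g}, R2 {t.r2:.4f}",
        ]
    if report.kinetic_table:
        t = report.kinetic_table
        ki = f"{t.Ki_mg_ml:.3g}" if t.Ki_mg_ml is not None else "n/a"
        lines += [
            "",
            "Lineweaver-Burk kinetics",
            f"  Vmax = {t.Vmax_per_min:.3g} /min, Km = {t.Km_mg_ml:.3g} mg/mL, "
            f"Ki = {ki} mg/mL",
            f"  verdict: {t.verdict}"
            + (f", {t.reversibility}" if t.reversibility else ""),
        ]
    if report.quench_table:
        lines += ["", "Fluorescence quenching"]
        for r in report.quench_table:
            lines.append(
                f"  {r.temperature_K:g} K: Ksv = {r.Ksv_L_per_mol:.3g} L/mol, "
                f"Kq = {r.Kq_L_per_mol_s:.3g} L/(mol s), Ka = {r.Ka_L_per_mol:.3g} "
                f"L/mol, n = {r.n_sites:.3g}, shift {r.peak_shift_nm:+.2f} nm "
                f"[{r.mechanism}]"
            )
    if report.thermo_table:
        lines += ["", "Thermodynamics"]
        for r in report.thermo_table:
            lines.append(
                f"  {r.temperature_K:g} K: dG = {r.dG_kJ_per_mol:.2f} kJ/mol, "
                f"dH = {r.dH_kJ_per_mol:.2f} kJ/mol, dS = {r.dS_J_per_mol_K:.2f} "
                f"J/(mol K) [{r.forces}]"
            )
    lines += ["", f"flags ({len(report.consistency_flags)}):"]
    lines += [f"  - {f}" for f in report.consistency_flags]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------- pipeline

def run_pipeline(cfg: RunConfig) -> StudyReport:
    """Run every stage whose inputs are configured; skip and flag the rest.

    A stage whose preconditions fail aborts only itself; the failure is
    recorded in ``consistency_flags``. When spectra are analysed at two or
    more temperatures the fitted binding constants feed the thermodynamics
    stage directly; a binding CSV with a reported dG column additionally
    triggers the dG/Ka cross-check.
    """
    cfg.validate_paths()
    tol = cfg.tolerances
    report = StudyReport()
    log.info("run_pipeline seed=%d tolerances=%s", cfg.seed, tol.model_dump())

    if cfg.plate_csv:
        try:
            assay = read_plate_csv(cfg.plate_csv)
            dr = inhibition.aggregate_dose_response(assay)
            fit = inhibition.fit_ic50(dr, clamp_pct=tol.probit_clamp_pct)
            report.ic50_table = IC50Row(
                ic50_mg_ml=fit.ic50,
                ci95_low_mg_ml=fit.ci95[0],
                ci95_high_mg_ml=fit.ci95[1],
                probit_slope=fit.slope,
                r2=fit.r2,
            )
            report.consistency_flags += fit.warnings
            log.info("IC50 = %.4g mg/mL (R2 %.4f)", fit.ic50, fit.r2)
        except EnzybindError as e:
            report.consistency_flags.append(f"inhibition stage failed: {e}")
    else:
        report.consistency_flags.append("inhibition inputs missing: stage skipped")

    if cfg.kinetics_csv:
        try:
            vs = read_kinetics_csv(cfg.kinetics_csv)
            kfit = kinetics.lineweaver_burk(vs, vmax_tol=tol.vmax_equality)
            reversibility = None
            if cfg.type_plot_csv:
                tp = kinetics.fit_type_plot(read_kinetics_csv(cfg.type_plot_csv))
                reversibility = kinetics.classify_reversibility(
                    tp, tol=tol.intercept_zero
                )
            report.kinetic_table = KineticRow(
                Vmax_per_min=kfit.Vmax,
                Km_mg_ml=kfit.Km,
                Ki_mg_ml=None if math.isnan(kfit.Ki) else kfit.Ki,
                verdict=kfit.verdict,
                reversibility=reversibility,
            )
            report.consistency_flags += kfit.warnings
            log.info(
                "kinetics: Vmax %.4g /min, Km %.4g mg/mL, verdict %s",
                kfit.Vmax,
                kfit.Km,
                kfit.verdict,
            )
        except EnzybindError as e:
            report.consistency_flags.append(f"kinetics stage failed: {e}")
    else:
        report.consistency_flags.append("kinetics inputs missing: stage skipped")

    ka_by_t: dict[float, float] = {}
    if cfg.spectra_manifest:
        try:
            series_by_T = read_titration_manifest(cfg.spectra_manifest)
            fits = quenching.analyze_titrations(series_by_T, tau0=cfg.tau0)
            for T in sorted(fits):
                f = fits[T]
                report.quench_table.append(
                    QuenchRow(
                        temperature_K=T,
                        Ksv_L_per_mol=f.Ksv,
                        Kq_L_per_mol_s=f.Kq,
                        Ka_L_per_mol=f.Ka,
                        n_sites=f.n_sites,
                        mechanism=f.mechanism,
                        peak_shift_nm=f.peak_shift,
                    )
                )
                report.consistency_flags += f.warnings
                ka_by_t[T] = f.Ka
                log.info(
                    "quenching %g K: Ksv %.4g, Ka %.4g, n %.3g (%s)",
                    T,
                    f.Ksv,
                    f.Ka,
                    f.n_sites,
                    f.mechanism,
                )
        except EnzybindError as e:
            report.consistency_flags.append(f"quenching stage failed: {e}")
    else:
        report.consistency_flags.append("quenching inputs missing: stage skipped")

    if not ka_by_t and cfg.binding_csv:
        try:
            binding = read_binding_csv(cfg.binding_csv)
            ka_by_t = dict(
                zip(
                    binding["T_K"].astype(float),
                    binding["Ka_L_per_mol"].astype(float),
                )
            )
        except EnzybindError as e:
            report.consistency_flags.append(f"binding table unreadable: {e}")

    if len(ka_by_t) >= 2:
        try:
            temps = sorted(ka_by_t)[:2]
            inp = thermodynamics.ThermoInput(
                Ka1=ka_by_t[temps[0]], T1=temps[0], Ka2=ka_by_t[temps[1]], T2=temps[1]
            )
            res = thermodynamics.analyze(inp, tol.dh_band_kj, tol.ds_band)
            for T in temps:
                report.thermo_table.append(
                    ThermoRow(
                        temperature_K=T,
                        dG_kJ_per_mol=res.dG_by_T[T],
                        dH_kJ_per_mol=res.dH,
                        dS_J_per_mol_K=res.dS_by_T[T],
                        forces=res.forces,
                    )
                )
            log.info("thermodynamics: dH %.4g kJ/mol, forces %s", res.dH, res.forces)
        except EnzybindError as e:
            report.consistency_flags.append(f"thermodynamics stage failed: {e}")
    else:
        report.consistency_flags.append(
            "thermodynamics inputs missing: needs Ka at two temperatures"
        )

    if cfg.binding_csv:
        try:
            binding = read_binding_csv(cfg.binding_csv)
            if "dG_kJ_per_mol" in binding.columns:
                report.consistency_flags += thermodynamics.check_binding_consistency(
                    binding.to_dict("records"), tol.gibbs_consistency_kj
                )
        except EnzybindError as e:
            report.consistency_flags.append(f"binding table unreadable: {e}")

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report_to_json(report))
        (out / "report.txt").write_text(report_to_text(report))
    return report
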