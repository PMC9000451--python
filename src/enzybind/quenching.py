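"""Fluorescence-quenching analysis of protein–ligand titrations.

A titration series is a set of emission spectra of the protein (here a
lipase excited at 280 nm, emitting 300–400 nm from its tryptophans)
recorded at increasing quencher concentration [Q]. Each spectrum is
reduced to its peak intensity F and peak wavelength; the zero-quencher
spectrum supplies the reference intensity F0. Two linear models are then
fitted:

* Stern–Volmer: ``F0/F = 1 + Ksv*[Q]`` with the intercept fixed at 1;
  the bimolecular quenching rate constant is ``Kq = Ksv/tau0`` where tau0
  is the unquenched fluorophore lifetime (~1e-8 s for tryptophan).
* Double-log binding: ``lg((F0-F)/F) = lg(Ka) + n*lg([Q])`` giving the
  apparent binding constant Ka and number of binding sites n. Logs are
  base 10 throughout.

The quenching mechanism is classified from Kq and the temperature trend of
Ksv: static quenching (ground-state complex) requires Kq above the
diffusion-limited ceiling of 2e10 L/(mol.s) and Ksv decreasing with
temperature; dynamic (collisional) quenching shows the opposite pattern.
Conflicting diagnostics yield ``indeterminate`` rather than a guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EnzybindError, InsufficientDataError, NoPeakError

#: Diffusion-limited ceiling on the dynamic quenching rate constant, L/(mol.s).
KQ_DIFFUSION_LIMIT = 2.0e10

#: Default unquenched fluorophore lifetime, s.
DEFAULT_TAU0 = 1.0e-8


@dataclass
class TitrationSeries:
    """Emission spectra of one titration at a single temperature.

    Parameters
    ----------
    temperature : float
        Kelvin.
    Q : ndarray
        Quencher molar concentrations, mol/L; must contain 0 (the F0
        reference).
    wavelengths : ndarray
        Common wavelength grid in nm, shared by all spectra.
    intensities : ndarray, shape (len(Q), len(wavelengths))
        Non-negative emission intensities, arbitrary units.
    enzyme_molar_conc : float
        Protein concentration, mol/L (bookkeeping only).
    """

    temperature: float
    Q: np.ndarray
    wavelengths: np.ndarray
    intensities: np.ndarray
    enzyme_molar_conc: float = float("nan")

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.Q.size, self.wavelengths.size):
            raise EnzybindError("intensities must be (n_spectra, n_wavelengths)")
        if not np.any(self.Q == 0):
            raise EnzybindError("titration lacks the Q=0 reference spectrum (F0 undefined)")
        if np.any(self.intensities < 0):
            raise EnzybindError("negative emission intensities")


@dataclass
class QuenchFit:
    """Quenching observables and fitted constants at one temperature."""

    temperature: float
    Ksv: float  # L/mol
    Kq: float  # L/(mol.s), == Ksv/tau0 exactly
    tau0: float  # s
    Ka: float  # L/mol
    n_sites: float
    peak_shift: float  # nm, + = red shift
    r2_sv: float
    r2_loglog: float
    sv_free_intercept: float  # QC diagnostic; the primary fit pins it at 1
    mechanism: str = "indeterminate"
    warnings: list[str] = field(default_factory=list)


def peak_reduce(series: TitrationSeries) -> list[tuple[float, float, float]]:
    """Reduce each spectrum to ``(Q, F, peak_lambda)``.

    F is the maximum intensity; peak_lambda the wavelength at that maximum,
    with ties resolved toward the longer wavelength so a red shift is never
    under-reported. Raises :class:`NoPeakError` on a flat spectrum.
    """
    out = []
    for q, spec in zip(series.Q, series.intensities):
        if np.ptp(spec) == 0:
            raise NoPeakError(f"flat spectrum at Q={q:g} mol/L")
        # argmax of the reversed array picks the last (longest-wavelength) tie
        idx = spec.size - 1 - int(np.argmax(spec[::-1]))
        out.append((float(q), float(spec[idx]), float(series.wavelengths[idx])))
    return out


def stern_volmer_fit(
    points: list[tuple[float, float]],
    F0: float,
    tau0: float = DEFAULT_TAU0,
) -> tuple[float, float, dict]:
    """Fit ``F0/F = 1 + Ksv*[Q]`` and return ``(Ksv, Kq, diagnostics)``.

    The primary fit constrains the intercept to 1 (the model has no free
    intercept); ``Ksv`` is the least-squares slope
    ``sum(Q*(F0/F - 1)) / sum(Q^2)`` over the nonzero-Q points and
    ``Kq = Ksv/tau0`` exactly. Diagnostics carry an unconstrained
    free-intercept fit and the R^2 of the constrained line; a negative
    slope is flagged as non-quenching.
    """
    pts = [(q, f) for q, f in points if q > 0]
    if len(pts) < 3:
        raise InsufficientDataError("Stern-Volmer fit needs >= 3 nonzero-Q points")
    q = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    if np.any(f <= 0) or F0 <= 0:
        raise EnzybindError("fluorescence intensities must be positive")
    y = F0 / f
    ksv = float(np.sum(q * (y - 1.0)) / np.sum(q * q))
    resid = y - (1.0 + ksv * q)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    slope_free, intercept_free = np.polyfit(q, y, 1)
    diagnostics = {
        "r2": r2,
        "free_slope": float(slope_free),
        "free_intercept": float(intercept_free),
        "warnings": [],
    }
    if ksv < 0:
        diagnostics["warnings"].append("negative Stern-Volmer slope: no quenching detected")
    return ksv, ksv / tau0, diagnostics


def double_log_fit(
    points: list[tuple[float, float]],
    F0: float,
) -> tuple[float, float, dict]:
    """Fit ``lg((F0-F)/F) = lg(Ka) + n*lg(Q)``; return ``(Ka, n, diagnostics)``.

    Points with ``F >= F0`` (no net quenching) are excluded with a warning;
    fewer than 3 usable points raises :class:`InsufficientDataError`.
    """
    warnings = []
    usable = []
    for q, f in points:
        if q <= 0:
            continue
        if f >= F0:
            warnings.append(f"point Q={q:g} excluded from double-log fit (F >= F0)")
            continue
        if f <= 0:
            warnings.append(f"point Q={q:g} excluded from double-log fit (F <= 0)")
            continue
        usable.append((q, f))
    if len(usable) < 3:
        raise InsufficientDataError("double-log fit needs >= 3 points with 0 < F < F0")
    q = np.array([p[0] for p in usable])
    f = np.array([p[1] for p in usable])
    x = np.log10(q)
    y = np.log10((F0 - f) / f)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return 10.0 ** float(intercept), float(slope), {"r2": r2, "warnings": warnings}


def fit_titration(series: TitrationSeries, tau0: float = DEFAULT_TAU0) -> QuenchFit:
    """Reduce one titration to a :class:`QuenchFit` (mechanism unset).

    Runs peak reduction, the Stern–Volmer fit and the double-log binding
    fit; the mechanism label requires the between-temperature comparison in
    :func:`classify_mechanism`.
    """
    reduced = peak_reduce(series)
    zero = [r for r in reduced if r[0] == 0]
    F0 = zero[0][1]
    lambda0 = zero[0][2]
    qmax = max(r[0] for r in reduced)
    lambda_max = [r[2] for r in reduced if r[0] == qmax][0]
    points = [(q, f) for q, f, _ in reduced]
    ksv, kq, sv_diag = stern_volmer_fit(points, F0, tau0)
    ka, n, ll_diag = double_log_fit(points, F0)
    return QuenchFit(
        temperature=series.temperature,
        Ksv=ksv,
        Kq=kq,
        tau0=tau0,
        Ka=ka,
        n_sites=n,
        peak_shift=lambda_max - lambda0,
        r2_sv=sv_diag["r2"],
        r2_loglog=ll_diag["r2"],
        sv_free_intercept=sv_diag["free_intercept"],
        warnings=sv_diag["warnings"] + ll_diag["warnings"],
    )


def classify_mechanism(fits_by_T: dict[float, QuenchFit]) -> str:
    """Label the quenching mechanism: ``static``, ``dynamic`` or ``indeterminate``.

    Static requires Kq above the diffusion limit at every temperature and,
    when two or more temperatures are available, Ksv strictly decreasing
    with temperature (complex formation is disfavoured by heat). Dynamic
    requires Kq at or below the limit and Ksv increasing (faster diffusion
    when warm). Any other combination — including a negative-slope
    non-quenching fit — is indeterminate. The map is total: every input
    yields exactly one label.
    """
    if not fits_by_T:
        raise InsufficientDataError("mechanism classification needs >= 1 temperature")
    temps = sorted(fits_by_T)
    fits = [fits_by_T[t] for t in temps]
    if any(f.Ksv <= 0 for f in fits):
        return "indeterminate"
    kq_above = all(f.Kq > KQ_DIFFUSION_LIMIT for f in fits)
    kq_below = all(f.Kq <= KQ_DIFFUSION_LIMIT for f in fits)
    ksv = [f.Ksv for f in fits]
    decreasing = all(b < a for a, b in zip(ksv, ksv[1:]))
    increasing = all(b > a for a, b in zip(ksv, ksv[1:]))
    if kq_above and (len(fits) < 2 or decreasing):
        return "static"
    if kq_below and (len(fits) < 2 or increasing):
        return "dynamic"
    return "indeterminate"


def analyze_titrations(
    series_by_T: dict[float, TitrationSeries],
    tau0: float = DEFAULT_TAU0,
) -> dict[float, QuenchFit]:
    """Fit every temperature and stamp the shared mechanism label on each fit."""
    fits = {T: fit_titration(s, tau0) for T, s in series_by_T.items()}
    mechanism = classify_mechanism(fits)
    for f in fits.values():
        f.mechanism = mechanism
    return fits
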