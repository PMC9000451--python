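"""Synthetic assay-data generators with known ground truth.

Every input the analysis stages consume can be generated here under a
stated forward model, so the whole pipeline is testable without deposited
instrument data:

* **Plate assay** (endpoint absorbances): the designed inhibition fraction
  at dose I follows a probit curve in log10 concentration centred at the
  true IC50; the four well roles (control blank A, uninhibited reaction a,
  no-enzyme blank B, sample reaction b) are laid out so that the
  blank-corrected rate formula recovers that fraction exactly at zero
  noise.
* **Velocity series** (Michaelis–Menten kinetics): competitive inhibition
  ``V = Vmax*[S] / (Km*(1 + [I]/Ki) + [S])`` by default, with
  noncompetitive and uncompetitive variants for exercising the
  complementary verdict branches.
* **Enzyme sweep** (type plot): V proportional to enzyme concentration,
  slope reduced by the dose factor 1/(1 + [I]/Ki) for a reversible
  inhibitor, or intercept shifted for the irreversible pattern.
* **Titration spectra**: a Gaussian tryptophan-like emission band whose
  peak intensity obeys the static single-site binding law
  ``(F0 - F)/F = Ka*[Q]**n`` (the Stern–Volmer law when n = 1) and whose
  centre red-shifts linearly with the quencher:protein molar ratio.

Noise is multiplicative Gaussian with relative SD ``noise_sd``, truncated
at zero — plate readers and fluorometers have signal-proportional error
and negative signals are unphysical. Identical (design, truth) with the
same seed give bit-identical outputs.

Default design grids copy a published lipase-inhibition study layout
(inhibitor 0–4.0 mg/mL, substrate 0.4–1.6 mg/mL, lipase 5–20 mg/mL,
quencher:enzyme ratios 0–20:1 at 5e-6 mol/L enzyme, 293 and 303 K,
triplicate wells); default truth parameters sit at the magnitudes such a
study reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidDesignError
from .inhibition import PlateAssay
from .kinetics import VelocitySeries
from .quenching import TitrationSeries


def _check_grid(name: str, values: tuple[float, ...], allow_leading_zero: bool) -> None:
    vals = list(values)
    if not vals:
        raise InvalidDesignError(f"{name} is empty")
    if allow_leading_zero and vals[0] == 0:
        vals = vals[1:]
    if any(v <= 0 for v in vals):
        raise InvalidDesignError(f"{name} must be strictly positive (leading 0 allowed)")
    if any(b <= a for a, b in zip(values, values[1:])):
        raise InvalidDesignError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class AssayDesign:
    """Experimental layout shared by all generators.

    Concentrations in mg/mL except ``enzyme_molar_conc`` (mol/L);
    ``molar_ratios`` are dimensionless quencher:enzyme ratios;
    temperatures in K; ``noise_sd`` is the relative SD of the
    multiplicative Gaussian noise.
    """

    inhibitor_concs: tuple[float, ...] = (0.0, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0, 4.0)
    substrate_concs: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6)
    enzyme_concs: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    molar_ratios: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 5.0, 10.0, 20.0)
    enzyme_molar_conc: float = 5.0e-6
    temperatures: tuple[float, ...] = (293.0, 303.0)
    replicates: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_grid("inhibitor_concs", self.inhibitor_concs, allow_leading_zero=True)
        _check_grid("substrate_concs", self.substrate_concs, allow_leading_zero=False)
        _check_grid("enzyme_concs", self.enzyme_concs, allow_leading_zero=False)
        _check_grid("molar_ratios", self.molar_ratios, allow_leading_zero=True)
        if self.enzyme_molar_conc <= 0:
            raise InvalidDesignError("enzyme_molar_conc must be positive")
        if self.replicates < 1:
            raise InvalidDesignError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be >= 0")


def _default_ksv() -> dict[float, float]:
    return {293.0: 6.03e4, 303.0: 4.19e4}


@dataclass(frozen=True)
class GroundTruth:
    """True parameter values the generators encode and the fits must recover.

    ``Ka_by_T`` defaults to ``Ksv_by_T`` because with one binding site
    (``n_sites = 1``) the double-log binding law coincides with the
    Stern–Volmer law and the two constants are the same number.
    """

    Km: float = 0.25  # mg/mL
    Vmax: float = 5.46  # 1/min
    Ki: float = 0.88  # mg/mL
    IC50: float = 1.80  # mg/mL
    probit_slope: float = 2.0  # probit units per log10 decade
    Ksv_by_T: dict[float, float] = field(default_factory=_default_ksv)
    Ka_by_T: dict[float, float] | None = None
    n_sites: float = 1.0
    tau0: float = 1.0e-8  # s
    peak_lambda: float = 340.0  # nm
    red_shift_per_ratio: float = 0.1  # nm per unit molar ratio

    def __post_init__(self) -> None:
        for name in ("Km", "Vmax", "Ki", "IC50", "probit_slope", "tau0", "n_sites"):
            if getattr(self, name) <= 0:
                raise InvalidDesignError(f"GroundTruth.{name} must be positive")
        if any(v <= 0 for v in self.Ksv_by_T.values()):
            raise InvalidDesignError("Ksv values must be positive")

    def binding_constants(self) -> dict[float, float]:
        ka = self.Ka_by_T if self.Ka_by_T is not None else self.Ksv_by_T
        if any(v <= 0 for v in ka.values()):
            raise InvalidDesignError("Ka values must be positive")
        return ka


def _noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """Multiplicative factors ~ N(1, sd), truncated at 0."""
    if sd == 0:
        return np.ones(shape)
    return np.maximum(rng.normal(1.0, sd, size=shape), 0.0)


def competitive_velocity(S, I, Km: float, Vmax: float, Ki: float):
    """Michaelis–Menten rate under competitive inhibition:
    ``Vmax*S / (Km*(1 + I/Ki) + S)``."""
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    v = Vmax * S / (Km * (1.0 + I / Ki) + S)
    return float(v) if v.ndim == 0 else v


def probit_inhibition_fraction(I, IC50: float, slope: float):
    """Designed inhibition fraction at dose I: ``Phi(slope*log10(I/IC50))``,
    0 at I = 0."""
    I = np.asarray(I, dtype=float)
    frac = np.zeros_like(I, dtype=float)
    pos = I > 0
    frac[pos] = stats.norm.cdf(slope * (np.log10(I[pos]) - np.log10(IC50)))
    return float(frac) if frac.ndim == 0 else frac


# plate layout constants: blank level, uninhibited signal span, and the
# per-dose background the inhibitor itself contributes at 405 nm
_BLANK_ABS = 0.05
_SIGNAL_ABS = 0.80
_SAMPLE_BG_PER_DOSE = 0.02


def generate_plate_assay(design: AssayDesign, truth: GroundTruth) -> PlateAssay:
    """Endpoint plate absorbances whose noiseless blank-corrected rates equal
    the designed probit inhibition fraction exactly.

    Per (dose, replicate) the four roles are: ``A`` the control blank,
    ``a = A + signal``, ``B`` a dose-proportional sample blank, and
    ``b = B + signal*(1 - fraction)``. Noise multiplies each absorbance
    independently.
    """
    rng = np.random.default_rng(design.seed)
    doses = np.asarray(design.inhibitor_concs, dtype=float)
    frac = probit_inhibition_fraction(doses, truth.IC50, truth.probit_slope)
    rows = []
    for dose, f in zip(doses, frac):
        for rep in range(design.replicates):
            A = _BLANK_ABS
            a = A + _SIGNAL_ABS
            B = _BLANK_ABS + _SAMPLE_BG_PER_DOSE * dose
            b = B + _SIGNAL_ABS * (1.0 - f)
            noisy = np.array([A, a, B, b]) * _noise(rng, 4, design.noise_sd)
            rows.append(
                {
                    "inhibitor_conc_mg_ml": dose,
                    "replicate": rep,
                    "A": noisy[0],
                    "a": noisy[1],
                    "B": noisy[2],
                    "b": noisy[3],
                }
            )
    return PlateAssay(data=pd.DataFrame(rows))


def generate_velocity_series(
    design: AssayDesign,
    truth: GroundTruth,
    mechanism: str = "competitive",
    enzyme_conc: float | None = None,
) -> VelocitySeries:
    """Velocities over the substrate grid at every inhibitor dose.

    ``mechanism`` selects the inhibition law encoded in the data:
    competitive (Km_app scales by 1 + I/Ki, Vmax fixed), noncompetitive
    (Vmax divided by 1 + I/Ki, Km fixed) or uncompetitive (both divided by
    1 + I/Ki, reciprocal lines parallel). Enzyme concentration is fixed
    (defaults to the lowest design level) as in a standard kinetic run.
    """
    if mechanism not in ("competitive", "noncompetitive", "uncompetitive"):
        raise InvalidDesignError(f"unknown inhibition mechanism '{mechanism}'")
    rng = np.random.default_rng(design.seed + 1)
    E = design.enzyme_concs[0] if enzyme_conc is None else enzyme_conc
    if E <= 0:
        raise InvalidDesignError("enzyme concentration must be positive")
    rows = []
    for dose in design.inhibitor_concs:
        factor = 1.0 + dose / truth.Ki
        for S in design.substrate_concs:
            if S <= 0:
                raise InvalidDesignError("substrate concentration must be positive")
            if mechanism == "competitive":
                v = truth.Vmax * S / (truth.Km * factor + S)
            elif mechanism == "noncompetitive":
                v = (truth.Vmax / factor) * S / (truth.Km + S)
            else:  # uncompetitive
                v = (truth.Vmax / factor) * S / (truth.Km / factor + S)
            rows.append(
                {
                    "substrate_conc_mg_ml": S,
                    "enzyme_conc_mg_ml": E,
                    "inhibitor_conc_mg_ml": dose,
                    "velocity_per_min": v * float(_noise(rng, (), design.noise_sd)),
                }
            )
    return VelocitySeries(data=pd.DataFrame(rows))


def generate_enzyme_sweep(
    design: AssayDesign,
    truth: GroundTruth,
    substrate_conc: float | None = None,
    reversible: bool = True,
) -> VelocitySeries:
    """Velocity against enzyme concentration at fixed substrate (type plot).

    Reversible inhibition reduces the slope by 1/(1 + I/Ki), with lines
    through the origin; the irreversible pattern keeps the uninhibited
    slope but titrates away a dose-proportional amount of enzyme, shifting
    intercepts negative (clipped at zero velocity).
    """
    rng = np.random.default_rng(design.seed + 2)
    S = design.substrate_concs[-1] if substrate_conc is None else substrate_conc
    sat = S / (truth.Km + S)
    rate_per_enzyme = truth.Vmax * sat / design.enzyme_concs[-1]
    rows = []
    for dose in design.inhibitor_concs:
        factor = 1.0 + dose / truth.Ki
        for E in design.enzyme_concs:
            if reversible:
                v = rate_per_enzyme * E / factor
            else:
                dead = 2.0 * dose  # mg/mL of enzyme irreversibly inactivated
                v = max(rate_per_enzyme * (E - dead), 0.0)
            rows.append(
                {
                    "substrate_conc_mg_ml": S,
                    "enzyme_conc_mg_ml": E,
                    "inhibitor_conc_mg_ml": dose,
                    "velocity_per_min": v * float(_noise(rng, (), design.noise_sd)),
                }
            )
    return VelocitySeries(data=pd.DataFrame(rows))


# emission-spectrum shape constants
_WL_START, _WL_STOP, _WL_STEP = 300.0, 400.0, 0.05
_PEAK_SIGMA = 25.0  # nm
_F0_AMPLITUDE = 1000.0  # arbitrary units


def generate_titration(
    design: AssayDesign, truth: GroundTruth
) -> dict[float, TitrationSeries]:
    """Emission titration spectra per temperature.

    Quencher molar concentration is ``ratio * enzyme_molar_conc``. The
    noiseless peak intensity follows ``F = F0 / (1 + Ka*[Q]**n)`` with the
    temperature's binding constant, which reduces to the Stern–Volmer law
    for ``n_sites = 1``; peak centres are red-shifted by
    ``red_shift_per_ratio`` per unit ratio and snapped to the wavelength
    grid so the sampled maximum equals the model intensity exactly.
    """
    if 0.0 not in design.molar_ratios:
        raise InvalidDesignError("molar_ratios must include 0 (the F0 reference)")
    rng = np.random.default_rng(design.seed + 3)
    wl = np.arange(_WL_START, _WL_STOP + _WL_STEP / 2, _WL_STEP)
    ka_by_t = truth.binding_constants()
    out = {}
    for T in design.temperatures:
        if T not in ka_by_t:
            raise InvalidDesignError(f"no binding constant for temperature {T} K")
        ka = ka_by_t[T]
        ratios = np.asarray(design.molar_ratios, dtype=float)
        Q = ratios * design.enzyme_molar_conc
        spectra = np.empty((Q.size, wl.size))
        for i, (ratio, q) in enumerate(zip(ratios, Q)):
            F = _F0_AMPLITUDE / (1.0 + ka * q**truth.n_sites) if q > 0 else _F0_AMPLITUDE
            center = truth.peak_lambda + truth.red_shift_per_ratio * ratio
            center = _WL_START + round((center - _WL_START) / _WL_STEP) * _WL_STEP
            clean = F * np.exp(-((wl - center) ** 2) / (2.0 * _PEAK_SIGMA**2))
            spectra[i] = clean * _noise(rng, wl.size, design.noise_sd)
        out[T] = TitrationSeries(
            temperature=T,
            Q=Q,
            wavelengths=wl,
            intensities=spectra,
            enzyme_molar_conc=design.enzyme_molar_conc,
        )
    return out
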