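"""Binding thermodynamics from equilibrium constants at two temperatures.

Given apparent binding constants :math:`K_a` measured at two temperatures,
this module computes

* the Gibbs free energy of binding, :math:`\\Delta G = -RT \\ln K`,
* the van't Hoff enthalpy,
  :math:`\\Delta H = R \\ln(K_{a2}/K_{a1}) / (1/T_1 - 1/T_2)`
  (assumed temperature-independent over the narrow interval),
* the entropy change, :math:`\\Delta S = (\\Delta H - \\Delta G)/T`,

and classifies the dominant intermolecular forces from the sign pattern of
(:math:`\\Delta H`, :math:`\\Delta S`) using the Ross–Subramanian rubric:
both negative -> hydrogen bonds + van der Waals; both positive ->
hydrophobic; :math:`\\Delta H \\approx 0` with :math:`\\Delta S > 0` ->
electrostatic.

Unit policy: all energies are computed in J internally and reported in
kJ/mol (dG, dH) and J/(mol.K) (dS); the single kJ<->J conversion lives in
this module to prevent 1000x slips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import EnzybindError

#: Gas constant, J/(mol.K).
R = 8.314

#: Default near-zero band for the enthalpy sign test, kJ/mol.
DEFAULT_DH_TOL = 1.0
#: Default near-zero band for the entropy sign test, J/(mol.K).
DEFAULT_DS_TOL = 5.0


@dataclass(frozen=True)
class ThermoInput:
    """Binding constants at two temperatures.

    Parameters
    ----------
    Ka1, Ka2 : float
        Apparent binding constants (L/mol) at ``T1`` and ``T2``.
    T1, T2 : float
        Absolute temperatures in K; must differ.
    """

    Ka1: float
    T1: float
    Ka2: float
    T2: float

    def __post_init__(self) -> None:
        if self.Ka1 <= 0 or self.Ka2 <= 0:
            raise EnzybindError("binding constants must be strictly positive")
        if self.T1 <= 0 or self.T2 <= 0:
            raise EnzybindError("temperatures must be positive (K)")
        if self.T1 == self.T2:
            raise EnzybindError("van't Hoff analysis needs two distinct temperatures")


@dataclass
class ThermoResult:
    """Thermodynamic profile at the two input temperatures.

    ``dS_by_T[T] == (dH - dG_by_T[T]) / T * 1000`` holds exactly by
    construction.
    """

    dG_by_T: dict[float, float]  # kJ/mol
    dH: float  # kJ/mol
    dS_by_T: dict[float, float]  # J/(mol.K)
    forces: str  # hbond_vdw | hydrophobic | electrostatic | indeterminate
    spontaneous: bool
    flags: list[str] = field(default_factory=list)


def gibbs(K: float, T: float) -> float:
    """Gibbs free energy of binding, kJ/mol: ``-R*T*ln(K) / 1000``.

    Raises a domain error for ``K <= 0`` or ``T <= 0``.
    """
    if K <= 0:
        raise EnzybindError(f"binding constant must be > 0, got {K}")
    if T <= 0:
        raise EnzybindError(f"temperature must be > 0 K, got {T}")
    return -R * T * math.log(K) / 1000.0


def vant_hoff_enthalpy(inp: ThermoInput) -> float:
    """Van't Hoff enthalpy, kJ/mol, from the two-point slope of ln K vs 1/T.

    Antisymmetric under swapping the two (Ka, T) pairs, zero when
    ``Ka1 == Ka2``.
    """
    num = math.log(inp.Ka2 / inp.Ka1)
    den = 1.0 / inp.T1 - 1.0 / inp.T2
    return R * num / den / 1000.0


def entropy(dH: float, dG: float, T: float) -> float:
    """Entropy change, J/(mol.K): ``(dH - dG) * 1000 / T`` with dH, dG in kJ/mol."""
    if T <= 0:
        raise EnzybindError(f"temperature must be > 0 K, got {T}")
    return (dH - dG) * 1000.0 / T


def classify_forces(
    dH: float,
    dS: float,
    dh_tol: float = DEFAULT_DH_TOL,
    ds_tol: float = DEFAULT_DS_TOL,
) -> str:
    """Dominant-intermolecular-force label from the (dH, dS) sign pattern.

    Parameters
    ----------
    dH : float
        Enthalpy change, kJ/mol.
    dS : float
        Entropy change, J/(mol.K).
    dh_tol, ds_tol : float
        Half-widths of the "approximately zero" bands for dH (kJ/mol) and
        dS (J/(mol.K)); the electrostatic branch requires ``|dH| <= dh_tol``.

    Returns
    -------
    str
        ``hbond_vdw`` (dH < 0 and dS < 0), ``hydrophobic`` (dH > 0 and
        dS > 0), ``electrostatic`` (dH ~ 0 and dS > 0), else
        ``indeterminate``.
    """
    if dH < -dh_tol and dS < -ds_tol:
        return "hbond_vdw"
    if dH > dh_tol and dS > ds_tol:
        return "hydrophobic"
    if abs(dH) <= dh_tol and dS > ds_tol:
        return "electrostatic"
    return "indeterminate"


def analyze(
    inp: ThermoInput,
    dh_tol: float = DEFAULT_DH_TOL,
    ds_tol: float = DEFAULT_DS_TOL,
) -> ThermoResult:
    """Full two-temperature thermodynamic profile.

    Computes dG at each temperature, the van't Hoff dH, dS at each
    temperature from the Gibbs-Helmholtz identity, the force label (from
    the mean dS) and the spontaneity verdict (dG < 0 at every T).
    """
    dH = vant_hoff_enthalpy(inp)
    dG_by_T = {inp.T1: gibbs(inp.Ka1, inp.T1), inp.T2: gibbs(inp.Ka2, inp.T2)}
    dS_by_T = {T: entropy(dH, dG, T) for T, dG in dG_by_T.items()}
    mean_dS = sum(dS_by_T.values()) / len(dS_by_T)
    return ThermoResult(
        dG_by_T=dG_by_T,
        dH=dH,
        dS_by_T=dS_by_T,
        forces=classify_forces(dH, mean_dS, dh_tol, ds_tol),
        spontaneous=all(dG < 0 for dG in dG_by_T.values()),
    )


def check_binding_consistency(
    entries: list[dict],
    tol_kj: float = 0.2,
) -> list[str]:
    """Cross-check reported dG values against dG recomputed from Ka.

    Each entry is ``{"sample": str, "T_K": float, "Ka_L_per_mol": float,
    "dG_kJ_per_mol": float}``. A flag string is emitted for every row whose
    reported dG differs from ``-RT ln Ka`` by more than ``tol_kj`` kJ/mol
    (wide enough to absorb rounding of a Ka printed to 3 significant
    figures, narrow enough to catch mislabelled rows).
    """
    flags: list[str] = []
    for e in entries:
        recomputed = gibbs(e["Ka_L_per_mol"], e["T_K"])
        reported = e["dG_kJ_per_mol"]
        if abs(recomputed - reported) > tol_kj:
            flags.append(
                f"dG/Ka mismatch for sample '{e['sample']}' at {e['T_K']} K: "
                f"reported dG = {reported:.2f} kJ/mol but Ka = "
                f"{e['Ka_L_per_mol']:.4g} L/mol implies dG = {recomputed:.2f} kJ/mol"
            )
    return flags
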