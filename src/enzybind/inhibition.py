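"""Inhibition rates from endpoint plate absorbances and probit IC50 fitting.

The endpoint assay reads the chromogenic product (p-nitrophenol, 405 nm) of
the enzymatic reaction in a microplate. Four absorbances enter the
blank-corrected inhibition rate:

    rate (%) = [1 - (b - B) / (a - A)] * 100

where ``A`` is the control blank, ``a`` the uninhibited reaction, ``B`` the
no-enzyme blank of the sample and ``b`` the inhibited sample reaction.
Replicate rates are aggregated per dose, and the IC50 is estimated by
probit regression: a linear least-squares fit of the inverse standard
normal transform of the mean inhibition fraction on log10 concentration.
The IC50 is the concentration at which the fitted probit crosses zero,
i.e. 50% inhibition; its confidence interval comes from the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateControlError, InsufficientDataError


@dataclass
class PlateAssay:
    """Replicate-indexed plate absorbances, one row per (dose, replicate).

    ``data`` columns: ``inhibitor_conc_mg_ml``, ``replicate``, and the four
    absorbance roles ``A`` (control blank), ``a`` (uninhibited reaction),
    ``B`` (no-enzyme blank), ``b`` (sample reaction).
    """

    data: pd.DataFrame

    REQUIRED = ("inhibitor_conc_mg_ml", "replicate", "A", "a", "B", "b")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"PlateAssay missing columns: {missing}")


@dataclass
class DoseResponse:
    """Per-dose summary: columns ``conc_mg_ml``, ``mean_inhibition_pct``,
    ``sd_pct``, ``n_rep``; concentrations strictly increasing."""

    points: pd.DataFrame


@dataclass
class IC50Fit:
    ic50: float  # mg/mL
    slope: float  # probit units per log10(mg/mL)
    intercept: float
    ci95: tuple[float, float]  # mg/mL
    r2: float
    warnings: list[str] = field(default_factory=list)


def inhibition_rate(A, a, B, b):
    """Blank-corrected inhibition rate in percent.

    Accepts scalars or arrays. May legitimately fall outside [0, 100] on
    noisy input; clamping is an aggregation-time policy, not applied here.
    Raises :class:`DegenerateControlError` when the uninhibited signal
    ``a - A`` is not positive.
    """
    A, a, B, b = (np.asarray(x, dtype=float) for x in (A, a, B, b))
    signal = a - A
    if np.any(signal <= 0):
        raise DegenerateControlError(
            "uninhibited control produced no signal (a - A <= 0)"
        )
    rate = (1.0 - (b - B) / signal) * 100.0
    return float(rate) if rate.ndim == 0 else rate


def aggregate_dose_response(
    assay: PlateAssay,
    clamp: tuple[float, float] = (0.0, 100.0),
) -> DoseResponse:
    """Per-dose mean and sample SD of replicate inhibition rates.

    Raw replicate rates are clamped into ``clamp`` (default the physical
    [0, 100]% range) before averaging; the zero-dose point is retained as a
    QC anchor even though the probit fit later excludes it.
    """
    df = assay.data
    rates = inhibition_rate(df["A"], df["a"], df["B"], df["b"])
    rates = np.clip(rates, clamp[0], clamp[1])
    tmp = pd.DataFrame(
        {"conc_mg_ml": df["inhibitor_conc_mg_ml"].to_numpy(), "rate": rates}
    )
    grouped = tmp.groupby("conc_mg_ml", sort=True)["rate"]
    points = pd.DataFrame(
        {
            "conc_mg_ml": grouped.mean().index.to_numpy(),
            "mean_inhibition_pct": grouped.mean().to_numpy(),
            "sd_pct": grouped.std(ddof=1).fillna(0.0).to_numpy(),
            "n_rep": grouped.count().to_numpy(),
        }
    )
    return DoseResponse(points=points)


def fit_ic50(
    dr: DoseResponse,
    clamp_pct: tuple[float, float] = (0.5, 99.5),
    min_points: int = 3,
) -> IC50Fit:
    """Probit regression of mean inhibition on log10 concentration.

    Mean percentages are clamped into ``clamp_pct`` (the probit transform
    is undefined at exactly 0 or 100%), transformed with the inverse
    standard normal CDF, and regressed on log10 dose by unweighted least
    squares, excluding the zero-dose anchor. Then
    ``ic50 = 10**(-intercept/slope)`` and the 95% CI follows from the delta
    method on the log10 scale.

    Raises :class:`InsufficientDataError` below ``min_points`` usable
    doses; attaches an extrapolation warning when all points sit on one
    side of 50%.
    """
    pts = dr.points[dr.points["conc_mg_ml"] > 0]
    if len(pts) < min_points:
        raise InsufficientDataError(
            f"probit fit needs >= {min_points} nonzero doses, got {len(pts)}"
        )
    conc = pts["conc_mg_ml"].to_numpy(dtype=float)
    pct = np.clip(pts["mean_inhibition_pct"].to_numpy(dtype=float), *clamp_pct)
    x = np.log10(conc)
    y = stats.norm.ppf(pct / 100.0)

    X = np.column_stack([np.ones_like(x), x])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    b0, b1 = beta
    fitted = X @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    warnings = []
    if b1 == 0:
        raise InsufficientDataError("probit slope is zero; IC50 undefined")
    log_ic50 = -b0 / b1
    ic50 = 10.0**log_ic50

    # delta-method variance of -b0/b1 on the log10 scale
    df_resid = len(x) - 2
    if df_resid > 0 and ss_res > 0:
        sigma2 = ss_res / df_resid
        cov = sigma2 * np.linalg.inv(X.T @ X)
        grad = np.array([-1.0 / b1, b0 / b1**2])
        var_log = float(grad @ cov @ grad)
        half = stats.t.ppf(0.975, df_resid) * np.sqrt(var_log)
        ci = (10.0 ** (log_ic50 - half), 10.0 ** (log_ic50 + half))
    else:
        ci = (ic50, ic50)
        warnings.append("exact fit: no residual degrees of freedom for a CI")

    if np.all(pct < 50.0) or np.all(pct > 50.0):
        warnings.append("all doses on one side of 50% inhibition: IC50 is extrapolated")

    return IC50Fit(
        ic50=float(ic50),
        slope=float(b1),
        intercept=float(b0),
        ci95=ci,
        r2=r2,
        warnings=warnings,
    )
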