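"""Type-plot diagnostics, Lineweaver–Burk fits and inhibition-type verdicts."""

import numpy as np
import pandas as pd
import pytest

from enzybind import kinetics as kin
from enzybind import synthetic_data as sd
from enzybind.errors import InsufficientDataError


def _series(rows):
    return kin.VelocitySeries(data=pd.DataFrame(rows))


def _proportional_sweep(slopes_by_dose, intercepts_by_dose=None, S=1.6):
    rows = []
    for dose, k in slopes_by_dose.items():
        c = (intercepts_by_dose or {}).get(dose, 0.0)
        for E in (5.0, 10.0, 15.0, 20.0):
            rows.append({"substrate_conc_mg_ml": S, "enzyme_conc_mg_ml": E,
                         "inhibitor_conc_mg_ml": dose,
                         "velocity_per_min": k * E + c})
    return _series(rows)


def test_type_plot_proportional_slopes_and_zero_intercepts():
    tp = kin.fit_type_plot(_proportional_sweep({0.0: 1.0, 1.0: 0.5, 2.0: 0.25}))
    lines = tp.lines.sort_values("inhibitor_conc_mg_ml")
    assert lines["slope"].to_numpy() == pytest.approx([1.0, 0.5, 0.25])
    assert lines["intercept"].to_numpy() == pytest.approx([0.0, 0.0, 0.0], abs=1e-12)


def test_type_plot_needs_three_enzyme_levels():
    rows = [{"substrate_conc_mg_ml": 1.6, "enzyme_conc_mg_ml": E,
             "inhibitor_conc_mg_ml": 0.0, "velocity_per_min": E}
            for E in (5.0, 10.0)]
    with pytest.raises(InsufficientDataError):
        kin.fit_type_plot(_series(rows))


def _type_plot(doses, slopes, intercepts):
    return kin.TypePlot(lines=pd.DataFrame({
        "inhibitor_conc_mg_ml": doses, "slope": slopes, "intercept": intercepts,
        "slope_se": 0.0, "intercept_se": 0.0, "r2": 1.0}))


@pytest.mark.parametrize(
    "slopes, intercepts, verdict",
    [
        ([1.0, 0.7, 0.5], [0.0, 0.0, 0.0], "reversible"),
        ([1.0, 1.0, 1.0], [0.0, -0.2, -0.4], "irreversible"),  # parallel lines
        ([1.0, 1.2, 0.8], [0.0, 0.0, 0.0], "indeterminate"),  # non-monotone
    ],
)
def test_reversibility_verdicts(slopes, intercepts, verdict):
    tp = _type_plot([0.0, 1.0, 2.0], slopes, intercepts)
    assert kin.classify_reversibility(tp) == verdict


def test_generated_reversible_and_irreversible_sweeps_classify():
    design = sd.AssayDesign()
    truth = sd.GroundTruth()
    rev = kin.fit_type_plot(sd.generate_enzyme_sweep(design, truth, reversible=True))
    irr = kin.fit_type_plot(sd.generate_enzyme_sweep(design, truth, reversible=False))
    assert kin.classify_reversibility(rev) == "reversible"
    assert kin.classify_reversibility(irr) == "irreversible"


def test_lineweaver_burk_noiseless_control_parameters(design, truth):
    fit = kin.lineweaver_burk(sd.generate_velocity_series(design, truth))
    assert fit.Km == pytest.approx(0.25, rel=1e-9)
    assert fit.Vmax == pytest.approx(5.46, rel=1e-9)
    assert fit.Ki == pytest.approx(0.88, rel=1e-9)
    assert fit.verdict == "competitive"


def test_competitive_signature_km_app_scaling(design, truth):
    """Km_app/Km - 1 == [I]/Ki and Vmax constant across doses."""
    fit = kin.lineweaver_burk(sd.generate_velocity_series(design, truth))
    for dose, km_app in fit.Km_app_by_I.items():
        assert km_app / truth.Km - 1.0 == pytest.approx(dose / truth.Ki, abs=1e-3)
    vmax = np.array(list(fit.Vmax_app_by_I.values()))
    assert (vmax.max() - vmax.min()) / vmax.mean() < 1e-3


def test_competitive_at_dose_equal_ki_doubles_km():
    design = sd.AssayDesign(inhibitor_concs=(0.0, 0.88))
    fit = kin.lineweaver_burk(sd.generate_velocity_series(design, sd.GroundTruth()))
    assert fit.Km_app_by_I[0.88] == pytest.approx(0.50, rel=1e-9)
    assert fit.Vmax_app_by_I[0.88] == pytest.approx(5.46, rel=1e-9)


@pytest.mark.parametrize("mechanism", ["competitive", "noncompetitive", "uncompetitive"])
def test_verdict_matches_generating_mechanism(design, truth, mechanism):
    vs = sd.generate_velocity_series(design, truth, mechanism=mechanism)
    assert kin.lineweaver_burk(vs).verdict == mechanism


def test_mixed_verdict_when_both_parameters_drift(design, truth):
    """Km rising while Vmax falls beyond tolerance must never be called
    competitive."""
    comp = sd.generate_velocity_series(design, truth).data.copy()
    # depress velocities progressively with dose: Vmax no longer shared
    comp["velocity_per_min"] *= 1.0 / (1.0 + 0.2 * comp["inhibitor_conc_mg_ml"])
    fit = kin.lineweaver_burk(kin.VelocitySeries(data=comp))
    assert fit.verdict == "mixed"
    assert any("downgraded" in w for w in fit.warnings)


def test_reciprocal_fit_matches_nonlinear_oracle(design, truth):
    """On noiseless data the double-reciprocal and direct Michaelis-Menten
    fits agree to machine-level relative error."""
    vs = sd.generate_velocity_series(design, truth)
    lb = kin.lineweaver_burk(vs)
    mm = kin.michaelis_menten_fit(vs)
    for dose, (km_app, vmax_app) in mm.items():
        assert lb.Km_app_by_I[dose] == pytest.approx(km_app, rel=1e-6)
        assert lb.Vmax_app_by_I[dose] == pytest.approx(vmax_app, rel=1e-6)


def test_global_competitive_fit_noiseless_exact(design, truth):
    km, vmax, ki = kin.fit_competitive_global(sd.generate_velocity_series(design, truth))
    assert km == pytest.approx(truth.Km, rel=1e-6)
    assert vmax == pytest.approx(truth.Vmax, rel=1e-6)
    assert ki == pytest.approx(truth.Ki, rel=1e-6)


def test_zero_velocity_points_excluded_with_warning(design, truth):
    df = sd.generate_velocity_series(design, truth).data.copy()
    df.loc[df.index[0], "velocity_per_min"] = 0.0
    # keep >= 4 usable substrate levels in that dose group
    fit = kin.lineweaver_burk(kin.VelocitySeries(data=df))
    assert any("V <= 0" in w for w in fit.warnings)


def test_too_few_substrate_levels_raise():
    rows = [{"substrate_conc_mg_ml": S, "enzyme_conc_mg_ml": 5.0,
             "inhibitor_conc_mg_ml": 0.0,
             "velocity_per_min": 5.0 * S / (0.25 + S)}
            for S in (0.4, 0.8, 1.2)]
    with pytest.raises(InsufficientDataError):
        kin.lineweaver_burk(_series(rows))
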