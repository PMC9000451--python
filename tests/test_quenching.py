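"""Spectral peak reduction, Stern–Volmer / double-log fits and mechanism calls."""

import numpy as np
import pytest

from enzybind import quenching as q
from enzybind import synthetic_data as sd
from enzybind.errors import InsufficientDataError, NoPeakError


def _gauss_series(Q, amplitudes, centers, temperature=293.0):
    wl = np.arange(300.0, 400.01, 0.05)
    spectra = np.vstack([
        a * np.exp(-((wl - c) ** 2) / (2 * 25.0**2))
        for a, c in zip(amplitudes, centers)
    ])
    return q.TitrationSeries(temperature, np.asarray(Q), wl, spectra, 5e-6)


def test_peak_reduce_locates_gaussian_center():
    series = _gauss_series([0.0], [1000.0], [340.0])
    (qv, F, lam), = q.peak_reduce(series)
    assert (qv, F, lam) == (0.0, pytest.approx(1000.0), pytest.approx(340.0))


def test_peak_shift_zero_for_identical_spectra():
    series = _gauss_series([0.0, 1e-5, 1e-4], [1.0, 1.0, 1.0], [340.0] * 3)
    reduced = q.peak_reduce(series)
    assert reduced[-1][2] - reduced[0][2] == 0.0


def test_generator_red_shift_round_trip(design, truth):
    fit = q.fit_titration(sd.generate_titration(design, truth)[293.0])
    # 0.1 nm per unit ratio, max ratio 20 -> +2 nm
    assert fit.peak_shift == pytest.approx(2.0, abs=1e-9)


def test_flat_spectrum_raises():
    wl = np.arange(300.0, 400.01, 0.05)
    series = q.TitrationSeries(293.0, np.array([0.0]), wl,
                               np.full((1, wl.size), 5.0), 5e-6)
    with pytest.raises(NoPeakError):
        q.peak_reduce(series)


def test_argmax_tie_breaks_to_longer_wavelength():
    wl = np.array([300.0, 340.0, 341.0, 400.0])
    series = q.TitrationSeries(293.0, np.array([0.0]), wl,
                               np.array([[0.0, 1.0, 1.0, 0.0]]), 5e-6)
    assert q.peak_reduce(series)[0][2] == 341.0


def test_peak_reduction_invariant_to_uniform_scaling(design, truth):
    series = sd.generate_titration(design, truth)[293.0]
    scaled = q.TitrationSeries(series.temperature, series.Q, series.wavelengths,
                               series.intensities * 37.0, series.enzyme_molar_conc)
    f1, f2 = q.fit_titration(series), q.fit_titration(scaled)
    assert f2.Ksv == pytest.approx(f1.Ksv, rel=1e-12)
    assert f2.Ka == pytest.approx(f1.Ka, rel=1e-12)
    assert f2.peak_shift == f1.peak_shift


def test_stern_volmer_round_trip_and_kq_identity():
    ksv_true, F0 = 6.03e4, 1000.0
    Q = np.array([0.0, 2.5e-6, 5e-6, 1e-5, 2e-5, 2.5e-5, 5e-5, 1e-4])
    points = [(qq, F0 / (1.0 + ksv_true * qq)) for qq in Q]
    ksv, kq, diag = q.stern_volmer_fit(points, F0)
    assert ksv == pytest.approx(ksv_true, rel=1e-12)
    assert kq == ksv / q.DEFAULT_TAU0  # exact identity, not approx
    assert diag["r2"] == pytest.approx(1.0)
    # direct model check at the top concentration: F0/F = 1 + 6.03 = 7.03
    assert F0 / points[-1][1] == pytest.approx(7.03, abs=1e-10)


def test_stern_volmer_zero_slope_for_constant_intensity():
    points = [(qq, 500.0) for qq in (0.0, 1e-5, 2e-5, 5e-5)]
    ksv, kq, diag = q.stern_volmer_fit(points, 500.0)
    assert ksv == 0.0 and kq == 0.0


def test_stern_volmer_negative_slope_flagged():
    points = [(1e-5, 510.0), (2e-5, 520.0), (5e-5, 560.0)]
    ksv, _, diag = q.stern_volmer_fit(points, 500.0)
    assert ksv < 0 and any("no quenching" in w for w in diag["warnings"])


def _fit(T, ksv, kq):
    return q.QuenchFit(temperature=T, Ksv=ksv, Kq=kq, tau0=1e-8, Ka=ksv,
                       n_sites=1.0, peak_shift=0.0, r2_sv=1.0, r2_loglog=1.0,
                       sv_free_intercept=1.0)


@pytest.mark.parametrize(
    "ksv_by_T, tau0, expected",
    [
        ({293.0: 0.58e4, 303.0: 0.44e4}, 1e-8, "static"),  # Kq ~ 1e12, Ksv falls
        ({293.0: 100.0, 303.0: 130.0}, 1e-8, "dynamic"),  # Kq ~ 1e10, Ksv rises
        ({293.0: 0.5e4, 303.0: 0.6e4}, 1e-8, "indeterminate"),  # conflict
    ],
)
def test_mechanism_classification(ksv_by_T, tau0, expected):
    fits = {T: _fit(T, ksv, ksv / tau0) for T, ksv in ksv_by_T.items()}
    assert q.classify_mechanism(fits) == expected


def test_mechanism_single_temperature_uses_kq_only():
    assert q.classify_mechanism({293.0: _fit(293.0, 6e4, 6e12)}) == "static"
    assert q.classify_mechanism({293.0: _fit(293.0, 150.0, 1.5e10)}) == "dynamic"


def test_mechanism_total_over_random_inputs():
    rng = np.random.default_rng(0)
    for _ in range(200):
        ksv = rng.uniform(-1e3, 1e5, size=2)
        fits = {T: _fit(T, k, k / 1e-8) for T, k in zip((293.0, 303.0), ksv)}
        assert q.classify_mechanism(fits) in {"static", "dynamic", "indeterminate"}


def test_double_log_exact_single_site_identity():
    # (F0-F)/F = Ka*Q with Ka = 1e5: intercept 5, slope 1
    F0 = 1000.0
    Q = np.array([2.5e-6, 5e-6, 1e-5, 2e-5, 5e-5, 1e-4])
    points = [(qq, F0 / (1.0 + 1e5 * qq)) for qq in Q]
    ka, n, _ = q.double_log_fit(points, F0)
    assert np.log10(ka) == pytest.approx(5.0, abs=1e-12)
    assert n == pytest.approx(1.0, abs=1e-12)


def test_double_log_generator_round_trip_strong_binder():
    truth = sd.GroundTruth(Ksv_by_T={293.0: 15.53e4},
                           Ka_by_T={293.0: 15.53e4}, n_sites=1.0)
    design = sd.AssayDesign(temperatures=(293.0,))
    fit = q.fit_titration(sd.generate_titration(design, truth)[293.0])
    assert fit.Ka == pytest.approx(15.53e4, rel=1e-9)
    assert fit.n_sites == pytest.approx(1.0, abs=1e-9)


def test_double_log_sublinear_sites_recovered():
    truth = sd.GroundTruth(Ksv_by_T={293.0: 0.58e4},
                           Ka_by_T={293.0: 7.14}, n_sites=0.34)
    design = sd.AssayDesign(temperatures=(293.0,))
    fit = q.fit_titration(sd.generate_titration(design, truth)[293.0])
    assert fit.n_sites == pytest.approx(0.34, abs=1e-9)
    assert fit.n_sites < 1.0
    assert fit.Ka == pytest.approx(7.14, rel=1e-9)


def test_double_log_excludes_unquenched_points():
    F0 = 1000.0
    points = [(1e-6, 1000.0), (2.5e-6, 990.0), (1e-5, 900.0), (5e-5, 700.0)]
    ka, n, diag = q.double_log_fit(points, F0)
    assert any("excluded" in w for w in diag["warnings"])
    points_bad = [(1e-6, 1000.0), (2e-6, 1001.0), (4e-6, 1002.0)]
    with pytest.raises(InsufficientDataError):
        q.double_log_fit(points_bad, F0)


def test_ka_equals_ksv_for_single_site_noiseless(design, truth):
    """For n = 1 static quenching the double-log Ka and the Stern-Volmer
    Ksv are the same constant."""
    fits = q.analyze_titrations(sd.generate_titration(design, truth))
    for f in fits.values():
        assert f.Ka == pytest.approx(f.Ksv, rel=1e-6)


def test_generator_series_classified_static(design, truth):
    fits = q.analyze_titrations(sd.generate_titration(design, truth))
    assert all(f.mechanism == "static" for f in fits.values())
    assert fits[293.0].Ksv == pytest.approx(6.03e4, rel=1e-9)
    assert fits[303.0].Ksv == pytest.approx(4.19e4, rel=1e-9)
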