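"""MSD extraction and resilience fits for elastic neutron scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbflex.neutron_elastic import (
    IN13_Q2_WINDOW,
    SPHERES_T_WINDOWS,
    ElasticScan,
    MSDSeries,
    ResilienceFit,
    fit_msd,
    force_constant,
    q_from_angle,
    read_scans,
    rmsd_at_temperature,
    scans_to_msd_series,
    windowed_force_constants,
)
from hbflex.synthetic_data import ScanGeneratorSpec, gen_elastic_scans


def _series(T, u2, sigma=None):
    sigma = np.full_like(np.asarray(u2, float), 1e-3) if sigma is None else sigma
    return MSDSeries(pd.DataFrame({"T": T, "u2": u2, "u2_sigma": sigma}))


@pytest.mark.parametrize(
    "wavelength, two_theta, expected",
    [
        (6.27, 0.0, 0.0),
        (4 * np.pi, 180.0, 1.0),  # sin(90 deg) = 1
        (2 * np.pi, 60.0, 1.0),  # 2 sin(30 deg) = 1
    ],
)
def test_q_from_angle(wavelength, two_theta, expected):
    assert q_from_angle(wavelength, two_theta) == pytest.approx(expected)


def test_q_from_angle_validation():
    with pytest.raises(ValueError, match="wavelength"):
        q_from_angle(-1.0, 30.0)
    with pytest.raises(ValueError, match="two_theta"):
        q_from_angle(6.0, 200.0)


def test_constant_intensity_gives_zero_msd():
    q2 = np.linspace(0.5, 4.0, 15)
    scan = ElasticScan(300.0, q2, np.ones_like(q2))
    u2, _, flag = fit_msd(scan)
    assert u2 == pytest.approx(0.0, abs=1e-12)
    assert not flag


def test_noise_free_gaussian_decay_recovered_exactly():
    q2 = np.linspace(0.4, 4.0, 25)
    scan = ElasticScan(300.0, q2, np.exp(-1.5 * q2 / 6.0))
    u2, u2_sigma, _ = fit_msd(scan, divisor=6)
    assert u2 == pytest.approx(1.5, rel=1e-12)


def test_windowed_fit_beats_full_range_under_curvature():
    """Curvature beyond the linear region biases only the full-range fit."""
    spec = ScanGeneratorSpec(
        slope=0.0184, intercept=-4.211, noise_cv=0.0, non_gaussian_c4=-1.0, seed=0
    )
    scans, truth = gen_elastic_scans(spec)
    scan = scans[-1]
    u2_true = truth["u2"][scan.temperature]
    u2_win, _, _ = fit_msd(scan, IN13_Q2_WINDOW)
    u2_full, _, _ = fit_msd(scan, (scan.q2.min(), scan.q2.max()))
    assert abs(u2_win - u2_true) < abs(u2_full - u2_true)


def test_fit_msd_input_validation():
    q2 = np.linspace(1.7, 3.4, 8)
    with pytest.raises(ValueError, match=">= 3 points"):
        fit_msd(ElasticScan(300.0, q2, np.ones_like(q2)), q2_window=(5.0, 6.0))
    bad = ElasticScan(300.0, q2, np.ones_like(q2))
    bad.intensity = bad.intensity - 1.0  # zero intensities inside window
    with pytest.raises(ValueError, match="non-positive"):
        fit_msd(bad)
    with pytest.raises(ValueError, match="divisor"):
        fit_msd(ElasticScan(300.0, q2, np.ones_like(q2)), divisor=4)


def test_gaussian_validity_flag_threshold():
    """Flag fires exactly when u2 * q2_max / divisor crosses the bound."""
    q2 = np.linspace(0.5, 4.0, 20)
    for u2_true, expect in ((2.9, False), (3.1, True)):
        scan = ElasticScan(300.0, q2, np.exp(-u2_true * q2 / 6.0))
        _, _, flag = fit_msd(scan, (0.5, 4.0), validity_bound=2.0)
        assert flag is expect  # u2 * 4.0 / 6 vs 2.0


def test_force_constant_resilience_conversion():
    """slope 0.0184 A^2/K -> 0.00276/0.0184 = 0.15 N/m."""
    T = np.arange(280.0, 316.0, 5.0)
    fit = force_constant(_series(T, 0.5 + 0.0184 * (T - 280.0)))
    assert fit.k_eff == pytest.approx(0.15, rel=1e-10)
    assert fit.slope == pytest.approx(0.0184, rel=1e-10)


def test_doubling_msd_halves_resilience():
    T = np.arange(280.0, 316.0, 5.0)
    u2 = 0.3 + 0.01 * (T - 280.0)
    k1 = force_constant(_series(T, u2)).k_eff
    k2 = force_constant(_series(T, 2 * u2)).k_eff
    assert k2 == pytest.approx(k1 / 2.0, rel=1e-9)


def test_non_positive_slope_reports_diagnostic():
    T = np.arange(280.0, 316.0, 5.0)
    fit = force_constant(_series(T, 2.0 - 0.01 * (T - 280.0)))
    assert np.isnan(fit.k_eff)
    assert "slope" in fit.diagnostic


def test_three_window_piecewise_recovery():
    """Independent window fits recover the generative piecewise slopes."""
    slopes = {(10.0, 100.0): 4.06e-4, (100.0, 200.0): 2.76e-3, (252.0, 292.0): 1.31e-2}
    T = np.arange(10.0, 301.0, 5.0)
    u2 = np.empty_like(T)
    for i, t in enumerate(T):
        u = 0.02 + 4.06e-4 * (min(t, 100) - 10)
        if t > 100:
            u += 2.76e-3 * (min(t, 200) - 100)
        if t > 200:
            u += 1.31e-2 * (t - 200)
        u2[i] = u
    fits = windowed_force_constants(_series(T, u2))
    for window, slope in slopes.items():
        assert fits[window].slope == pytest.approx(slope, rel=1e-6)


def test_single_regime_gives_equal_window_constants():
    T = np.arange(10.0, 301.0, 5.0)
    fits = windowed_force_constants(_series(T, 0.05 + 2e-3 * T))
    ks = [f.k_eff for f in fits.values()]
    assert ks[0] == pytest.approx(ks[1], rel=1e-9)
    assert ks[1] == pytest.approx(ks[2], rel=1e-9)


def test_sparse_window_skipped_with_warning():
    T = np.arange(150.0, 301.0, 5.0)  # nothing below 150 K
    with pytest.warns(UserWarning, match="skipped"):
        fits = windowed_force_constants(_series(T, 0.05 + 2e-3 * T))
    assert (10, 100) not in fits


def test_rmsd_flat_series():
    fit = ResilienceFit(
        k_eff=np.nan, k_sigma=np.nan, slope=0.0, slope_sigma=0.0,
        intercept=1.44, intercept_sigma=0.01, slope_intercept_cov=0.0,
        T_window=(280.0, 315.0), n_points=8,
    )
    for T in (100.0, 300.0, 400.0):
        assert rmsd_at_temperature(fit, T)[0] == pytest.approx(1.2)


def test_rmsd_rejects_negative_interpolation():
    fit = ResilienceFit(
        k_eff=0.15, k_sigma=0.01, slope=0.0184, slope_sigma=1e-4,
        intercept=-4.211, intercept_sigma=0.05, slope_intercept_cov=0.0,
        T_window=(280.0, 315.0), n_points=8,
    )
    with pytest.raises(ValueError, match="non-positive"):
        rmsd_at_temperature(fit, 100.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    slope=st.floats(min_value=1e-3, max_value=0.05),
    u2_280=st.floats(min_value=0.1, max_value=2.0),
)
def test_zero_noise_roundtrip_property(slope, u2_280):
    """generate -> fit recovers slope and intercept to 1e-6 relative."""
    intercept = u2_280 - slope * 280.0
    spec = ScanGeneratorSpec(slope=slope, intercept=intercept, noise_cv=0.0, seed=0)
    scans, _ = gen_elastic_scans(spec)
    series = scans_to_msd_series(scans, IN13_Q2_WINDOW)
    fit = force_constant(series)
    assert fit.slope == pytest.approx(slope, rel=1e-6)
    assert fit.intercept == pytest.approx(intercept, rel=1e-6, abs=1e-6)


@pytest.mark.parametrize("noise_cv", [0.005, 0.02, 0.05])
def test_estimator_consistency_under_noise(noise_cv):
    """k' bias shrinks with noise; recovery stays within replicate spread."""
    rng = np.random.default_rng(123)
    ks = []
    for _ in range(50):
        spec = ScanGeneratorSpec(
            k_target=0.15, intercept=-4.211, noise_cv=noise_cv,
            seed=int(rng.integers(2**31 - 1)),
        )
        scans, _ = gen_elastic_scans(spec)
        fit = force_constant(scans_to_msd_series(scans, IN13_Q2_WINDOW))
        ks.append(fit.k_eff)
    mean, sd = np.mean(ks), np.std(ks, ddof=1)
    assert abs(mean - 0.15) < max(3 * sd / np.sqrt(len(ks)), 0.01 * 0.15 * (noise_cv / 0.005))


def test_read_scans_long_format(tmp_path):
    path = tmp_path / "scans.tsv"
    spec = ScanGeneratorSpec(slope=0.01, intercept=0.0, noise_cv=0.01, seed=3)
    scans, _ = gen_elastic_scans(spec)
    rows = ["T\tq2\tI\tsigma"]
    for s in scans:
        rows += [
            f"{s.temperature}\t{a}\t{b}\t{c}"
            for a, b, c in zip(s.q2, s.intensity, s.sigma)
        ]
    path.write_text("\n".join(rows) + "\n")
    back = read_scans(path)
    assert len(back) == len(scans)
    np.testing.assert_allclose(back[0].intensity, scans[0].intensity, rtol=1e-12)
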