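"""Recovery properties of the fitting chain: profile, surface-value,
indirect-pressure and total-exponential fits, and the table assembly."""

import numpy as np
import pytest

from hydrep import (
    FitError,
    LGParameters,
    OrderParameterProfile,
    PressureDistanceCurve,
    SystemDataset,
    ValidationError,
    extract_parameter_table,
    fit_indirect_pressure,
    fit_profile_sinh,
    fit_surface_values,
    fit_total_exponential,
    indirect_pressure,
    profile_antisymmetric,
    surface_value,
)


def sinh_profile(d, lam, m_s, n=200, noise=0.0, rng=None):
    z = np.linspace(-d / 2, d / 2, n)
    vals = m_s * np.sinh(z / lam) / np.sinh(d / (2 * lam))
    if noise:
        vals = vals + noise * np.max(np.abs(vals)) * rng.standard_normal(n)
    return OrderParameterProfile(z=z, values=vals, d=d)


class TestProfileFit:
    def test_noiseless_recovery_to_machine_precision(self):
        prof = sinh_profile(2.0, 0.28, -0.84)
        fr = fit_profile_sinh(prof)
        assert fr.estimates["lam"] == pytest.approx(0.28, rel=1e-6)
        assert fr.estimates["m_s"] == pytest.approx(-0.84, rel=1e-6)

    def test_noisy_recovery_within_three_sigma(self):
        """5% noise, 200 points: the estimate and its reported 1-sigma
        uncertainty are consistent with the truth over 100 replicates."""
        rng = np.random.default_rng(42)
        lam_true = 0.28
        pulls, lams = [], []
        for _ in range(100):
            prof = sinh_profile(2.0, lam_true, -0.84, noise=0.05, rng=rng)
            fr = fit_profile_sinh(prof)
            lams.append(fr.estimates["lam"])
            pulls.append((fr.estimates["lam"] - lam_true) / fr.std_errors["lam"])
        assert abs(np.mean(lams) - lam_true) < 3 * np.std(lams) / 10  # 100 reps
        assert np.mean(np.abs(np.asarray(pulls)) < 3) > 0.95

    def test_estimator_bias_below_two_percent(self):
        rng = np.random.default_rng(7)
        lams = [
            fit_profile_sinh(
                sinh_profile(2.0, 0.28, -0.84, noise=0.05, rng=rng)
            ).estimates["lam"]
            for _ in range(100)
        ]
        assert abs(np.mean(lams) / 0.28 - 1.0) < 0.02

    def test_symmetric_profile_rejected(self):
        z = np.linspace(-1.0, 1.0, 100)
        vals = np.cosh(z / 0.3)
        prof = OrderParameterProfile(z=z, values=vals, d=2.0)
        with pytest.raises(FitError, match="antisymmetric"):
            fit_profile_sinh(prof)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_profile_sinh(sinh_profile(2.0, 0.28, -0.8, n=5))


class TestSurfaceValueFit:
    def test_noiseless_exact_recovery(self, dppc_params):
        ds = np.array([0.6, 0.9, 1.2, 1.6, 2.0, 2.4])
        pts = [(d, surface_value(d, dppc_params)) for d in ds]
        fr = fit_surface_values(pts, lam_fixed=dppc_params.lam)
        assert fr.estimates["h_over_a"] == pytest.approx(-0.273, rel=1e-12)
        assert fr.residual_norm < 1e-12

    def test_sign_follows_surface_values(self):
        p = LGParameters.from_correlation_length(a=492.0, lam=0.22, h_over_a=0.15)
        pts = [(d, surface_value(d, p)) for d in (0.6, 1.2, 2.4)]
        fr = fit_surface_values(pts, lam_fixed=0.22)
        assert fr.estimates["h_over_a"] > 0

    def test_needs_three_separations(self):
        with pytest.raises(ValidationError):
            fit_surface_values([(0.5, -1.0), (1.0, -1.1)], lam_fixed=0.22)


class TestIndirectPressureFit:
    def test_noiseless_self_consistency(self):
        p = LGParameters.from_correlation_length(a=500.0, lam=0.21, h_over_a=-0.3)
        d = np.arange(0.3, 1.8, 0.1)
        curve = PressureDistanceCurve(
            d=d, pressure=np.array([indirect_pressure(x, p) for x in d]),
            contribution="indirect",
        )
        fr = fit_indirect_pressure(curve)
        assert fr.estimates["lam"] == pytest.approx(0.21, rel=1e-6)
        assert fr.estimates["amplitude"] == pytest.approx(p.h**2 / p.b, rel=1e-6)

    def test_amplitude_to_stiffness_inversion(self, dppc_params):
        """Amplitude built from (a=492, lam=0.22, h/a=-0.273) returns a=492."""
        d = np.arange(0.3, 2.4, 0.1)
        curve = PressureDistanceCurve(
            d=d,
            pressure=np.array([indirect_pressure(x, dppc_params) for x in d]),
            contribution="indirect",
        )
        fr = fit_indirect_pressure(curve, h_over_a_fixed=-0.273)
        assert fr.estimates["a"] == pytest.approx(492.0, rel=1e-6)

    def test_noisy_decanol_recovery_within_interval(self, decanol_params):
        rng = np.random.default_rng(3)
        d = np.arange(0.3, 1.5, 0.05)
        base = np.array([indirect_pressure(x, decanol_params) for x in d])
        weights = 1.0 / (0.05 * base) ** 2  # known multiplicative noise
        hits = 0
        for _ in range(50):
            curve = PressureDistanceCurve(
                d=d, pressure=base * (1 + 0.05 * rng.standard_normal(d.size)),
                contribution="indirect",
            )
            fr = fit_indirect_pressure(curve, weights=weights)
            lo = fr.estimates["lam"] - 3 * fr.std_errors["lam"]
            hi = fr.estimates["lam"] + 3 * fr.std_errors["lam"]
            hits += lo <= decanol_params.lam <= hi
        assert hits >= 47

    def test_nonpositive_points_excluded_and_reported(self, dppc_params):
        d = np.arange(0.3, 1.4, 0.1)
        pressure = np.array([indirect_pressure(x, dppc_params) for x in d])
        pressure[4] = -0.5
        curve = PressureDistanceCurve(d=d, pressure=pressure, contribution="indirect")
        fr = fit_indirect_pressure(curve)
        assert fr.excluded_points == (4,)
        assert fr.n_points_used == d.size - 1

    def test_all_nonpositive_rejected(self):
        curve = PressureDistanceCurve(
            d=np.array([0.5, 1.0, 1.5, 2.0]),
            pressure=np.array([-1.0, -0.5, -0.2, -0.1]),
        )
        with pytest.raises(FitError):
            fit_indirect_pressure(curve)


class TestTotalExponentialFit:
    def test_negative_point_exclusion_rule(self):
        """[10, 5, -0.1, 2]: exactly the negative point is dropped."""
        curve = PressureDistanceCurve(
            d=np.array([0.5, 1.0, 1.5, 2.0]),
            pressure=np.array([10.0, 5.0, -0.1, 2.0]),
        )
        fr = fit_total_exponential(curve)
        assert fr.excluded_points == (2,)
        assert fr.n_points_used == 3

    def test_zero_pressure_is_retained(self):
        curve = PressureDistanceCurve(
            d=np.array([0.5, 1.0, 1.5, 2.0]),
            pressure=np.array([10.0, 5.0, 0.0, 2.0]),
        )
        fr = fit_total_exponential(curve)
        assert fr.excluded_points == ()
        assert fr.n_points_used == 4

    def test_exact_exponential_recovery(self):
        d = np.linspace(0.4, 2.4, 15)
        curve = PressureDistanceCurve(d=d, pressure=120.0 * np.exp(-d / 0.26))
        fr = fit_total_exponential(curve)
        assert fr.estimates["lam_tilde"] == pytest.approx(0.26, rel=1e-6)
        assert fr.estimates["amplitude"] == pytest.approx(120.0, rel=1e-6)

    def test_log_linear_and_nonlinear_agree_noiseless(self):
        d = np.linspace(0.4, 2.4, 15)
        p = 80.0 * np.exp(-d / 0.21)
        curve = PressureDistanceCurve(d=d, pressure=p)
        fr = fit_total_exponential(curve)
        slope, intercept = np.polyfit(d, np.log(p), 1)
        assert -1.0 / slope == pytest.approx(
            fr.estimates["lam_tilde"], abs=max(fr.std_errors["lam_tilde"], 1e-9)
        )

    def test_too_few_survivors_rejected(self):
        curve = PressureDistanceCurve(
            d=np.array([0.5, 1.0, 1.5]),
            pressure=np.array([1.0, -0.1, -0.2]),
        )
        with pytest.raises(FitError):
            fit_total_exponential(curve)


class TestParameterTable:
    def test_common_lambda_across_all_three_routes(self, dppc_params):
        """Profiles, surface values and pressures generated with one
        lambda give back one lambda through every route."""
        ds = (0.6, 0.9, 1.2, 1.6, 2.0, 2.4)
        profiles = [profile_antisymmetric(d, dppc_params, 201) for d in ds]
        lam_profiles = [fit_profile_sinh(p).estimates["lam"] for p in profiles]
        dgrid = np.arange(0.3, 2.4, 0.1)
        curve = PressureDistanceCurve(
            d=dgrid,
            pressure=np.array([indirect_pressure(x, dppc_params) for x in dgrid]),
            contribution="indirect",
        )
        lam_pressure = fit_indirect_pressure(curve).estimates["lam"]
        pts = [(d, surface_value(d, dppc_params)) for d in ds]
        hoa = fit_surface_values(pts, lam_fixed=np.mean(lam_profiles))
        assert np.allclose(lam_profiles, dppc_params.lam, rtol=1e-6)
        assert lam_pressure == pytest.approx(dppc_params.lam, rel=1e-6)
        assert hoa.estimates["h_over_a"] == pytest.approx(
            dppc_params.h_over_a, rel=1e-6
        )

    def test_full_synthetic_dataset_recovers_truth(self, dppc_params):
        ds = (0.6, 0.9, 1.2, 1.6, 2.0, 2.4)
        dgrid = np.arange(0.3, 2.4, 0.1)
        dataset = SystemDataset(
            label="dppc_like",
            profiles={
                "polarization": [
                    profile_antisymmetric(d, dppc_params, 201) for d in ds
                ]
            },
            indirect_pressure=PressureDistanceCurve(
                d=dgrid,
                pressure=np.array(
                    [indirect_pressure(x, dppc_params) for x in dgrid]
                ),
                contribution="indirect",
            ),
        )
        table = extract_parameter_table([dataset])
        col = table["dppc_like"]
        assert col["lam_Pi_ind [nm]"] == pytest.approx(0.22, rel=1e-6)
        assert col["lam_polarization [nm]"] == pytest.approx(0.22, rel=1e-6)
        assert col["h_over_a_polarization [e/nm]"] == pytest.approx(-0.273, rel=1e-6)
        assert col["a_polarization [nm/e^2]"] == pytest.approx(492.0, rel=1e-5)

    def test_empty_dataset_gives_empty_table(self):
        table = extract_parameter_table([])
        assert table.empty

    def test_missing_stage_reported_not_fatal(self, dppc_params):
        dataset = SystemDataset(
            label="partial",
            profiles={
                "polarization": [profile_antisymmetric(1.2, dppc_params, 201)]
            },
        )
        table = extract_parameter_table([dataset])
        assert "lam_polarization [nm]" in table.index
        assert any("partial" in m for m in table.attrs["messages"])
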