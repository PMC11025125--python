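"""Closed-form Landau-Ginzburg solutions against the discrete
functional minimizer, thermodynamic consistency, and the sign laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrep import (
    LGParameters,
    ValidationError,
    free_energy_per_area,
    indirect_pressure,
    minimize_functional,
    pressure_from_minimizer,
    profile_antisymmetric,
    profile_closed_form,
    surface_value,
    symmetric_variant_pressure,
)
from hydrep.errors import ConvergenceError


def params(a=492.0, lam=0.22, h_over_a=-0.273, **kw) -> LGParameters:
    return LGParameters.from_correlation_length(a=a, lam=lam, h_over_a=h_over_a, **kw)


class TestParameters:
    def test_triple_conversion_is_exact(self):
        p = params(a=492.0, lam=0.22, h_over_a=-0.273)
        assert p.b == 492.0 * 0.22**2
        assert p.h == -0.273 * 492.0
        assert p.lam == pytest.approx(0.22, rel=1e-14)
        assert p.h_over_a == pytest.approx(-0.273, rel=1e-14)

    def test_correlation_length_squared_equals_b_over_a(self):
        p = params()
        assert p.lam**2 == pytest.approx(p.b / p.a, rel=1e-14)

    @pytest.mark.parametrize("bad", [dict(a=-1.0), dict(a=0.0), dict(lam=-0.2)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValidationError):
            params(**{**dict(a=492.0, lam=0.22), **bad})

    def test_fixed_order_parameter_requires_surface_value(self):
        with pytest.raises(ValidationError):
            LGParameters(a=1.0, b=1.0, bc_kind="fixed_order_parameter")

    def test_antisymmetric_surface_fields_are_opposite(self):
        p = params()
        assert p.h_plus == -p.h_minus


class TestClosedForms:
    @given(
        d=st.floats(0.2, 5.0),
        lam=st.floats(0.05, 0.6),
        h_over_a=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_profile_antisymmetry_and_midpoint_zero(self, d, lam, h_over_a):
        prof = profile_antisymmetric(d, params(lam=lam, h_over_a=h_over_a), 101)
        assert prof.values[50] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(prof.values, -prof.values[::-1], atol=1e-12)

    def test_zero_field_gives_zero_profile_energy_pressure(self):
        p = params(h_over_a=0.0)
        assert np.all(profile_antisymmetric(1.0, p).values == 0.0)
        assert free_energy_per_area(1.0, p).f_per_area == 0.0
        assert indirect_pressure(1.0, p) == 0.0
        assert symmetric_variant_pressure(1.0, p.with_(symmetry="symmetric")) == 0.0

    def test_surface_value_monotonic_and_saturates(self):
        p = params()
        ds = np.linspace(0.05, 4.0, 60)
        ms = np.array([surface_value(d, p) for d in ds])
        assert np.all(np.diff(np.abs(ms)) > 0)
        # large-d limit (h/a)/lambda, Table-1 liquid-DPPC inputs
        assert surface_value(50.0, p) == pytest.approx(-0.273 / 0.22, rel=1e-12)
        assert surface_value(50.0, p) == pytest.approx(-1.2409, abs=1e-4)

    def test_surface_value_vanishes_at_contact(self):
        assert surface_value(1e-6, params()) == pytest.approx(0.0, abs=1e-5)

    def test_amplitude_combination_h2_over_b(self, dppc_params):
        # (h/a)^2 a / lam^2 for the liquid-DPPC parameters
        assert dppc_params.h**2 / dppc_params.b == pytest.approx(757.6, abs=0.1)

    def test_nonpositive_separation_rejected(self):
        for fn in (profile_antisymmetric, surface_value, free_energy_per_area,
                   indirect_pressure):
            with pytest.raises(ValidationError):
                fn(-1.0, params())

    def test_pressure_quadratic_in_h(self):
        p1 = params(h_over_a=-0.1)
        p2 = params(h_over_a=-0.2)
        for d in (0.4, 1.0, 2.5):
            assert indirect_pressure(d, p2) == pytest.approx(
                4.0 * indirect_pressure(d, p1), rel=1e-12
            )


class TestOracleAgreement:
    """Closed forms against the independent discrete minimizer."""

    @pytest.mark.parametrize("d_over_lam", [0.5, 2.0, 5.0, 10.0])
    @pytest.mark.parametrize("h_over_a", [-0.273, -0.011, 0.15])
    def test_profile_matches_discrete_minimizer(self, d_over_lam, h_over_a):
        p = params(h_over_a=h_over_a)
        d = d_over_lam * p.lam
        n = 801
        closed = profile_antisymmetric(d, p, n)
        numeric, _ = minimize_functional(d, p, n)
        scale = np.max(np.abs(closed.values))
        assert scale > 0
        np.testing.assert_allclose(
            numeric.values, closed.values, atol=1e-4 * scale
        )

    @pytest.mark.parametrize("d_over_lam", [0.5, 2.0, 5.0, 10.0])
    def test_free_energy_matches_minimizer(self, d_over_lam):
        p = params()
        d = d_over_lam * p.lam
        _, coarse = minimize_functional(d, p, 1601)
        _, fine = minimize_functional(d, p, 3201)
        converged = (4.0 * fine.f_per_area - coarse.f_per_area) / 3.0
        assert converged == pytest.approx(
            free_energy_per_area(d, p).f_per_area, rel=1e-6
        )

    def test_grid_refinement_is_second_order(self):
        p = params()
        d = 1.0
        exact = free_energy_per_area(d, p).f_per_area
        errs = [abs(minimize_functional(d, p, n)[1].f_per_area - exact)
                for n in (101, 201, 401)]
        # doubling the grid should quarter the error (ratio ~4)
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.15)

    def test_minimizer_rejects_bad_grid(self):
        with pytest.raises(ValidationError):
            minimize_functional(1.0, params(), n_grid=2)

    def test_unreachable_tolerance_raises_with_diagnostics(self):
        with pytest.raises(ConvergenceError, match="residual"):
            minimize_functional(1.0, params(), 101, residual_tol=1e-30)


class TestThermodynamicConsistency:
    @pytest.mark.parametrize("d", [0.3, 0.7, 1.5, 3.0])
    def test_pressure_is_minus_dF_dd(self, d, dppc_params):
        delta = 1e-5
        fd = -(
            free_energy_per_area(d + delta, dppc_params).f_per_area
            - free_energy_per_area(d - delta, dppc_params).f_per_area
        ) / (2 * delta)
        assert indirect_pressure(d, dppc_params) == pytest.approx(fd, rel=1e-4)

    def test_pressure_matches_minimizer_derivative(self, dppc_params):
        d = 0.9
        assert pressure_from_minimizer(d, dppc_params, 3201) == pytest.approx(
            indirect_pressure(d, dppc_params), rel=1e-4
        )

    def test_pressure_vanishes_at_large_separation(self, dppc_params):
        assert indirect_pressure(40 * dppc_params.lam, dppc_params) < 1e-12


class TestSignLaws:
    def test_antisymmetric_fixed_field_is_repulsive_decreasing(self, dppc_params):
        ds = np.linspace(0.1, 3.0, 40)
        pis = np.array([indirect_pressure(d, dppc_params) for d in ds])
        assert np.all(pis > 0)
        assert np.all(np.diff(pis) < 0)

    def test_symmetric_fixed_field_is_attractive(self, dppc_params):
        for d in (0.3, 1.0, 2.5):
            assert symmetric_variant_pressure(
                d, dppc_params.with_(symmetry="symmetric")
            ) < 0

    def test_symmetric_pressure_decays_with_same_lambda(self, dppc_params):
        # |Pi_sym| tail slope equals -1/lambda, checked via the minimizer
        psym = dppc_params.with_(symmetry="symmetric")
        ds = np.linspace(5 * psym.lam, 8 * psym.lam, 6)
        mag = [abs(pressure_from_minimizer(d, psym, 1601)) for d in ds]
        slope = np.polyfit(ds, np.log(mag), 1)[0]
        assert -1.0 / slope == pytest.approx(psym.lam, rel=1e-2)

    def test_bc_switch_at_matched_surface_amplitude_flips_sign(self, dppc_params):
        """The Marcelja-Radic-style fixed surface value (antisymmetric
        data) is repulsive; transplanting the same-sign boundary data to
        a fixed surface field yields the symmetric profile and an
        attractive pressure at the matched surface amplitude."""
        d, m0 = 1.0, 0.5
        fixed_m = dppc_params.with_(
            bc_kind="fixed_order_parameter", m_surface=m0
        )
        pi_fixed_m = indirect_pressure(d, fixed_m)
        assert pi_fixed_m > 0
        # fixed field with the same amplitude on both walls -> cosh profile
        h_match = m0 * dppc_params.a * dppc_params.lam * math.tanh(
            0.5 * d / dppc_params.lam
        )
        sym_field = LGParameters(
            a=dppc_params.a, b=dppc_params.b, h=h_match, symmetry="symmetric"
        )
        assert surface_value(d, sym_field) == pytest.approx(m0, rel=1e-12)
        assert indirect_pressure(d, sym_field) < 0

    def test_fixed_order_parameter_closed_forms_match_minimizer(self, dppc_params):
        for symmetry in ("antisymmetric", "symmetric"):
            p = dppc_params.with_(
                bc_kind="fixed_order_parameter", m_surface=0.4, symmetry=symmetry
            )
            assert pressure_from_minimizer(1.0, p, 3201) == pytest.approx(
                indirect_pressure(1.0, p), rel=1e-3
            )

    def test_midplane_stress_sets_the_sign(self, dppc_params):
        """First integral: beta Pi = (b/2) m'(0)^2 - (a/2) m(0)^2, so the
        profile symmetry class alone fixes the sign of the pressure."""
        d = 1.0
        for symmetry, sign in (("antisymmetric", 1.0), ("symmetric", -1.0)):
            p = dppc_params.with_(symmetry=symmetry)
            prof = profile_closed_form(d, p, 4001)
            i0 = 2000  # z = 0
            dz = prof.z[1] - prof.z[0]
            mprime = (prof.values[i0 + 1] - prof.values[i0 - 1]) / (2 * dz)
            stress = 0.5 * p.b * mprime**2 - 0.5 * p.a * prof.values[i0] ** 2
            assert stress == pytest.approx(indirect_pressure(d, p), rel=1e-4)
            assert math.copysign(1.0, stress) == sign


class TestExponentialTail:
    def test_log_pressure_slope_recovers_lambda(self, dppc_params):
        lam = dppc_params.lam
        ds = np.linspace(5 * lam, 10 * lam, 20)
        logs = np.log([indirect_pressure(d, dppc_params) for d in ds])
        slope = np.polyfit(ds, logs, 1)[0]
        assert -1.0 / slope == pytest.approx(lam, rel=5e-3)
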