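"""Logistic mass trajectories and sap-flux schedules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from tritrace.growth import (
    GrowthParams,
    WheatPart,
    default_time_grid,
    flux_series,
    logistic_mass,
    mass_series,
)


def ode_mass(params: GrowthParams, t_eval: np.ndarray) -> np.ndarray:
    """Independent oracle: integrate dM/dt = G M (1 - M/Mmax) numerically."""
    sol = solve_ivp(
        lambda t, m: params.g * m * (1.0 - m / params.mmax),
        (0.0, float(t_eval[-1])),
        [params.m0],
        t_eval=t_eval,
        rtol=1e-10,
        atol=1e-16,
        method="RK45",
    )
    return sol.y[0]


class TestLogisticMass:
    def test_initial_mass_at_emergence(self, growth_defaults):
        grain = growth_defaults[WheatPart.GRAIN]
        assert logistic_mass(grain, grain.emergence_day) == pytest.approx(5.6e-6, rel=1e-12)

    def test_asymptote_is_mmax(self, growth_defaults):
        for p in growth_defaults.values():
            assert logistic_mass(p, 1e6) == pytest.approx(p.mmax, rel=1e-9)

    def test_zero_before_emergence(self, growth_defaults):
        grain = growth_defaults[WheatPart.GRAIN]
        assert logistic_mass(grain, 49.9) == 0.0
        assert logistic_mass(grain, 0.0) == 0.0

    def test_grain_inflection_closed_form(self, growth_defaults):
        """Half-maximum occurs at ln((Mmax-M0)/M0)/G after emergence (~82.24 d)."""
        grain = growth_defaults[WheatPart.GRAIN]
        t_half = math.log((grain.mmax - grain.m0) / grain.m0) / grain.g
        assert t_half == pytest.approx(82.24, abs=0.01)
        m = logistic_mass(grain, grain.emergence_day + t_half)
        assert m == pytest.approx(grain.mmax / 2, rel=1e-12)
        # cross-check by bisection on the formula itself
        lo, hi = 0.0, 1000.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if logistic_mass(grain, grain.emergence_day + mid) < grain.mmax / 2:
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(t_half, abs=1e-9)

    def test_matches_ode_oracle_all_parts(self, growth_defaults):
        """Closed form vs numerical ODE integration, rel err < 1e-6 on [0, 160]."""
        t = np.linspace(0.0, 160.0, 321)
        for part, p in growth_defaults.items():
            if p.emergence_day > 0:
                tau = t[t >= p.emergence_day] - p.emergence_day
            else:
                tau = t
            expected = ode_mass(p, tau)
            got = np.asarray(
                logistic_mass(p, tau + p.emergence_day)
            )
            assert np.max(np.abs(got - expected) / expected) < 1e-6, part

    def test_stem_fraction_at_90d(self, growth_defaults):
        """Plug-in value: stem reaches ~79% of its maximum at 90 d."""
        stem = growth_defaults[WheatPart.STEM]
        assert logistic_mass(stem, 90.0) / stem.mmax == pytest.approx(0.789, abs=0.005)

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            GrowthParams(WheatPart.ROOT, m0=0.5, mmax=0.25, g=0.1)
        with pytest.raises(ValueError):
            GrowthParams(WheatPart.ROOT, m0=0.01, mmax=0.25, g=-1.0)
        with pytest.raises(ValueError):
            logistic_mass(GrowthParams(WheatPart.ROOT, 0.01, 0.25, 0.1), float("nan"))

    @given(
        st.floats(min_value=0.01, max_value=0.2),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_transformed_symmetry(self, g, frac):
        """ln(M/(Mmax-M)) is antisymmetric about the inflection time."""
        p = GrowthParams(WheatPart.STEM, 1e-3, 0.45, g)
        t_inf = p.inflection_day
        d = frac * 0.99 * t_inf

        def z(t):
            m = logistic_mass(p, t)
            return math.log(m / (p.mmax - m))

        assert z(t_inf + d) + z(t_inf - d) == pytest.approx(0.0, abs=1e-8)


class TestMassSeries:
    def test_grain_emerges_at_50d(self, growth_defaults):
        series = mass_series(growth_defaults, default_time_grid())
        grain = series.mass[WheatPart.GRAIN]
        assert np.all(grain[series.t < 50.0] == 0.0)
        assert np.all(grain[series.t >= 50.0] > 0.0)

    def test_invariants(self, growth_defaults):
        series = mass_series(growth_defaults)
        for part, m in series.mass.items():
            assert np.all(m >= 0.0)
            assert np.all(np.diff(m) >= 0.0)
            assert np.all(m <= series.params[part].mmax)

    def test_single_point_grid(self, growth_defaults):
        root = growth_defaults[WheatPart.ROOT]
        series = mass_series([root], np.array([0.0]))
        assert series.mass[WheatPart.ROOT][0] == pytest.approx(root.m0)

    def test_rejects_bad_grids_and_duplicates(self, growth_defaults):
        root = growth_defaults[WheatPart.ROOT]
        with pytest.raises(ValueError):
            mass_series([], default_time_grid())
        with pytest.raises(ValueError):
            mass_series([root, root])
        with pytest.raises(ValueError):
            mass_series([root], np.array([1.0, 2.0]))  # must start at 0
        with pytest.raises(ValueError):
            mass_series([root], np.array([0.0, 2.0, 1.0]))


class TestFluxSeries:
    def test_zero_coefficient_zero_flux(self, growth_defaults):
        series = flux_series(mass_series(growth_defaults), 0.0, 0.5)
        for part in series.parts:
            assert np.all(series.q_up[part] == 0.0)
            assert np.all(series.q_down[part] == 0.0)

    def test_direct_product(self, growth_defaults):
        series = flux_series(mass_series(growth_defaults), 1.0, 0.5)
        for part in series.parts:
            np.testing.assert_allclose(series.q_up[part], series.mass[part])
            np.testing.assert_allclose(series.q_down[part], 0.5 * series.mass[part])

    def test_phloem_never_exceeds_xylem(self, growth_defaults):
        series = flux_series(mass_series(growth_defaults), 2.0, 0.9)
        for part in series.parts:
            assert np.all(series.q_down[part] <= series.q_up[part])

    def test_root_flux_exceeds_grain_flux_at_60d(self, growth_defaults):
        series = flux_series(mass_series(growth_defaults), 1.0, 0.4)
        i = int(np.searchsorted(series.t, 60.0))
        assert series.q_up[WheatPart.ROOT][i] > series.q_up[WheatPart.GRAIN][i]

    def test_rejects_phloem_fraction_ge_one(self, growth_defaults):
        with pytest.raises(ValueError):
            flux_series(mass_series(growth_defaults), 1.0, 1.0)
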