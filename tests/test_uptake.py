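"""Elementary and composed transfer rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tritrace.growth import WheatPart, default_time_grid, flux_series, mass_series
from tritrace.uptake import (
    AtmosphereParams,
    MetalEnvironment,
    PartGeometry,
    PreEmergenceError,
    RootTransportParams,
    atmos_rate,
    build_rate_set,
    compose_pathway,
    root_uptake_rate,
    transfer_rate,
)


def make_env(**over):
    defaults = dict(
        metal="Cu",
        c_total_soil=22.1,
        c_soluble=0.05,
        c_exchangeable=0.15,
        c_atmosphere=1e-6,
        soil_mass=200.0,
        k_sw=20.0,
    )
    defaults.update(over)
    return MetalEnvironment(**defaults)


class TestTransferRate:
    def test_zero_flux(self):
        assert transfer_rate(0.0, 4.0, 0.5) == 0.0

    @pytest.mark.parametrize(
        "q, k, m, expected",
        [(2.0, 4.0, 0.5, 1.0), (0.35, 7.0, 0.1, 0.5)],
    )
    def test_direct_quotient(self, q, k, m, expected):
        assert transfer_rate(q, k, m) == pytest.approx(expected, rel=1e-12)

    def test_pre_emergence_mass_raises(self):
        with pytest.raises(PreEmergenceError):
            transfer_rate(1.0, 4.0, 0.0)


class TestRootUptakeRate:
    def test_zero_pathways(self):
        rt = RootTransportParams(q=0.0, f_c=1000.0, d_r=0.0)
        assert root_uptake_rate(rt, 0.5, make_env()) == 0.0

    def test_single_term(self):
        rt = RootTransportParams(q=1.0, f_c=1000.0, d_r=0.0)
        env = make_env(soil_mass=10.0, k_sw=0.1)
        assert root_uptake_rate(rt, 0.0, env) == pytest.approx(1.0, rel=1e-12)

    def test_hand_evaluation(self):
        rt = RootTransportParams(q=1.0, f_c=1000.0, d_r=1e-3)
        env = make_env(soil_mass=100.0, k_sw=2.0)
        assert root_uptake_rate(rt, 0.5, env) == pytest.approx(7.5e-3, rel=1e-12)

    @given(st.floats(0, 10), st.floats(0, 1e-2))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_additivity_of_pathways(self, q, d_r):
        """The two entry pathways are exactly additive."""
        env = make_env()
        both = root_uptake_rate(RootTransportParams(q, 1000.0, d_r), 0.5, env)
        flow = root_uptake_rate(RootTransportParams(q, 1000.0, 0.0), 0.5, env)
        diff = root_uptake_rate(RootTransportParams(0.0, 1000.0, d_r), 0.5, env)
        assert both == pytest.approx(flow + diff, rel=1e-12, abs=1e-18)


class TestAtmosRate:
    def test_zero_area(self):
        assert atmos_rate(0.0, 0.5, AtmosphereParams(0.3, 1.0)) == 0.0

    def test_pure_metabolic_limit(self):
        assert atmos_rate(2.0, 0.1, AtmosphereParams(0.0, 5.0)) == pytest.approx(0.2)

    def test_pure_deposition_limit(self):
        assert atmos_rate(2.0, 0.1, AtmosphereParams(1.0, 5.0)) == pytest.approx(10.0)

    def test_hand_evaluation(self):
        assert atmos_rate(2.0, 0.1, AtmosphereParams(0.4, 0.5)) == pytest.approx(0.52, rel=1e-12)

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            AtmosphereParams(1.2, 1.0)


class TestComposePathway:
    def test_single_stage_identity(self):
        assert compose_pathway([0.37]) == pytest.approx(0.37)

    def test_two_stage_product(self):
        assert compose_pathway([0.1, 0.5], tau=1.0) == pytest.approx(0.05)

    def test_three_deep_product(self):
        assert compose_pathway([0.2, 0.2, 0.2], tau=1.0) == pytest.approx(0.008, rel=1e-12)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            compose_pathway([])

    @given(
        st.lists(st.floats(0.0, 2.0), min_size=1, max_size=5),
        st.integers(0, 4),
        st.floats(0.0, 1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_monotone_in_each_stage(self, chain, idx, bump):
        """Raising any stage never lowers the composed rate."""
        idx = idx % len(chain)
        bumped = list(chain)
        bumped[idx] += bump
        assert compose_pathway(bumped) >= compose_pathway(chain)


@pytest.fixture
def series(growth_defaults):
    return flux_series(mass_series(growth_defaults, default_time_grid()), 1.0, 0.4)


@pytest.fixture
def geometry():
    return {
        WheatPart.ROOT: PartGeometry(WheatPart.ROOT, 2.0, 0.8, 30.0),
        WheatPart.STEM: PartGeometry(WheatPart.STEM, 0.05, 0.6, 15.0),
        WheatPart.LEAF: PartGeometry(WheatPart.LEAF, 0.2, 0.75, 20.0, permeability=1e-4),
        WheatPart.GRAIN: PartGeometry(WheatPart.GRAIN, 1e-3, 0.12, 10.0, permeability=1e-5),
    }


class TestBuildRateSet:
    def test_all_zero_inputs_give_zero_rates(self, growth_defaults, geometry):
        dead = flux_series(mass_series(growth_defaults, default_time_grid()), 0.0, 0.0)
        geom0 = {
            p: PartGeometry(p, 0.0, g.water_content, g.k_iw,
                            0.0 if g.permeability is not None else None)
            for p, g in geometry.items()
        }
        rates = build_rate_set(
            geom0,
            make_env(),
            RootTransportParams(0.0, 1000.0, 0.0),
            AtmosphereParams(0.5, 0.0),
            dead,
            100.0,
        )
        assert all(r == 0.0 for r in rates.elementary.values())
        assert all(r == 0.0 for r in rates.loss.values())

    def test_composed_root_equals_elementary_soil_edge(self, series, geometry):
        rates = build_rate_set(
            geometry, make_env(), RootTransportParams(5.0, 1000.0, 1e-6),
            AtmosphereParams(0.5, 10.0), series, 100.0,
        )
        assert rates.composed_soil[WheatPart.ROOT] == rates.elementary["S->R"]

    def test_grain_loss_rate_is_zero(self, series, geometry):
        rates = build_rate_set(
            geometry, make_env(), RootTransportParams(5.0, 1000.0, 1e-6),
            AtmosphereParams(0.5, 10.0), series, 100.0,
        )
        assert rates.loss[WheatPart.GRAIN] == 0.0

    def test_all_rates_nonnegative(self, series, geometry):
        for t in (0.0, 30.0, 60.0, 160.0):
            rates = build_rate_set(
                geometry, make_env(), RootTransportParams(5.0, 1000.0, 1e-6),
                AtmosphereParams(0.5, 10.0), series, t,
            )
            assert all(r >= 0.0 for r in rates.elementary.values())
            assert all(r >= 0.0 for r in rates.composed_soil.values())
            assert all(r >= 0.0 for r in rates.composed_atmos.values())

    def test_grain_edges_before_emergence(self, series, geometry):
        rates = build_rate_set(
            geometry, make_env(), RootTransportParams(5.0, 1000.0, 1e-6),
            AtmosphereParams(0.5, 10.0), series, 30.0,
        )
        assert not rates.grain_emerged
        with pytest.raises(PreEmergenceError):
            rates.edge("St->G")
        with pytest.raises(PreEmergenceError):
            rates.edge("A->G")

    def test_loss_rates_sum_outgoing_edges(self, series, geometry):
        rates = build_rate_set(
            geometry, make_env(), RootTransportParams(5.0, 1000.0, 1e-6),
            AtmosphereParams(0.5, 10.0), series, 120.0,
        )
        e = rates.elementary
        assert rates.loss[WheatPart.ROOT] == pytest.approx(e["R->St"])
        assert rates.loss[WheatPart.STEM] == pytest.approx(
            e["St->L"] + e["St->G"] + e["St->R"]
        )
        assert rates.loss[WheatPart.LEAF] == pytest.approx(e["L->St"])

    def test_time_outside_grid_rejected(self, series, geometry):
        with pytest.raises(ValueError):
            build_rate_set(
                geometry, make_env(), RootTransportParams(5.0, 1000.0, 1e-6),
                AtmosphereParams(0.5, 10.0), series, 1e4,
            )
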