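"""Unit and property tests for the two-layer sediment diagenesis model."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedcarb import (
    DiagenesisParams,
    LayerGeometry,
    SedimentState,
    ch4_resuspension_flux,
    ch4_transport_capacity,
    inorganic_release,
    methane_partition,
    partition_deposition,
    poc_burial_flux,
    poc_mineralization_flux,
    poc_resuspension_flux,
    step_aerobic_ch4,
    step_anaerobic,
    step_sediment,
)
from sedcarb.diagenesis import DiagenesisFluxes

PARAMS = DiagenesisParams()
GEOM = LayerGeometry()


class TestPartitionDeposition:
    @pytest.mark.parametrize(
        "j_total, fractions, expected",
        [
            (0.0, (0.65, 0.20, 0.15), (0.0, 0.0, 0.0)),
            (2.5, (1.0, 0.0, 0.0), (2.5, 0.0, 0.0)),
            (1.0, (0.65, 0.20, 0.15), (0.65, 0.20, 0.15)),
        ],
    )
    def test_split(self, j_total, fractions, expected):
        p = DiagenesisParams(f_g1=fractions[0], f_g2=fractions[1], f_g3=fractions[2])
        got = partition_deposition(j_total, p)
        assert got == pytest.approx(expected)
        assert sum(got) == pytest.approx(j_total)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            partition_deposition(-1.0, PARAMS)


class TestResuspensionFlux:
    @pytest.mark.parametrize(
        "conc, rho, j_sed_r, expected",
        [
            (0.0, 1.0, 1e6, 0.0),
            (1000.0, 1.0, 1000.0, 1.0),  # conc/(rho*1e6) * flux
            (10.0, 1.0, 1e5, 1.0),
        ],
    )
    def test_hand_values(self, conc, rho, j_sed_r, expected):
        assert poc_resuspension_flux(conc, rho, j_sed_r) == pytest.approx(expected)
        assert ch4_resuspension_flux(conc, rho, j_sed_r) == pytest.approx(expected)

    def test_mass_limiter(self):
        # raw request vastly exceeds the pool: capped at available/dt
        assert poc_resuspension_flux(1000.0, 1.0, 1e9, available_mass=100.0, dt=1.0) == 100.0
        assert ch4_resuspension_flux(1000.0, 1.0, 1e9, available_mass=7.0, dt=1.0) == 7.0

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            poc_resuspension_flux(1.0, 0.0, 1.0)


class TestMineralizationAndBurial:
    def test_hand_value_at_reference_temperature(self):
        # theta exponent vanishes at 20 degC: k * poc * H2
        assert poc_mineralization_flux(100.0, 0.035, 1.1, 20.0, 0.1) == pytest.approx(0.35)

    def test_zero_pool(self):
        assert poc_mineralization_flux(0.0, 0.035, 1.1, 25.0, 0.1) == 0.0

    def test_g3_never_mineralizes(self):
        assert poc_mineralization_flux(1e6, 10.0, 2.0, 35.0, 0.1, pool=3) == 0.0

    def test_temperature_correction(self):
        cold = poc_mineralization_flux(100.0, 0.035, 1.1, 10.0, 0.1)
        warm = poc_mineralization_flux(100.0, 0.035, 1.1, 30.0, 0.1)
        assert warm / cold == pytest.approx(1.1**20)

    @pytest.mark.parametrize(
        "poc, w, expected",
        [(0.0, 6.85e-6, 0.0), (1000.0, 6.85e-6, 6.85e-3), (123.0, 0.0, 0.0)],
    )
    def test_burial(self, poc, w, expected):
        assert poc_burial_flux(poc, w) == pytest.approx(expected)


class TestStepAnaerobic:
    def test_zero_in_zero_out(self):
        pools, flx = step_anaerobic(SedimentState(), (0, 0, 0), 0.0, 20.0, PARAMS)
        assert pools == (0.0, 0.0, 0.0)
        assert flx.j_c == 0.0 and sum(flx.j_poc_res) == 0.0

    def test_g1_steady_state_matches_closed_form(self):
        """Constant G1 deposition drives the pool to J/(k*H2 + w_bury)."""
        j_dep = 0.1
        expected = j_dep / (PARAMS.k_g1 * GEOM.h2 + PARAMS.w_bury)  # ~28.52
        state = SedimentState()
        for _ in range(3000):
            pools, _ = step_anaerobic(state, (j_dep, 0, 0), 0.0, 20.0, PARAMS)
            state = SedimentState(*pools, 0.0)
        assert state.poc_g1 == pytest.approx(expected, rel=1e-6)
        assert state.poc_g1 == pytest.approx(28.52, rel=0.01)

    def test_g3_exact_euler_accumulation(self):
        """With burial off and no resuspension, G3 integrates deposition exactly."""
        p = DiagenesisParams(w_bury=0.0)
        state = SedimentState()
        for _ in range(10):
            pools, _ = step_anaerobic(state, (0, 0, 0.15), 0.0, 20.0, p)
            state = SedimentState(*pools, 0.0)
        assert state.poc_g3 == pytest.approx(0.15 * 10 / GEOM.h2)  # 15 gC/m3

    def test_g3_sinks_only_burial_and_resuspension(self):
        state = SedimentState(poc_g3=50.0)
        _, flx = step_anaerobic(state, (0, 0, 0), 500.0, 25.0, PARAMS)
        assert flx.j_poc_min[2] == 0.0
        assert flx.j_poc_res[2] > 0.0 and flx.j_poc_bury[2] > 0.0

    def test_dt_positive_required(self):
        with pytest.raises(ValueError):
            step_anaerobic(SedimentState(), (0, 0, 0), 0.0, 20.0, PARAMS, dt=0.0)


class TestMethanePartition:
    @pytest.mark.parametrize(
        "j_c, j_den, cap, expected",
        [
            (0.0, 0.0, 1.0, (0.0, 0.0)),
            (0.35, 0.0, 1.0, (0.35, 0.0)),
            (0.35, 0.05, 0.10, (0.10, 0.20)),
        ],
    )
    def test_split(self, j_c, j_den, cap, expected):
        got = methane_partition(j_c, j_den, cap)
        assert got == pytest.approx(expected)
        assert sum(got) == pytest.approx(j_c - j_den)

    def test_denitrification_cannot_exceed_supply(self):
        with pytest.raises(ValueError):
            methane_partition(0.1, 0.2, 1.0)

    def test_capacity_falls_with_warming(self):
        assert ch4_transport_capacity(30.0, PARAMS) < ch4_transport_capacity(10.0, PARAMS)


class TestStepAerobicCh4:
    def test_all_zero(self):
        assert step_aerobic_ch4(0.0, 0.0, 0.0, 20.0, PARAMS) == (0.0, 0.0, 0.0, 0.0)

    def test_single_sink_steady_state_passes_everything_through(self):
        p = DiagenesisParams(k_ch4_ox=0.0)
        ch4, j_w = 0.0, 0.0
        for _ in range(2000):
            ch4, j_w, _, _ = step_aerobic_ch4(ch4, 0.2, 0.0, 20.0, p)
        assert j_w == pytest.approx(0.2, rel=1e-9)

    def test_diffusion_oxidation_steady_ratio(self):
        """At steady state j_w/j_o = v_diff / (k_ox * theta^(T-20) * H1)."""
        p = DiagenesisParams(k_ch4_ox=5.0, v_diff=0.05)
        temp = 25.0
        ch4 = 0.0
        for _ in range(3000):
            ch4, j_w, _, j_o = step_aerobic_ch4(ch4, 0.3, 0.0, temp, p)
        expected = p.v_diff / (p.k_ch4_ox * p.theta_ch4_ox ** (temp - 20.0) * GEOM.h1)
        assert j_w / j_o == pytest.approx(expected, rel=1e-9)


class TestInorganicRelease:
    def test_definitional_sum(self):
        flx = DiagenesisFluxes(j_ch4_w=0.1, j_ch4_gas=0.2, j_ch4_o=0.05)
        assert inorganic_release(flx) == pytest.approx(0.35)

    def test_zero(self):
        assert inorganic_release(DiagenesisFluxes()) == 0.0

    def test_equals_diagenesis_minus_storage_identity(self):
        """Inorganic release = j_c - j_c_den - j_ch4_r - dCH4*H1/dt each step."""
        state = SedimentState(poc_g1=40.0, poc_g2=20.0, poc_g3=10.0, ch4=0.5)
        new, flx = step_sediment(state, 0.8, 300.0, 24.0, PARAMS)
        d_ch4 = (new.ch4 - state.ch4) * GEOM.h1
        lhs = inorganic_release(flx)
        rhs = flx.j_c - flx.j_c_den - flx.j_ch4_r - d_ch4
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)


nonneg = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


class TestConservationProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        g1=nonneg, g2=nonneg, g3=nonneg, ch4=st.floats(0, 100),
        dep=st.floats(0, 100), sed_r=st.floats(0, 1e6),
        temp=st.floats(0.0, 35.0), den=st.floats(0, 10),
    )
    def test_whole_sediment_carbon_conservation(self, g1, g2, g3, ch4, dep, sed_r, temp, den):
        """deposition = d(storage) + resuspension + burial + inorganic + denit."""
        state = SedimentState(g1, g2, g3, ch4)
        new, flx = step_sediment(state, dep, sed_r, temp, PARAMS, j_c_den=den)
        d_storage = new.storage(GEOM) - state.storage(GEOM)
        lhs = flx.deposition_total
        rhs = (
            d_storage
            + flx.resuspension_total
            + flx.burial_total
            + inorganic_release(flx)
            + flx.j_c_den
        )
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        g1=nonneg, g2=nonneg, g3=nonneg, ch4=st.floats(0, 100),
        dep=st.floats(0, 100), sed_r=st.floats(0, 1e7), temp=st.floats(0.0, 35.0),
    )
    def test_pools_and_fluxes_stay_nonnegative(self, g1, g2, g3, ch4, dep, sed_r, temp):
        state = SedimentState(g1, g2, g3, ch4)
        new, flx = step_sediment(state, dep, sed_r, temp, PARAMS)
        assert min(new.poc_g1, new.poc_g2, new.poc_g3, new.ch4) >= 0.0
        assert min(flx.as_dict().values()) >= 0.0

    def test_no_resuspension_reduction(self):
        """j_sed_r = 0 gives identically zero resuspension fluxes and the same
        trajectory as an independent Euler integration without those terms."""
        state = SedimentState()
        dep_series = [0.5, 1.0, 0.2, 0.0, 0.8] * 20
        # independent oracle: plain Euler recurrence without resuspension
        oracle = [0.0, 0.0, 0.0]
        fr = (PARAMS.f_g1, PARAMS.f_g2, PARAMS.f_g3)
        ks = (PARAMS.k_g1, PARAMS.k_g2, 0.0)
        for dep in dep_series:
            for i in range(3):
                sink = ks[i] * oracle[i] * GEOM.h2 + PARAMS.w_bury * oracle[i]
                oracle[i] += (fr[i] * dep - sink) / GEOM.h2
            new, flx = step_sediment(state, dep, 0.0, 20.0, PARAMS)
            assert flx.j_poc_res == (0.0, 0.0, 0.0) and flx.j_ch4_r == 0.0
            state = new
        assert state.poc == pytest.approx(tuple(oracle), rel=1e-12)


class TestParamValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            DiagenesisParams(f_g1=0.5, f_g2=0.2, f_g3=0.2)

    def test_g1_must_be_more_labile_than_g2(self):
        with pytest.raises(ValueError):
            DiagenesisParams(k_g1=0.001, k_g2=0.0018)

    def test_layer_thickness_positive(self):
        with pytest.raises(ValueError):
            LayerGeometry(h1=0.0)
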