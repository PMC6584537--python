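"""Flux laws, climate/anoxia functions, and the mass/isotope balances."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ediacaran_o2.forcings import ForcingSnapshot
from ediacaran_o2.model import (
    anoxic_fraction,
    burial_and_degassing_fluxes,
    climate_state,
    compute_fluxes,
    isotope_balance,
    mass_balance,
    new_production,
    ocean_ecology_fluxes,
    present_day_forcing,
    present_day_state,
    rhs,
    weathering_fluxes,
)
from ediacaran_o2.params import ARRHENIUS_DENOM, default_parameters


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def test_climate_identity_and_solar_term(baseline_params):
    c = climate_state(1.0, 0.0, baseline_params)
    assert c.RCO2 == 1.0 and c.deltaT == 0.0
    c = climate_state(1.0, 570.0, baseline_params)
    assert c.deltaT == pytest.approx(-7.4)


def test_climate_doubling_sensitivity():
    """A CO2 doubling warms by exactly the configured sensitivity."""
    p = default_parameters(climate_sensitivity=3.0)
    a_rel = math.sqrt(2.0)  # RCO2 = a^2 = 2
    c = climate_state(a_rel, 0.0, p)
    assert c.RCO2 == pytest.approx(2.0)
    assert c.deltaT == pytest.approx(3.0)


def test_climate_rejects_nonpositive_carbon(baseline_params):
    with pytest.raises(ValueError):
        climate_state(0.0, 0.0, baseline_params)


# ---------------------------------------------------------------------------
# anoxic fraction
# ---------------------------------------------------------------------------

def test_anoxia_limits_and_midpoint(baseline_params):
    p = baseline_params
    assert anoxic_fraction(1.0, 1e6, p) < 1e-6
    # logistic midpoint: newp' = o'/k_u
    assert anoxic_fraction(1.0 / p.k_u, 1.0, p) == pytest.approx(0.5)
    # frozen hand evaluation at the reference point (k_anox=12, k_u=0.5):
    # 1 / (1 + e^6)
    assert anoxic_fraction(1.0, 1.0, p) == pytest.approx(0.0024726232, abs=1e-9)


_ANOX_PARAMS = default_parameters()


@settings(max_examples=80, deadline=None)
@given(
    newp=st.floats(0.0, 50.0, allow_nan=False),
    o=st.floats(0.0, 50.0, allow_nan=False),
    d=st.floats(1e-4, 5.0),
)
def test_anoxia_bounded_and_monotone(newp, o, d):
    p = _ANOX_PARAMS
    a = anoxic_fraction(newp, o, p)
    assert 0.0 <= a <= 1.0
    # strict openness holds wherever the logistic is resolvable in floats
    if abs(p.k_anox * (p.k_u * newp - o)) < 30.0:
        assert 0.0 < a < 1.0
    assert anoxic_fraction(newp + d, o, p) >= a
    assert anoxic_fraction(newp, o + d, p) <= a


# ---------------------------------------------------------------------------
# ecology
# ---------------------------------------------------------------------------

def test_present_day_ecology_identity(baseline_params, reference_state):
    """At the reference point every marine flux equals its constant."""
    p = baseline_params
    eco = ocean_ecology_fluxes(
        reference_state, p.anox0, present_day_forcing(), p
    )
    assert eco.mocb == pytest.approx(p.k2)
    assert eco.capb == pytest.approx(p.k7)
    assert eco.mopb == pytest.approx(p.k2 / p.CP_sea)
    assert eco.monb == pytest.approx(p.k2 / p.CN_sea)
    assert eco.fepb == pytest.approx(p.fepb0)
    assert eco.denit == pytest.approx(p.denit0)
    assert eco.nfix == pytest.approx(p.k3)
    assert eco.newp == pytest.approx(p.newp0)


def test_mocb_o2_factor_is_unity_at_present():
    """The optional O2 dependence is normalised: f(O2) = 1 at o = 1."""
    p = default_parameters(mocb_o2_dependence=True, mocb_uplift_dependence=False)
    st0 = present_day_state(p)
    eco = ocean_ecology_fluxes(st0, p.anox0, present_day_forcing(), p)
    assert eco.mocb / p.k2 == pytest.approx(1.0, abs=1e-4)


def test_nutrient_limitation_branches(baseline_params, reference_state):
    p = baseline_params
    # N in vast excess: production hits the P-limited ceiling, fixation off
    n_rich = dataclasses.replace(reference_state, N=50.0 * p.N0)
    assert new_production(n_rich, p) == pytest.approx(p.r_CP * 2.2)
    eco = ocean_ecology_fluxes(n_rich, p.anox0, present_day_forcing(), p)
    assert eco.nfix == 0.0


def test_ecology_rejects_negative_reservoirs(baseline_params, reference_state):
    bad = dataclasses.replace(reference_state, P=1.0, N=1.0, O=1.0)
    # positive but vanishing reservoirs are fine; zero is not constructible
    ocean_ecology_fluxes(bad, 0.5, present_day_forcing(), baseline_params)
    with pytest.raises(ValueError):
        dataclasses.replace(reference_state, P=-1.0)


# ---------------------------------------------------------------------------
# weathering
# ---------------------------------------------------------------------------

def test_present_day_weathering_identity(baseline_params, reference_state):
    p = baseline_params
    climate = climate_state(1.0, 0.0, p)
    wea = weathering_fluxes(reference_state, present_day_forcing(), climate, p)
    assert wea.granw == pytest.approx(p.k_granw)
    assert wea.basw == pytest.approx(p.k_basw)
    assert wea.silw == pytest.approx(p.silw0)
    assert wea.carbw == pytest.approx(p.k14)
    assert wea.oxidw == pytest.approx(p.k17)
    assert wea.pyrw == pytest.approx(p.k21)
    assert wea.gypw == pytest.approx(p.k22)
    assert wea.sfw == pytest.approx(p.k_sfw)
    # P weathering channel weights sum to one
    assert wea.phosw == pytest.approx(p.k_phosw)


def test_oxidative_weathering_power_law(baseline_params, reference_state):
    p = default_parameters(oxidw_exponent=0.5)
    climate = climate_state(1.0, 0.0, p)
    rich = dataclasses.replace(present_day_state(p), O=4.0 * p.O0)
    wea = weathering_fluxes(rich, present_day_forcing(), climate, p)
    assert wea.oxidw == pytest.approx(2.0 * p.k17)


def test_seafloor_weathering_arrhenius_oracle():
    """sfw against an independent evaluation of k_sfw*D*exp(E/(R*T0^2)*dT)
    at the mid-range activation energy and +2 degC."""
    p = default_parameters(E_sfw=70.0e3)
    st0 = present_day_state(p)
    # a_rel chosen so that deltaT = +2 at t = 0
    a_rel = math.exp(1.0 / p.k_c)  # ln RCO2 = 2/k_c
    warm = dataclasses.replace(st0, A=a_rel * p.A0)
    climate = climate_state(a_rel, 0.0, p)
    assert climate.deltaT == pytest.approx(2.0)
    wea = weathering_fluxes(warm, ForcingSnapshot(D=1.3, V=1.0), climate, p)
    expected = 1.75e12 * 1.3 * math.exp(2.0 * 70.0e3 / ARRHENIUS_DENOM)
    assert wea.sfw == pytest.approx(expected)


def test_preplant_biota_factor(baseline_params, reference_state):
    """With vegetation off, weathering at present-day climate drops to the
    pre-plant fraction k15."""
    p = baseline_params
    climate = climate_state(1.0, 0.0, p)
    veg_off = ForcingSnapshot(D=1.0, U=1.0, V=0.0)
    wea = weathering_fluxes(reference_state, veg_off, climate, p)
    assert wea.granw == pytest.approx(p.k15_preplant * p.k_granw)
    assert wea.carbw == pytest.approx(p.k15_preplant * p.k14)


# ---------------------------------------------------------------------------
# burial and degassing
# ---------------------------------------------------------------------------

def test_present_day_burial_identity(baseline_params, reference_state):
    p = baseline_params
    fx, _, _ = compute_fluxes(0.0, reference_state, present_day_forcing(), p)
    assert fx.mpsb == pytest.approx(p.k_mpsb)
    assert fx.mgsb == pytest.approx(p.k_mgsb)
    assert fx.ocdeg == pytest.approx(p.k13)
    assert fx.ccdeg == pytest.approx(p.k12)
    assert fx.pyrdeg == pytest.approx(p.k_pyrdeg)
    assert fx.gypdeg == pytest.approx(p.k_gypdeg)
    assert fx.rgf == pytest.approx(p.k_rgf)
    assert fx.locb == pytest.approx(p.k5)
    assert fx.mccb == pytest.approx(p.mccb0)


def test_degassing_linear_in_D(baseline_params, reference_state):
    p = baseline_params
    f1 = compute_fluxes(0.0, reference_state, present_day_forcing(), p)[0]
    doubled = ForcingSnapshot(D=2.0, U=1.0, V=1.0)
    f2 = compute_fluxes(0.0, reference_state, doubled, p)[0]
    for name in ("ocdeg", "ccdeg", "pyrdeg", "gypdeg", "rgf"):
        assert getattr(f2, name) == pytest.approx(2.0 * getattr(f1, name))


def test_pyrite_burial_scales_with_sulphate_oxygen_ratio(
    baseline_params, reference_state
):
    """s/o = 2 with unit relative organic burial doubles pyrite burial."""
    p = baseline_params
    state = dataclasses.replace(reference_state, S=2.0 * p.S0)
    eco = ocean_ecology_fluxes(state, p.anox0, present_day_forcing(), p)
    climate = climate_state(1.0, 0.0, p)
    wea = weathering_fluxes(state, present_day_forcing(), climate, p)
    bur = burial_and_degassing_fluxes(
        state, present_day_forcing(), eco, wea, p
    )
    assert bur.mpsb == pytest.approx(2.0 * p.k_mpsb * (eco.mocb / p.k2))


def test_vegetation_off_kills_land_fluxes(baseline_params, reference_state):
    p = baseline_params
    fx, _, _ = compute_fluxes(
        635.0, reference_state, ForcingSnapshot(D=1.0, U=1.0, V=0.0), p
    )
    assert fx.pland == 0.0
    assert fx.locb == 0.0
    assert fx.psea == pytest.approx(fx.phosw)


def test_carbonate_burial_identity_holds(baseline_params, reference_state, rng):
    """mccb = silw + carbw + mpsb - pyrw - pyrdeg at random states."""
    p = baseline_params
    for _ in range(20):
        mult = rng.uniform(0.3, 3.0, size=5)
        state = dataclasses.replace(
            reference_state, P=mult[0] * p.P0, N=mult[1] * p.N0,
            O=mult[2] * p.O0, A=mult[3] * p.A0, S=mult[4] * p.S0,
        )
        snap = ForcingSnapshot(
            D=rng.uniform(0.5, 2), U=rng.uniform(0.5, 2), V=0.0
        )
        fx, _, _ = compute_fluxes(600.0, state, snap, p)
        expected = fx.silw + fx.carbw + fx.mpsb - fx.pyrw - fx.pyrdeg
        assert fx.mccb == pytest.approx(max(0.0, expected))
        assert all(
            getattr(fx, n) >= 0.0
            for n in ("mocb", "mccb", "mpsb", "mgsb", "phosw", "oxidw")
        )


# ---------------------------------------------------------------------------
# mass balance
# ---------------------------------------------------------------------------

def _zero_fluxes(fx):
    return dataclasses.replace(
        fx, **{f.name: 0.0 for f in dataclasses.fields(fx)
               if f.name != "mccb_clamped"}
    )


def test_zero_fluxes_zero_derivatives(baseline_params, reference_state):
    fx, _, _ = compute_fluxes(
        0.0, reference_state, present_day_forcing(), baseline_params
    )
    mass = mass_balance(reference_state, _zero_fluxes(fx), baseline_params)
    assert all(v == 0.0 for v in mass)


def test_pyrite_burial_oxygen_stoichiometry(baseline_params, reference_state):
    """1e12 mol/yr of extra pyrite-S burial yields 2e12 mol/yr of O2."""
    p = baseline_params
    fx, _, _ = compute_fluxes(0.0, reference_state, present_day_forcing(), p)
    bumped = dataclasses.replace(fx, mpsb=fx.mpsb + 1.0e12)
    d0 = mass_balance(reference_state, fx, p)
    d1 = mass_balance(reference_state, bumped, p)
    assert d1.dO - d0.dO == pytest.approx(2.0e12)
    assert d1.dS - d0.dS == pytest.approx(-1.0e12)


def test_redox_bookkeeping_identity(rng):
    """With no reduced-gas flux, dO/dt decomposes exactly into the organic
    and pyrite sub-budgets."""
    p = default_parameters(k_rgf=0.0)
    state = present_day_state(p)
    for _ in range(10):
        mult = rng.uniform(0.3, 3.0, size=5)
        st_i = dataclasses.replace(
            state, P=mult[0] * p.P0, N=mult[1] * p.N0, O=mult[2] * p.O0,
            A=mult[3] * p.A0, S=mult[4] * p.S0,
        )
        snap = ForcingSnapshot(D=rng.uniform(0.5, 2), U=rng.uniform(0.5, 2))
        fx, _, _ = compute_fluxes(600.0, st_i, snap, p)
        mass = mass_balance(st_i, fx, p)
        organic = fx.mocb + fx.locb - fx.oxidw - fx.ocdeg
        pyrite = 2.0 * (fx.mpsb - fx.pyrw - fx.pyrdeg)
        assert mass.dO == pytest.approx(organic + pyrite, abs=1e-3)


# ---------------------------------------------------------------------------
# isotope balance
# ---------------------------------------------------------------------------

def test_degenerate_fractionation_tracks_mass(baseline_params, reference_state):
    """With all source compositions equal and zero fractionation the moment
    derivative is delta times the mass derivative."""
    p = dataclasses.replace(
        default_parameters(), Delta_C=0.0, Delta_S=0.0,
        delta_carb_rock=2.0, delta_org_rock=2.0, delta_mantle_c=2.0,
        delta_gyp_rock=5.0, delta_pyr_rock=5.0,
    )
    state = dataclasses.replace(
        present_day_state(p),
        moment_A_d13C=2.0 * p.A0, moment_S_d34S=5.0 * p.S0,
    )
    fx, _, _ = compute_fluxes(0.0, state, present_day_forcing(), p)
    mass = mass_balance(state, fx, p)
    iso = isotope_balance(state, fx, p)
    assert iso.d_moment_A == pytest.approx(2.0 * mass.dA, abs=1e-3)
    assert iso.d_moment_S == pytest.approx(5.0 * mass.dS, abs=1e-3)


def test_pyrite_fraction_at_table_midpoints():
    """f_py from the uncertainty-table midpoints: 0.70 / (0.70 + 2.50)."""
    p = default_parameters(k_mpsb=0.70e12)
    state = present_day_state(p)
    fx, _, _ = compute_fluxes(0.0, state, present_day_forcing(), p)
    fx = dataclasses.replace(fx, mpsb=0.70e12, mgsb=2.5e12)
    iso = isotope_balance(state, fx, p)
    assert iso.f_py == pytest.approx(0.21875)


def test_isotope_moment_conservation(baseline_params, reference_state, rng):
    """The carbon-13 moment derivative equals the brute-force sum of
    flux x composition over every carbon pathway."""
    p = baseline_params
    for _ in range(10):
        mult = rng.uniform(0.3, 3.0, size=5)
        state = dataclasses.replace(
            reference_state, P=mult[0] * p.P0, N=mult[1] * p.N0,
            O=mult[2] * p.O0, A=mult[3] * p.A0, S=mult[4] * p.S0,
            moment_A_d13C=rng.uniform(-5, 5) * mult[3] * p.A0,
        )
        snap = ForcingSnapshot(D=rng.uniform(0.5, 2), U=rng.uniform(0.5, 2), V=0.0)
        fx, _, _ = compute_fluxes(600.0, state, snap, p)
        iso = isotope_balance(state, fx, p)
        d_a = state.moment_A_d13C / state.A
        brute = (
            fx.ccdeg * p.delta_carb_rock + fx.carbw * p.delta_carb_rock
            + fx.ocdeg * p.delta_org_rock + fx.oxidw * p.delta_org_rock
            + fx.rgf * p.delta_mantle_c
            - fx.mccb * d_a - fx.sfw * d_a
            - (fx.mocb + fx.locb) * (d_a - p.Delta_C)
        )
        assert iso.d_moment_A == pytest.approx(brute, rel=1e-12, abs=1e-3)


# ---------------------------------------------------------------------------
# rhs
# ---------------------------------------------------------------------------

def test_rhs_zero_at_reference(baseline_params, reference_state):
    deriv = rhs(0.0, reference_state, present_day_forcing(), baseline_params)
    scales = reference_state.to_vector()
    assert np.all(np.abs(deriv) / np.abs(scales) < 1e-8)


def test_rhs_is_pure(baseline_params, reference_state):
    snap = ForcingSnapshot(D=1.3, U=0.8, V=0.0)
    a = rhs(600.0, reference_state, snap, baseline_params, rb_elapsed_yr=1e6)
    b = rhs(600.0, reference_state, snap, baseline_params, rb_elapsed_yr=1e6)
    assert np.array_equal(a, b)


def test_rhs_degassing_superposition(baseline_params, reference_state):
    """Doubling D at fixed state shifts the derivatives by exactly the
    degassing-linked flux deltas."""
    p = baseline_params
    f1 = ForcingSnapshot(D=1.0, U=1.0, V=1.0)
    f2 = ForcingSnapshot(D=2.0, U=1.0, V=1.0)
    d1 = rhs(0.0, reference_state, f1, p)
    d2 = rhs(0.0, reference_state, f2, p)
    fx1 = compute_fluxes(0.0, reference_state, f1, p)[0]
    fx2 = compute_fluxes(0.0, reference_state, f2, p)[0]
    dS_expected = (
        (fx2.gypdeg - fx1.gypdeg) + (fx2.pyrdeg - fx1.pyrdeg)
        - (fx2.mgsb - fx1.mgsb) - (fx2.mpsb - fx1.mpsb)
    )
    assert d2[4] - d1[4] == pytest.approx(dS_expected, abs=1.0)
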