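"""Strontium cycle: Rb/Sr calibration, end members, fluxes and isotopes."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ediacaran_o2 import strontium
from ediacaran_o2.forcings import ForcingSnapshot
from ediacaran_o2.model import compute_fluxes, present_day_forcing, present_day_state
from ediacaran_o2.params import SrParameters


@pytest.fixture(scope="module")
def sr():
    return SrParameters()


def test_calibration_degenerate_case(sr):
    assert strontium.rb_sr_calibrate(sr.ratio_initial, sr) == 0.0


def test_calibration_reaches_crustal_average_exactly(sr):
    """Calibrate to 0.73 and evolve for the age of the Earth: the crustal
    average is recovered exactly."""
    rb_sr = strontium.rb_sr_calibrate(sr.crustal_avg_ratio, sr)
    grown = strontium.grow_ratio(rb_sr, sr.earth_age_yr, sr)
    assert grown == pytest.approx(0.73, abs=1e-15)


@settings(max_examples=60, deadline=None)
@given(
    target=st.floats(0.699, 0.99),
    lam=st.floats(1e-12, 1e-10),
)
def test_calibration_round_trip(target, lam):
    sr = SrParameters(lambda_rb=lam)
    rb_sr = strontium.rb_sr_calibrate(target, sr)
    assert strontium.grow_ratio(rb_sr, sr.earth_age_yr, sr) == pytest.approx(
        target, abs=1e-14
    )


def test_calibration_rejects_subinitial_ratio(sr):
    with pytest.raises(ValueError):
        strontium.rb_sr_calibrate(0.69, sr)


def test_end_members_at_formation_and_present(sr):
    at0 = strontium.end_member_ratios(0.0, sr)
    assert all(r == pytest.approx(sr.ratio_initial) for r in at0)
    now = strontium.end_member_ratios(sr.earth_age_yr, sr)
    assert now.granite == pytest.approx(sr.present_ratio_granite, abs=1e-14)
    assert now.basalt == pytest.approx(sr.present_ratio_basalt, abs=1e-14)
    assert now.mantle == pytest.approx(sr.present_ratio_mantle, abs=1e-14)


def test_end_members_halfway_oracle(sr):
    """Half the Earth's age against an independent evaluation of the
    exponential growth law."""
    t = 2.25e9
    got = strontium.end_member_ratios(t, sr)
    for name, present in [
        ("granite", sr.present_ratio_granite),
        ("basalt", sr.present_ratio_basalt),
        ("mantle", sr.present_ratio_mantle),
    ]:
        rb = (present - sr.ratio_initial) / (
            1.0 - math.exp(-sr.lambda_rb * 4.5e9)
        )
        expected = sr.ratio_initial + rb * (1.0 - math.exp(-sr.lambda_rb * t))
        assert getattr(got, name) == pytest.approx(expected, abs=1e-15)


def test_end_members_monotone(sr):
    times = [0.0, 1e9, 2e9, 3e9, 4e9, 4.5e9]
    ratios = [strontium.end_member_ratios(t, sr).granite for t in times]
    assert ratios == sorted(ratios)


def test_end_members_out_of_range(sr):
    with pytest.raises(ValueError):
        strontium.end_member_ratios(-1.0, sr)
    with pytest.raises(ValueError):
        strontium.end_member_ratios(5e9, sr)


# ---------------------------------------------------------------------------
# fluxes
# ---------------------------------------------------------------------------

def test_present_day_ocean_sr_steady(baseline_params):
    """At the reference point each Sr flux equals its constant and ocean
    inputs balance ocean outputs."""
    p = baseline_params
    state = present_day_state(p)
    cfx, _, _ = compute_fluxes(0.0, state, present_day_forcing(), p)
    srfx = strontium.sr_fluxes(state, present_day_forcing(), cfx, p)
    assert srfx.mantle == pytest.approx(p.sr.k_mantle)
    assert srfx.basw == pytest.approx(p.sr.k_basw)
    assert srfx.granw == pytest.approx(p.sr.k_granw)
    assert srfx.sedw == pytest.approx(p.sr.k_sedw)
    assert srfx.metam == pytest.approx(p.sr.k_metam)
    inputs = srfx.mantle + srfx.basw + srfx.granw + srfx.sedw
    outputs = srfx.sedb + srfx.sfw
    assert inputs == pytest.approx(outputs)
    # removal split follows the carbonate-burial : seafloor-weathering ratio
    assert srfx.sedb / srfx.sfw == pytest.approx(p.mccb0 / p.k_sfw)


def test_sr_fluxes_scale_with_drivers(baseline_params):
    p = baseline_params
    state = present_day_state(p)
    base, _, _ = compute_fluxes(0.0, state, present_day_forcing(), p)
    f15 = ForcingSnapshot(D=1.5, U=1.0, V=1.0)
    cfx, _, _ = compute_fluxes(0.0, state, f15, p)
    srfx = strontium.sr_fluxes(state, f15, cfx, p)
    assert srfx.mantle == pytest.approx(1.5 * p.sr.k_mantle)
    assert srfx.metam == pytest.approx(1.5 * p.sr.k_metam)
    doubled_basw = dataclasses.replace(base, basw=2.0 * base.basw)
    srfx2 = strontium.sr_fluxes(state, present_day_forcing(), doubled_basw, p)
    assert srfx2.basw == pytest.approx(2.0 * p.sr.k_basw)


# ---------------------------------------------------------------------------
# isotope balance
# ---------------------------------------------------------------------------

def test_uniform_ratio_fixed_point(baseline_params):
    """If every source and both reservoirs share one ratio, the ocean ratio
    does not drift."""
    p = baseline_params
    r = 0.71
    sr = dataclasses.replace(
        p.sr,
        present_ratio_granite=r, present_ratio_basalt=r,
        present_ratio_mantle=r, ratio_initial=r, crustal_avg_ratio=r,
    )
    p_uniform = dataclasses.replace(p, sr=sr)
    state = present_day_state(p_uniform)
    state = dataclasses.replace(
        state, moment_OSr_ratio=r * state.OSr, moment_SSr_ratio=r * state.SSr
    )
    cfx, _, _ = compute_fluxes(0.0, state, present_day_forcing(), p_uniform)
    srfx = strontium.sr_fluxes(state, present_day_forcing(), cfx, p_uniform)
    members = strontium.end_member_ratios(sr.earth_age_yr, sr)
    bal = strontium.sr_isotope_balance(state, srfx, members, 0.0, sr)
    d_ratio = (bal.d_moment_OSr - bal.sr_ocean * bal.dOSr) / state.OSr
    assert d_ratio == pytest.approx(0.0, abs=1e-18)


def test_steady_ocean_ratio_is_flux_weighted_mean(baseline_params):
    """On a toy 4-source configuration the zero-drift ocean ratio equals the
    brute-force flux-weighted mean of the source ratios."""
    p = baseline_params
    sr = p.sr
    state = present_day_state(p)
    cfx, _, _ = compute_fluxes(0.0, state, present_day_forcing(), p)
    srfx = strontium.sr_fluxes(state, present_day_forcing(), cfx, p)
    members = strontium.end_member_ratios(sr.earth_age_yr, sr)
    r_sed = state.moment_SSr_ratio / state.SSr
    weighted = (
        srfx.granw * members.granite + srfx.basw * members.basalt
        + srfx.mantle * members.mantle + srfx.sedw * r_sed
    ) / (srfx.granw + srfx.basw + srfx.mantle + srfx.sedw)
    state_w = dataclasses.replace(state, moment_OSr_ratio=weighted * state.OSr)
    bal = strontium.sr_isotope_balance(state_w, srfx, members, 0.0, sr)
    d_ratio = (bal.d_moment_OSr - weighted * bal.dOSr) / state.OSr
    # inputs balance outputs at the reference, so the ratio is stationary
    assert d_ratio * 1e6 == pytest.approx(0.0, abs=1e-9)  # per Myr


def test_sediment_ratio_rb_ingrowth(baseline_params):
    """The sediment-ratio diagnostic gains the calibrated radiogenic
    ingrowth over a transient run."""
    p = baseline_params
    state = present_day_state(p)
    base = strontium.sediment_ratio(state, 0.0, p.sr)
    dt = 1.09e8  # a full transient span
    grown = strontium.sediment_ratio(state, dt, p.sr)
    rb = strontium.sediment_rb_sr(p.sr)
    assert grown - base == pytest.approx(
        rb * (1.0 - math.exp(-p.sr.lambda_rb * dt)), abs=1e-15
    )
    assert grown > base


def test_sr_mass_bookkeeping(baseline_params):
    """d(OSr)+d(SSr) equals inputs minus outputs of the combined system."""
    p = baseline_params
    state = present_day_state(p)
    cfx, _, _ = compute_fluxes(
        600.0, state, ForcingSnapshot(D=1.4, U=1.7, V=0.0), p
    )
    srfx = strontium.sr_fluxes(
        state, ForcingSnapshot(D=1.4, U=1.7, V=0.0), cfx, p
    )
    members = strontium.end_member_ratios(3.9e9, p.sr)
    bal = strontium.sr_isotope_balance(state, srfx, members, 0.0, p.sr)
    external_in = srfx.mantle + srfx.basw + srfx.granw
    external_out = srfx.sfw + srfx.metam
    assert bal.dOSr + bal.dSSr == pytest.approx(external_in - external_out)
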