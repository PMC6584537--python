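"""Ocean-sediment strontium cycle and the 87Sr/86Sr isotope system.

Strontium enters the ocean from mantle (hydrothermal) exchange, basalt and
granite weathering, and recycling of marine carbonate sediments, and leaves
by carbonate burial and seafloor weathering; the sedimentary reservoir is
returned by weathering and destroyed by metamorphism.  Each Sr flux scales
with its carbon-cycle counterpart.  There is no isotopic fractionation on
input or output; the 87Sr/86Sr contrast between end members comes from
87Rb decay, which is represented explicitly: each rock type's Rb/Sr ratio
is calibrated so that its observed present-day ratio is reached after
4.5 Gyr of decay from a common initial ratio, and the sedimentary-carbonate
reservoir additionally accumulates radiogenic 87Sr *during* a transient run
(Rb/Sr calibrated to the average crustal ratio of 0.73).
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, NamedTuple

from .forcings import ForcingSnapshot
from .params import SrParameters

if TYPE_CHECKING:  # only for annotations; avoids a circular import
    from .model import FluxVector, ReservoirState
    from .params import ModelParameters


class EndMemberRatios(NamedTuple):
    granite: float
    basalt: float
    mantle: float


class SrFluxes(NamedTuple):
    """Instantaneous Sr fluxes, mol Sr / yr."""

    mantle: float
    basw: float
    granw: float
    sedw: float
    sedb: float
    sfw: float
    metam: float


class SrBalance(NamedTuple):
    dOSr: float
    dSSr: float
    d_moment_OSr: float
    d_moment_SSr: float
    sr_ocean: float
    sr_sediment: float


def rb_sr_calibrate(present_ratio: float, sr: SrParameters) -> float:
    """Rb/Sr ratio that grows ``ratio_initial`` to ``present_ratio`` over the
    age of the Earth: (r_present - r_0) / (1 - exp(-lambda * 4.5e9))."""
    if present_ratio < sr.ratio_initial:
        raise ValueError(
            f"present ratio {present_ratio} below the initial ratio "
            f"{sr.ratio_initial}: no non-negative Rb/Sr can produce it"
        )
    return (present_ratio - sr.ratio_initial) / (
        1.0 - math.exp(-sr.lambda_rb * sr.earth_age_yr)
    )


def grow_ratio(rb_sr: float, t_since_formation_yr: float, sr: SrParameters) -> float:
    """Decay growth law: r(t) = r_0 + Rb/Sr * (1 - exp(-lambda t))."""
    return sr.ratio_initial + rb_sr * (
        1.0 - math.exp(-sr.lambda_rb * t_since_formation_yr)
    )


def end_member_ratios(t_since_formation_yr: float, sr: SrParameters) -> EndMemberRatios:
    """87Sr/86Sr of granite, basalt and mantle at a given time after Earth
    formation; equals the configured present-day values at 4.5 Gyr."""
    if not 0.0 <= t_since_formation_yr <= sr.earth_age_yr:
        raise ValueError(
            f"t since formation must lie in [0, {sr.earth_age_yr:g}] yr, "
            f"got {t_since_formation_yr:g}"
        )
    return EndMemberRatios(
        granite=grow_ratio(
            rb_sr_calibrate(sr.present_ratio_granite, sr), t_since_formation_yr, sr
        ),
        basalt=grow_ratio(
            rb_sr_calibrate(sr.present_ratio_basalt, sr), t_since_formation_yr, sr
        ),
        mantle=grow_ratio(
            rb_sr_calibrate(sr.present_ratio_mantle, sr), t_since_formation_yr, sr
        ),
    )


def sediment_rb_sr(sr: SrParameters) -> float:
    """Sedimentary Rb/Sr, calibrated to the average crustal ratio (0.73)."""
    return rb_sr_calibrate(sr.crustal_avg_ratio, sr)


def sediment_ratio(
    state: "ReservoirState", rb_elapsed_yr: float, sr: SrParameters
) -> float:
    """Sediment 87Sr/86Sr diagnostic: the reservoir moment ratio plus the
    radiogenic ingrowth accumulated since the start of the run."""
    if state.SSr <= 0:
        raise ValueError("sediment Sr reservoir must be positive")
    base = state.moment_SSr_ratio / state.SSr
    if rb_elapsed_yr <= 0.0:
        return base
    return base + sediment_rb_sr(sr) * (1.0 - math.exp(-sr.lambda_rb * rb_elapsed_yr))


def sr_fluxes(
    state: "ReservoirState",
    forcing: ForcingSnapshot,
    carbon_fluxes: "FluxVector",
    p: "ModelParameters",
) -> SrFluxes:
    """Sr fluxes, each scaling with its carbon-cycle counterpart.

    The present-day removal constants (k_sedb, k_sfw) were derived at
    closure so that ocean inputs equal outputs at the reference point, split
    in the proportion of present-day carbonate burial to seafloor
    weathering.
    """
    sr = p.sr
    osr_rel = state.OSr / sr.OSr0
    ssr_rel = state.SSr / sr.SSr0
    return SrFluxes(
        mantle=sr.k_mantle * forcing.D,
        basw=sr.k_basw * carbon_fluxes.basw / p.k_basw,
        granw=sr.k_granw * carbon_fluxes.granw / p.k_granw,
        sedw=sr.k_sedw * (carbon_fluxes.carbw / p.k14) * ssr_rel,
        sedb=sr.k_sedb * (carbon_fluxes.mccb / p.mccb0) * osr_rel,
        sfw=sr.k_sfw * (carbon_fluxes.sfw / p.k_sfw) * osr_rel,
        metam=sr.k_metam * forcing.D * ssr_rel,
    )


def sr_isotope_balance(
    state: "ReservoirState",
    fluxes: SrFluxes,
    members: EndMemberRatios,
    rb_elapsed_yr: float,
    sr: SrParameters,
) -> SrBalance:
    """Mass and isotope-moment derivatives of the two Sr reservoirs.

    Inputs carry their source ratios and outputs carry the instantaneous
    reservoir ratios.  Sr weathered out of the sediments carries the
    Rb-corrected sediment composition (the ingrown 87Sr leaves with it),
    while the sediment moment itself follows the printed burial/weathering
    bookkeeping.
    """
    if state.OSr <= 0 or state.SSr <= 0:
        raise ValueError("Sr reservoirs must be positive")
    r_ocean = state.moment_OSr_ratio / state.OSr
    r_sed_raw = state.moment_SSr_ratio / state.SSr
    r_sed = sediment_ratio(state, rb_elapsed_yr, sr)
    d_osr = fluxes.mantle + fluxes.basw + fluxes.granw + fluxes.sedw \
        - fluxes.sedb - fluxes.sfw
    d_ssr = fluxes.sedb - fluxes.sedw - fluxes.metam
    d_m_osr = (
        fluxes.granw * members.granite
        + fluxes.basw * members.basalt
        + fluxes.mantle * members.mantle
        + fluxes.sedw * r_sed
        - (fluxes.sedb + fluxes.sfw) * r_ocean
    )
    d_m_ssr = fluxes.sedb * r_ocean - (fluxes.sedw + fluxes.metam) * r_sed_raw
    return SrBalance(d_osr, d_ssr, d_m_osr, d_m_ssr, r_ocean, r_sed)
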