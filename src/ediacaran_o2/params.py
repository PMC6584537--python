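"""Model parameters, Monte-Carlo ranges, and present-day closure construction.

The box model is normalised so that with all relative reservoirs equal to 1,
all external forcings equal to 1 (vegetation off) and zero temperature
anomaly, every flux equals its present-day rate constant.  The sampled
present-day fluxes are not mutually balanced, so a *closure construction*
derives the remaining constants such that the present-day reference point is
an exact fixed point of the ODE:

1. total outgassing is partitioned into carbonate and organic-carbon
   degassing in the fixed baseline proportion 12:1;
2. the sampled *total* organic carbon burial is split between marine and
   terrestrial burial in the base model's present-day proportion (half
   each); the closure reference has vegetation on, as today, while the
   Precambrian runs switch it off;
3. the present oxidative-weathering rate balances the oxygen budget;
4. present silicate weathering is the residual of the carbon budget and is
   split into basalt/granite shares by the sampled basaltic fraction;
5. the sulphur budget residual is absorbed into the effective gypsum-burial
   constant;
6. the phosphorus and nitrogen budgets are closed through the land-P
   routing constant, the calcium-bound P burial constant and the
   nitrogen-fixation constant.

Draws for which a derived constant would be negative are physically
inconsistent and are rejected (the caller redraws); this affects only the
extreme corner where near-maximal organic burial meets minimal reactive-P
supply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

R_GAS = 8.314  # J mol-1 K-1
T_REF = 288.0  # K, present-day global mean surface temperature
#: converts an activation energy (J/mol) into the linearised-Arrhenius
#: temperature coefficient k_T such that f_T = exp(k_T * deltaT)
ARRHENIUS_DENOM = R_GAS * T_REF**2

#: baseline split of total outgassing between carbonate- and organic-carbon
#: degassing (1.5e13 : 1.25e12 mol/yr)
CCDEG_OCDEG_SPLIT = (12.0 / 13.0, 1.0 / 13.0)


class ClosureError(ValueError):
    """A sampled present-day flux set admits no physical closure."""


@dataclass(frozen=True, slots=True)
class SrParameters:
    """Strontium-cycle constants (fluxes in mol Sr / yr).

    Flux constants and end-member ratios follow the ocean Sr mass-balance
    literature as adopted by the base model; they are exposed here because
    they are not part of the sampled uncertainty space.  ``k_sedb`` and
    ``k_sfw`` are derived per parameter draw so that the present-day ocean
    Sr reservoir is at steady state, with the removal split between
    carbonate burial and seafloor weathering in the same proportion as the
    corresponding carbon fluxes.
    """

    k_mantle: float = 7.3e9
    k_basw: float = 13.0e9
    k_granw: float = 13.0e9
    k_sedw: float = 17.0e9
    k_metam: float = 13.0e9
    # derived per draw (present-day ocean steady state)
    k_sedb: float = 0.0
    k_sfw: float = 0.0
    lambda_rb: float = 1.42e-11          # 87Rb decay constant, yr-1
    ratio_initial: float = 0.69898       # 87Sr/86Sr at Earth formation
    present_ratio_granite: float = 0.715
    present_ratio_basalt: float = 0.705
    present_ratio_mantle: float = 0.703
    crustal_avg_ratio: float = 0.73      # calibration target for sediments
    earth_age_yr: float = 4.5e9
    OSr0: float = 1.2e17                 # mol, present ocean Sr
    SSr0: float = 5.0e18                 # mol, present sedimentary-carbonate Sr


@dataclass(frozen=True, slots=True)
class ModelParameters:
    """One complete, closed parameter set (one Monte-Carlo draw).

    All flux constants are mol/yr at the present-day reference point.
    Constants that are *derived* by the closure construction are documented
    as such; constants not sampled are base-model defaults.
    """

    # ---- sampled present-day fluxes --------------------------------------
    k14: float            # carbonate weathering, carbw0
    total_outgassing: float
    total_org_burial: float  # total (marine + land) organic C burial
    basfrac: float        # basaltic fraction of silicate weathering
    k_pyrdeg: float
    k_gypdeg: float
    k_mpsb: float         # marine pyrite S burial
    k_mgsb_sampled: float  # sampled gypsum S burial (superseded by closure)
    k21: float            # pyrite weathering, pyrw0
    k22: float            # gypsum weathering, gypw0
    k_phosw: float        # reactive P weathering
    E_sfw: float          # J/mol activation energies
    E_bas: float
    E_gran: float
    k_rgf: float          # modern H2 outgassing (reduced gas flux)
    oxidw_exponent: float  # power of o in oxidative weathering
    climate_sensitivity: float  # degC per CO2 doubling

    # ---- closure-derived constants ---------------------------------------
    k2: float = 0.0       # marine organic C burial, mocb0
    k5: float = 0.0       # land organic C burial, locb0 (zero in V=0 runs)
    k11: float = 0.0      # land P routing fraction
    k12: float = 0.0      # carbonate C degassing, ccdeg0
    k13: float = 0.0      # organic C degassing, ocdeg0
    k17: float = 0.0      # oxidative weathering, oxidw0
    silw0: float = 0.0
    k_granw: float = 0.0
    k_basw: float = 0.0
    k_mgsb: float = 0.0   # effective gypsum S burial constant
    k7: float = 0.0       # calcium-bound P burial, capb0
    k3: float = 0.0       # nitrogen fixation, nfix0
    mccb0: float = 0.0
    k_c: float = 0.0      # = climate_sensitivity / ln 2, degC
    kT_sfw: float = 0.0   # = E_sfw / (R*T0^2), 1/degC
    kT_bas: float = 0.0
    kT_gran: float = 0.0
    anox0: float = 0.0    # present-day anoxic fraction (logistic at o=newp'=1)
    fepb0: float = 0.0
    denit0: float = 0.0

    # ---- base-model (unsampled) constants --------------------------------
    k_l: float = 7.4      # degC, solar-luminosity temperature term
    k1: float = 0.86      # oxic-fraction constant (fepb, denit laws)
    k4: float = 4.3e12    # denitrification scale, mol N/yr
    k6: float = 6.0e9     # iron-sorbed P burial scale, mol P/yr
    marine_fraction_org_burial: float = 0.5  # present marine share of burial
    k_aq: float = 0.8
    b_coal: float = 1.0
    k_sfw: float = 1.75e12
    k_anox: float = 12.0
    k_u: float = 0.5
    r_CP: float = 117.0   # C:P of marine new production
    r_NP: float = 16.0
    CP_sea: float = 250.0  # C:P of buried marine organics
    CN_sea: float = 37.5
    CP_land: float = 1000.0
    runoff_coeff_sil: float = 0.038
    runoff_exp_sil: float = 0.65
    runoff_coeff_carb: float = 0.087
    # pre-plant (abiotic) weathering: f_biota = V + (1-V)*k15*RCO2**exp,
    # i.e. without land plants weathering is k15 of its vegetated rate at
    # equal climate, with a direct CO2 dependence
    k15_preplant: float = 0.15
    biota_co2_exp: float = 0.5

    # ---- reservoirs (mol) -------------------------------------------------
    P0: float = 3.1e15
    N0: float = 4.35e16
    O0: float = 3.7e19
    A0: float = 3.193e18
    S0: float = 4.0e19
    sulphate_mM: float = 28.4  # present ocean [SO4], for the conc. diagnostic

    # ---- isotope constants (permil) ---------------------------------------
    Delta_C: float = 27.0       # organic C burial fractionation
    Delta_S: float = 35.0       # pyrite S burial fractionation
    delta_carb_rock: float = 1.0    # d13C of weathered/degassed carbonate
    delta_org_rock: float = -27.0   # d13C of weathered/degassed organics
    delta_mantle_c: float = -5.0    # d13C of ridge CO2
    delta_gyp_rock: float = 20.0    # d34S of weathered/degassed gypsum
    delta_pyr_rock: float = -15.0   # d34S of weathered/degassed pyrite
    d13C_carb_offset: float = 0.0   # carbonate minus ocean-atmosphere d13C

    # ---- options -----------------------------------------------------------
    mocb_o2_dependence: bool = False  # optional f(O2) on organic burial
    mocb_uplift_dependence: bool = True   # direct U factor on mocb (printed law)
    capb_anoxia: bool = False         # optional f(anox) on Ca-bound P burial
    rgf_o2_equivalent: float = 1.0    # mol O2 consumed per mol H2

    sr: SrParameters = field(default_factory=SrParameters)

    # ---- derived conveniences ---------------------------------------------
    @property
    def newp0(self) -> float:
        """Present-day new production (normalisation denominator)."""
        return self.r_CP * min(30.9 / self.r_NP, 2.2)

    @property
    def sfw0(self) -> float:
        return self.k_sfw

    @property
    def mocb0(self) -> float:
        return self.k2

    @property
    def oxidw0(self) -> float:
        return self.k17

    @property
    def carbw0(self) -> float:
        return self.k14


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def close_parameters(draw: ModelParameters) -> ModelParameters:
    """Apply the closure construction to a raw draw.

    Returns a new :class:`ModelParameters` whose present-day reference point
    is an exact fixed point of the mass balances.  Raises
    :class:`ClosureError` when a derived constant would be negative.
    """
    ccdeg0 = draw.total_outgassing * CCDEG_OCDEG_SPLIT[0]
    ocdeg0 = draw.total_outgassing * CCDEG_OCDEG_SPLIT[1]
    # net present-day pyrite-sulphur burial (an O2 source term)
    ds0 = draw.k_mpsb - draw.k21 - draw.k_pyrdeg

    k2 = draw.marine_fraction_org_burial * draw.total_org_burial
    locb0 = draw.total_org_burial - k2
    k11 = locb0 / (draw.CP_land * draw.k_phosw)
    if k11 >= 1.0:
        raise ClosureError(f"derived land P routing fraction {k11:.3f} >= 1")

    oxidw0 = (
        draw.total_org_burial + 2.0 * ds0 - ocdeg0
        - draw.rgf_o2_equivalent * draw.k_rgf
    )
    if oxidw0 <= 0.0:
        raise ClosureError(
            f"derived present-day oxidative weathering {oxidw0:.3e} <= 0"
        )
    silw0 = ccdeg0 - draw.k_sfw + ds0
    if silw0 <= 0.0:
        raise ClosureError(f"derived present-day silicate weathering {silw0:.3e} <= 0")
    mgsb0 = draw.k22 + draw.k21 + draw.k_gypdeg + draw.k_pyrdeg - draw.k_mpsb
    if mgsb0 <= 0.0:
        raise ClosureError(f"derived present-day gypsum burial {mgsb0:.3e} <= 0")

    anox0 = _logistic(draw.k_anox * (draw.k_u - 1.0))
    fepb0 = (draw.k6 / draw.k1) * (1.0 - anox0)
    mopb0 = k2 / draw.CP_sea
    psea0 = (1.0 - k11) * draw.k_phosw
    k7 = psea0 - mopb0 - fepb0
    if k7 <= 0.0:
        raise ClosureError(
            "P budget cannot close: marine organic P burial "
            f"{mopb0:.3e} + Fe-P {fepb0:.3e} exceeds marine P supply {psea0:.3e}"
        )
    denit0 = draw.k4 * (1.0 + anox0 / (1.0 - draw.k1))
    k3 = denit0 + k2 / draw.CN_sea

    mccb0 = silw0 + draw.k14 + ds0
    if mccb0 <= 0.0:
        raise ClosureError(f"derived present-day carbonate burial {mccb0:.3e} <= 0")

    # ocean Sr steady state: removal matches inputs, split as mccb0 : sfw0
    sr = draw.sr
    sr_in0 = sr.k_mantle + sr.k_basw + sr.k_granw + sr.k_sedw
    share_sedb = mccb0 / (mccb0 + draw.k_sfw)
    sr = replace(sr, k_sedb=sr_in0 * share_sedb, k_sfw=sr_in0 * (1.0 - share_sedb))

    return replace(
        draw,
        k2=k2,
        k5=locb0,
        k11=k11,
        k12=ccdeg0,
        k13=ocdeg0,
        k17=oxidw0,
        silw0=silw0,
        k_granw=(1.0 - draw.basfrac) * silw0,
        k_basw=draw.basfrac * silw0,
        k_mgsb=mgsb0,
        k7=k7,
        k3=k3,
        mccb0=mccb0,
        k_c=draw.climate_sensitivity / math.log(2.0),
        kT_sfw=draw.E_sfw / ARRHENIUS_DENOM,
        kT_bas=draw.E_bas / ARRHENIUS_DENOM,
        kT_gran=draw.E_gran / ARRHENIUS_DENOM,
        anox0=anox0,
        fepb0=fepb0,
        denit0=denit0,
        sr=sr,
    )


#: Monte-Carlo row order (fixed, so that the random stream is stable)
RANGE_FIELDS = (
    "k14",
    "total_outgassing",
    "total_org_burial",
    "basfrac",
    "k_pyrdeg",
    "k_gypdeg",
    "k_mpsb",
    "k_mgsb_sampled",
    "k21",
    "k22",
    "k_phosw",
    "E_sfw",
    "E_bas",
    "E_gran",
    "k_rgf",
    "oxidw_exponent",
    "climate_sensitivity",
)

#: canonical uncertainty intervals for the 17 sampled rows
CANONICAL_RANGES = {
    "k14": (7.0e12, 14.0e12),
    "total_outgassing": (4.0e12, 16.25e12),
    "total_org_burial": (5.0e12, 14.0e12),
    "basfrac": (0.17, 0.35),
    "k_pyrdeg": (0.12e12, 0.38e12),
    "k_gypdeg": (0.25e12, 0.75e12),
    "k_mpsb": (0.53e12, 0.87e12),
    "k_mgsb_sampled": (1.0e12, 4.0e12),
    "k21": (0.37e12, 0.53e12),
    "k22": (1.0e12, 3.0e12),
    "k_phosw": (3.7e10, 4.7e10),
    "E_sfw": (40.0e3, 100.0e3),
    "E_bas": (33.0e3, 62.0e3),
    "E_gran": (45.0e3, 62.0e3),
    "k_rgf": (0.0, 2.2e12),
    "oxidw_exponent": (0.0, 0.5),
    "climate_sensitivity": (1.5, 6.0),
}


@dataclass(frozen=True)
class ParameterRanges:
    """Flat-sampling intervals, one ``(min, max)`` pair per sampled row."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CANONICAL_RANGES)
    )

    def __post_init__(self) -> None:
        unknown = set(self.ranges) - set(RANGE_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter-range keys: {sorted(unknown)}")
        missing = set(RANGE_FIELDS) - set(self.ranges)
        if missing:
            raise ValueError(f"missing parameter-range keys: {sorted(missing)}")
        for name, (lo, hi) in self.ranges.items():
            if not lo <= hi:
                raise ValueError(f"range for {name} has min {lo} > max {hi}")

    @classmethod
    def default(cls) -> "ParameterRanges":
        return cls()

    def midpoint(self) -> dict[str, float]:
        return {k: 0.5 * (lo + hi) for k, (lo, hi) in self.ranges.items()}

    def items(self) -> Iterator[tuple[str, tuple[float, float]]]:
        return iter(self.ranges.items())


#: a documented, closure-feasible baseline draw: base-model published values
#: where they fall inside the sampled intervals, interval midpoints otherwise
BASELINE_DRAW = {
    "k14": 13.35e12,
    "total_outgassing": 16.25e12,
    "total_org_burial": 9.0e12,
    "basfrac": 0.26,
    "k_pyrdeg": 0.25e12,
    "k_gypdeg": 0.5e12,
    "k_mpsb": 0.7e12,
    "k_mgsb_sampled": 2.5e12,
    "k21": 0.45e12,
    "k22": 2.0e12,
    "k_phosw": 4.25e10,
    "E_sfw": 70.0e3,
    "E_bas": 47.5e3,
    "E_gran": 53.5e3,
    # the reduced-gas flux is this study's model extension; the base model has
    # none, so the baseline (non-ensemble) draw carries zero
    "k_rgf": 0.0,
    "oxidw_exponent": 0.5,
    "climate_sensitivity": 3.0,
}


def default_parameters(**overrides) -> ModelParameters:
    """The package's closed baseline parameter set."""
    draw = dict(BASELINE_DRAW)
    closure_kwargs = {}
    for key, value in overrides.items():
        if key in draw:
            draw[key] = value
        else:
            closure_kwargs[key] = value
    return close_parameters(ModelParameters(**draw, **closure_kwargs))


def central_parameters(**overrides) -> ModelParameters:
    """The central draw of the sampled uncertainty space (every row at its
    interval midpoint), closed.  This draw represents the ensemble's centre
    and is the reference set for response-surface characterisation."""
    ranges = ParameterRanges.default()
    draw = ranges.midpoint()
    closure_kwargs = {}
    for key, value in overrides.items():
        if key in draw:
            draw[key] = value
        else:
            closure_kwargs[key] = value
    return close_parameters(ModelParameters(**draw, **closure_kwargs))


def sample_parameters(
    ranges: ParameterRanges,
    rng: np.random.Generator,
    max_rejections: int = 1000,
    rejection_log: list | None = None,
    **options,
) -> ModelParameters:
    """Draw one closed parameter set by flat sampling with rejection.

    Each of the 17 rows is drawn independently and uniformly from its
    interval; the closure construction is then applied and infeasible draws
    are rejected and redrawn.  Rejection reasons are appended to
    ``rejection_log`` when given.  Extra keyword arguments are passed through
    to :class:`ModelParameters` (e.g. ``mocb_o2_dependence=True``).
    """
    for _ in range(max_rejections):
        draw = {
            name: rng.uniform(lo, hi) for name, (lo, hi) in sorted(ranges.items())
        }
        try:
            return close_parameters(ModelParameters(**draw, **options))
        except ClosureError as err:
            if rejection_log is not None:
                rejection_log.append(str(err))
    raise ClosureError(
        f"no feasible draw after {max_rejections} rejections; check the ranges"
    )
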