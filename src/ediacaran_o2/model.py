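"""COPSE-style flux laws, climate and anoxia functions, mass and isotope
balances, and the stiff ODE right-hand side / integrator.

The model tracks five evolving ocean-atmosphere reservoirs (phosphate P,
nitrate N, oxygen O, carbon A, sulphate S), two strontium reservoirs (ocean
OSr and sedimentary carbonate SSr) and four isotope moments (reservoir mass
x isotopic composition).  The large crustal reservoirs (carbonate C, organic
carbon G, pyrite PYR, gypsum GYP) are held at their present relative size 1
throughout: their fractional change over the ~100-Myr windows considered is
negligible.

Time runs in Myr before present and decreases during integration.  All
fluxes are mol/yr; the integrator works internally in years, with reservoir
masses in log space so that positivity is structural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .forcings import ForcingSnapshot
from .params import ModelParameters
from . import strontium

__all__ = [
    "ReservoirState",
    "Climate",
    "FluxVector",
    "Diagnostics",
    "SolverOptions",
    "Trajectory",
    "climate_state",
    "anoxic_fraction",
    "new_production",
    "ocean_ecology_fluxes",
    "weathering_fluxes",
    "burial_and_degassing_fluxes",
    "compute_fluxes",
    "mass_balance",
    "isotope_balance",
    "rhs",
    "integrate",
    "present_day_state",
]


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

N_STATE = 11


@dataclass(frozen=True, slots=True)
class ReservoirState:
    """Mole inventories of the evolving reservoirs plus isotope moments."""

    t_model: float  # Myr before present (metadata, not integrated)
    P: float
    N: float
    O: float
    A: float
    S: float
    OSr: float
    SSr: float
    moment_A_d13C: float     # A * d13C_A, mol * permil
    moment_S_d34S: float     # S * d34S,  mol * permil
    moment_OSr_ratio: float  # OSr * (87Sr/86Sr)_ocean
    moment_SSr_ratio: float  # SSr * (87Sr/86Sr)_sediment

    def __post_init__(self) -> None:
        for name in ("P", "N", "O", "A", "S", "OSr", "SSr"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"reservoir {name} must be strictly positive")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [
                self.P, self.N, self.O, self.A, self.S, self.OSr, self.SSr,
                self.moment_A_d13C, self.moment_S_d34S,
                self.moment_OSr_ratio, self.moment_SSr_ratio,
            ]
        )

    @classmethod
    def from_vector(cls, t_model: float, vec: np.ndarray) -> "ReservoirState":
        return cls(t_model, *map(float, vec))

    # relative (dimensionless) reservoirs
    def a_rel(self, p: ModelParameters) -> float:
        return self.A / p.A0

    def o_rel(self, p: ModelParameters) -> float:
        return self.O / p.O0

    def s_rel(self, p: ModelParameters) -> float:
        return self.S / p.S0

    def d13C_A(self) -> float:
        return self.moment_A_d13C / self.A

    def d34S(self) -> float:
        return self.moment_S_d34S / self.S

    def sr_ocean(self) -> float:
        return self.moment_OSr_ratio / self.OSr


class Climate(NamedTuple):
    RCO2: float    # atmospheric CO2 relative to present
    deltaT: float  # global temperature anomaly, degC


class EcologyFluxes(NamedTuple):
    newp: float
    nfix: float
    denit: float
    mocb: float
    mopb: float
    monb: float
    capb: float
    fepb: float


class WeatheringFluxes(NamedTuple):
    granw: float
    basw: float
    silw: float
    carbw: float
    oxidw: float
    phosw: float
    pyrw: float
    gypw: float
    sfw: float


class BurialFluxes(NamedTuple):
    mccb: float
    mpsb: float
    mgsb: float
    ocdeg: float
    ccdeg: float
    pyrdeg: float
    gypdeg: float
    rgf: float
    locb: float
    pland: float
    psea: float
    mccb_clamped: bool


#: order of the flux columns in trajectory output
FLUX_FIELDS = (
    "phosw", "pland", "locb", "psea", "newp", "mocb", "mopb", "capb", "fepb",
    "nfix", "monb", "denit", "granw", "basw", "silw", "carbw", "oxidw",
    "mccb", "sfw", "pyrw", "gypw", "mpsb", "mgsb", "ocdeg", "ccdeg",
    "pyrdeg", "gypdeg", "rgf",
)


@dataclass(frozen=True, slots=True)
class FluxVector:
    """All instantaneous fluxes, mol/yr (newp in relative production units)."""

    phosw: float
    pland: float
    locb: float
    psea: float
    newp: float
    mocb: float
    mopb: float
    capb: float
    fepb: float
    nfix: float
    monb: float
    denit: float
    granw: float
    basw: float
    silw: float
    carbw: float
    oxidw: float
    mccb: float
    sfw: float
    pyrw: float
    gypw: float
    mpsb: float
    mgsb: float
    ocdeg: float
    ccdeg: float
    pyrdeg: float
    gypdeg: float
    rgf: float
    mccb_clamped: bool = False


@dataclass(frozen=True, slots=True)
class Diagnostics:
    RCO2: float
    deltaT: float
    anox: float
    O2_PAL: float
    d13C_carb: float
    d34S_sw: float
    sr_ocean: float
    sr_sediment: float
    f_org: float
    f_py: float
    SO4_mM: float


DIAG_FIELDS = (
    "RCO2", "deltaT", "anox", "O2_PAL", "d13C_carb", "d34S_sw",
    "sr_ocean", "sr_sediment", "f_org", "f_py", "SO4_mM",
)


# ---------------------------------------------------------------------------
# individual flux laws
# ---------------------------------------------------------------------------

def climate_state(a_rel: float, t_Ma: float, p: ModelParameters) -> Climate:
    """CO2 and the global temperature anomaly.

    RCO2 = a^2 maps the relative ocean-atmosphere carbon inventory onto
    atmospheric CO2; the temperature anomaly combines logarithmic CO2
    forcing (k_c degC per e-fold, i.e. ``climate_sensitivity`` per doubling)
    with a linear penalty for the fainter young sun, -k_l * t/570.
    """
    if a_rel <= 0.0:
        raise ValueError(f"relative carbon reservoir must be positive, got {a_rel}")
    if t_Ma < 0.0:
        raise ValueError(f"t_Ma must be >= 0, got {t_Ma}")
    rco2 = a_rel * a_rel
    return Climate(rco2, p.k_c * math.log(rco2) - p.k_l * t_Ma / 570.0)


def anoxic_fraction(newp_rel: float, o_rel: float, p: ModelParameters) -> float:
    """Global ocean anoxic fraction: a logistic function that expands with
    export production and contracts with atmospheric oxygen."""
    # clamp the exponent: the logistic saturates long before float overflow
    z = min(700.0, max(-700.0, -p.k_anox * (p.k_u * newp_rel - o_rel)))
    return 1.0 / (1.0 + math.exp(z))


def new_production(state: ReservoirState, p: ModelParameters) -> float:
    """Marine new production, limited by the scarcer of N and P."""
    return p.r_CP * min(
        30.9 * (state.N / p.N0) / p.r_NP, 2.2 * (state.P / p.P0)
    )


def ocean_ecology_fluxes(
    state: ReservoirState,
    anox: float,
    forcing: ForcingSnapshot,
    p: ModelParameters,
) -> EcologyFluxes:
    """Production, burial and N-cycle fluxes of the marine biosphere."""
    if state.P <= 0 or state.N <= 0 or state.O <= 0:
        raise ValueError("P, N, O reservoirs must be positive")
    newp = new_production(state, p)
    newp_rel = newp / p.newp0
    o_rel = state.O / p.O0
    f_o2 = 2.1276 * math.exp(-0.755 * o_rel) if p.mocb_o2_dependence else 1.0
    # marine organic burial scales with export production squared and, by
    # default, directly with uplift/erosion (burial tracks sedimentation);
    # the erosion factor largely cancels against erosion-driven oxidative
    # weathering in the O2 budget and can be disabled via config
    u_fac = forcing.U if p.mocb_uplift_dependence else 1.0
    mocb = p.k2 * u_fac * newp_rel * newp_rel * f_o2
    f_anox = (1.0 - anox) / (1.0 - p.anox0) if p.capb_anoxia else 1.0
    capb = p.k7 * newp_rel * newp_rel * f_anox
    fepb = (p.k6 / p.k1) * (1.0 - anox) * (state.P / p.P0)
    surplus = state.P - state.N / p.r_NP
    if surplus > 0.0:
        x = surplus / (p.P0 - p.N0 / p.r_NP)
        nfix = p.k3 * x * x
    else:
        nfix = 0.0
    denit = p.k4 * (1.0 + anox / (1.0 - p.k1)) * (state.N / p.N0)
    return EcologyFluxes(
        newp=newp,
        nfix=nfix,
        denit=denit,
        mocb=mocb,
        mopb=mocb / p.CP_sea,
        monb=mocb / p.CN_sea,
        capb=capb,
        fepb=fepb,
    )


def weathering_fluxes(
    state: ReservoirState,
    forcing: ForcingSnapshot,
    climate: Climate,
    p: ModelParameters,
) -> WeatheringFluxes:
    """Continental and seafloor weathering fluxes.

    Temperature factors are linearised-Arrhenius, exp(E/(R*T0^2) * deltaT);
    runoff factors follow the base model's polynomial forms (clamped at 0);
    the biotic factor blends vegetated weathering (1 at present) with the
    pre-plant rate k15 * RCO2^0.5, so vegetation-off runs weather at a
    fraction of the vegetated rate for equal climate and gain a direct CO2
    dependence.  The oxidative-weathering O2 exponent is a sampled
    parameter (0-0.5).
    """
    dT = climate.deltaT
    f_runoff = max(0.0, 1.0 + p.runoff_coeff_sil * dT) ** p.runoff_exp_sil
    g_runoff = max(0.0, 1.0 + p.runoff_coeff_carb * dT)
    v = forcing.V
    f_biota = v + (1.0 - v) * p.k15_preplant * climate.RCO2 ** p.biota_co2_exp
    granw = (
        p.k_granw * forcing.U * forcing.PG * forcing.a_gran
        * math.exp(p.kT_gran * dT) * f_runoff * f_biota
    )
    basw = (
        p.k_basw * forcing.PG * forcing.a_bas
        * math.exp(p.kT_bas * dT) * f_runoff * f_biota
    )
    silw = granw + basw
    carbw = p.k14 * forcing.U * forcing.PG * forcing.a_carb * g_runoff * f_biota
    o_rel = state.O / p.O0
    oxidw = p.k17 * forcing.U * o_rel ** p.oxidw_exponent
    phosw = p.k_phosw * (
        0.8 * silw / p.silw0 + 0.14 * carbw / p.k14 + 0.06 * oxidw / p.k17
    )
    pyrw = p.k21 * forcing.U
    gypw = p.k22 * forcing.U * forcing.PG * g_runoff * f_biota
    sfw = p.k_sfw * forcing.D * math.exp(p.kT_sfw * dT)
    return WeatheringFluxes(granw, basw, silw, carbw, oxidw, phosw, pyrw, gypw, sfw)


def burial_and_degassing_fluxes(
    state: ReservoirState,
    forcing: ForcingSnapshot,
    ecology: EcologyFluxes,
    weathering: WeatheringFluxes,
    p: ModelParameters,
) -> BurialFluxes:
    """Sediment burial and metamorphic/volcanic degassing fluxes.

    Carbonate burial closes the ocean alkalinity budget:
    mccb = silw + carbw + mpsb - pyrw - pyrdeg.  Under extreme draws this
    can transiently go negative; it is clamped at zero and flagged (a run
    with a persistent clamp is excluded from ensemble statistics).
    """
    s_rel = state.S / p.S0
    o_rel = state.O / p.O0
    mpsb = p.k_mpsb * (s_rel / o_rel) * (ecology.mocb / p.k2)
    mgsb = p.k_mgsb * s_rel * forcing.c_cal
    ocdeg = p.k13 * forcing.D
    ccdeg = p.k12 * forcing.D * forcing.B
    pyrdeg = p.k_pyrdeg * forcing.D
    gypdeg = p.k_gypdeg * forcing.D
    rgf = p.k_rgf * forcing.D
    mccb = weathering.silw + weathering.carbw + mpsb - weathering.pyrw - pyrdeg
    clamped = mccb < 0.0
    if clamped:
        mccb = 0.0
    pland = (
        p.k11 * forcing.V * weathering.phosw
        * (p.k_aq * forcing.U + (1.0 - p.k_aq) * p.b_coal)
    )
    locb = p.CP_land * pland
    psea = weathering.phosw - pland
    return BurialFluxes(
        mccb, mpsb, mgsb, ocdeg, ccdeg, pyrdeg, gypdeg, rgf,
        locb, pland, psea, clamped,
    )


def compute_fluxes(
    t_Ma: float,
    state: ReservoirState,
    forcing: ForcingSnapshot,
    p: ModelParameters,
) -> tuple[FluxVector, Climate, float]:
    """Evaluate the full flux vector: climate -> ecology -> weathering ->
    burial/degassing, in that order."""
    climate = climate_state(state.A / p.A0, t_Ma, p)
    newp_rel = new_production(state, p) / p.newp0
    anox = anoxic_fraction(newp_rel, state.O / p.O0, p)
    eco = ocean_ecology_fluxes(state, anox, forcing, p)
    wea = weathering_fluxes(state, forcing, climate, p)
    bur = burial_and_degassing_fluxes(state, forcing, eco, wea, p)
    fluxes = FluxVector(
        phosw=wea.phosw, pland=bur.pland, locb=bur.locb, psea=bur.psea,
        newp=eco.newp, mocb=eco.mocb, mopb=eco.mopb, capb=eco.capb,
        fepb=eco.fepb, nfix=eco.nfix, monb=eco.monb, denit=eco.denit,
        granw=wea.granw, basw=wea.basw, silw=wea.silw, carbw=wea.carbw,
        oxidw=wea.oxidw, mccb=bur.mccb, sfw=wea.sfw, pyrw=wea.pyrw,
        gypw=wea.gypw, mpsb=bur.mpsb, mgsb=bur.mgsb, ocdeg=bur.ocdeg,
        ccdeg=bur.ccdeg, pyrdeg=bur.pyrdeg, gypdeg=bur.gypdeg, rgf=bur.rgf,
        mccb_clamped=bur.mccb_clamped,
    )
    return fluxes, climate, anox


class MassDerivatives(NamedTuple):
    dP: float
    dN: float
    dO: float
    dA: float
    dS: float


def mass_balance(
    state: ReservoirState, fx: FluxVector, p: ModelParameters
) -> MassDerivatives:
    """Time derivatives (mol/yr) of the five evolving ocean-atmosphere
    reservoirs.  The reduced-gas flux carries mol-for-mol ridge CO2 input
    (a carbon source) and consumes O2 at the configured equivalence."""
    dA = (
        fx.ccdeg + fx.ocdeg + fx.oxidw + fx.carbw + fx.rgf
        - fx.mocb - fx.locb - fx.mccb - fx.sfw
    )
    dO = (
        (fx.mocb + fx.locb - fx.oxidw - fx.ocdeg)
        + 2.0 * (fx.mpsb - fx.pyrw - fx.pyrdeg)
        - p.rgf_o2_equivalent * fx.rgf
    )
    dS = fx.gypw + fx.pyrw + fx.gypdeg + fx.pyrdeg - fx.mgsb - fx.mpsb
    dP = fx.psea - fx.mopb - fx.capb - fx.fepb
    dN = fx.nfix - fx.denit - fx.monb
    return MassDerivatives(dP, dN, dO, dA, dS)


class IsotopeResult(NamedTuple):
    d_moment_A: float  # mol * permil / yr
    d_moment_S: float
    d13C_carb: float
    d34S_sw: float
    f_org: float
    f_py: float


def isotope_balance(
    state: ReservoirState, fx: FluxVector, p: ModelParameters
) -> IsotopeResult:
    """Moment bookkeeping for d13C and d34S.

    Input fluxes carry their source compositions; carbonate burial and
    seafloor weathering remove carbon at the ocean-atmosphere composition;
    organic and pyrite burial remove it fractionated by Delta_C / Delta_S.
    """
    if state.A <= 0 or state.S <= 0:
        raise ValueError("A and S must be positive for isotope diagnostics")
    d_a = state.moment_A_d13C / state.A
    d_s = state.moment_S_d34S / state.S
    d_moment_a = (
        (fx.ccdeg + fx.carbw) * p.delta_carb_rock
        + (fx.ocdeg + fx.oxidw) * p.delta_org_rock
        + fx.rgf * p.delta_mantle_c
        - (fx.mccb + fx.sfw) * d_a
        - (fx.mocb + fx.locb) * (d_a - p.Delta_C)
    )
    d_moment_s = (
        (fx.gypw + fx.gypdeg) * p.delta_gyp_rock
        + (fx.pyrw + fx.pyrdeg) * p.delta_pyr_rock
        - fx.mgsb * d_s
        - fx.mpsb * (d_s - p.Delta_S)
    )
    total_c_burial = fx.mocb + fx.locb + fx.mccb + fx.sfw
    f_org = (fx.mocb + fx.locb) / total_c_burial if total_c_burial > 0 else 0.0
    total_s_burial = fx.mpsb + fx.mgsb
    f_py = fx.mpsb / total_s_burial if total_s_burial > 0 else 0.0
    return IsotopeResult(
        d_moment_a, d_moment_s,
        d13C_carb=d_a + p.d13C_carb_offset, d34S_sw=d_s,
        f_org=f_org, f_py=f_py,
    )


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def rhs(
    t_Ma: float,
    state: ReservoirState,
    forcing: ForcingSnapshot | Callable[[float], ForcingSnapshot],
    p: ModelParameters,
    rb_elapsed_yr: float = 0.0,
) -> np.ndarray:
    """Full derivative vector (mol/yr and mol*permil/yr) in state order.

    Deterministic and pure: identical arguments give identical output.
    ``rb_elapsed_yr`` is the time since the start of the transient run,
    used by the sedimentary Rb-decay term of the Sr system (0 during
    steady-state spin-up).
    """
    snap = forcing(t_Ma) if callable(forcing) else forcing
    fx, climate, anox = compute_fluxes(t_Ma, state, snap, p)
    mass = mass_balance(state, fx, p)
    iso = isotope_balance(state, fx, p)
    t_formation = p.sr.earth_age_yr - t_Ma * 1.0e6
    members = strontium.end_member_ratios(t_formation, p.sr)
    srfx = strontium.sr_fluxes(state, snap, fx, p)
    srbal = strontium.sr_isotope_balance(state, srfx, members, rb_elapsed_yr, p.sr)
    return np.array(
        [
            mass.dP, mass.dN, mass.dO, mass.dA, mass.dS,
            srbal.dOSr, srbal.dSSr,
            iso.d_moment_A, iso.d_moment_S,
            srbal.d_moment_OSr, srbal.d_moment_SSr,
        ]
    )


def diagnostics_at(
    t_Ma: float,
    state: ReservoirState,
    forcing: ForcingSnapshot,
    p: ModelParameters,
    rb_elapsed_yr: float = 0.0,
) -> tuple[FluxVector, Diagnostics]:
    """Fluxes plus derived observables at one instant."""
    fx, climate, anox = compute_fluxes(t_Ma, state, forcing, p)
    iso = isotope_balance(state, fx, p)
    sr_sed = strontium.sediment_ratio(state, rb_elapsed_yr, p.sr)
    diag = Diagnostics(
        RCO2=climate.RCO2,
        deltaT=climate.deltaT,
        anox=anox,
        O2_PAL=state.O / p.O0,
        d13C_carb=iso.d13C_carb,
        d34S_sw=iso.d34S_sw,
        sr_ocean=state.sr_ocean(),
        sr_sediment=sr_sed,
        f_org=iso.f_org,
        f_py=iso.f_py,
        SO4_mM=(state.S / p.S0) * p.sulphate_mM,
    )
    return fx, diag


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolverOptions:
    """Adaptive stiff-solver settings.

    ``atol`` applies in the transformed coordinates (log relative reservoir
    masses; moments normalised by present reservoir size, i.e. permil /
    isotope-ratio scale).
    """

    method: str = "LSODA"
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    grid_Myr: float = 1.0
    max_step_yr: float = np.inf


class SolverFailure(RuntimeError):
    """Integration failed; carries the failure time and parameter draw."""

    def __init__(self, message: str, t_Ma: float, params: ModelParameters):
        super().__init__(message)
        self.t_Ma = t_Ma
        self.params = params


def _scales(p: ModelParameters) -> np.ndarray:
    """Normalisation of the state vector for the transformed coordinates."""
    return np.array(
        [p.P0, p.N0, p.O0, p.A0, p.S0, p.sr.OSr0, p.sr.SSr0,
         p.A0, p.S0, p.sr.OSr0, p.sr.SSr0]
    )


def _to_transformed(vec: np.ndarray, scales: np.ndarray) -> np.ndarray:
    y = vec / scales
    y[:7] = np.log(y[:7])
    return y


def _from_transformed(y: np.ndarray, scales: np.ndarray) -> np.ndarray:
    vec = y.copy()
    # clip the log coordinates: beyond ~e+-200 the solver is probing an
    # absurd trial step that will be rejected anyway; keep floats finite
    vec[:7] = np.exp(np.clip(vec[:7], -200.0, 200.0))
    return vec * scales


def _transformed_rhs(
    p: ModelParameters,
    scales: np.ndarray,
    forcing_at: Callable[[float], ForcingSnapshot],
    t_Ma_of: Callable[[float], float],
    rb_elapsed_of: Callable[[float], float],
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build dy/dtau (tau in years) in the log/normalised coordinates."""

    def fun(tau: float, y: np.ndarray) -> np.ndarray:
        vec = _from_transformed(y, scales)
        t_Ma = t_Ma_of(tau)
        state = ReservoirState.from_vector(t_Ma, vec)
        deriv = rhs(t_Ma, state, forcing_at(t_Ma), p, rb_elapsed_yr=rb_elapsed_of(tau))
        dy = deriv / scales
        dy[:7] = deriv[:7] / vec[:7]
        return dy

    return fun


@dataclass
class Trajectory:
    """A model run sampled on a uniform output grid (1 Myr by default).

    ``frame`` holds one row per grid time with reservoirs (mol), relative
    reservoirs, all fluxes (mol/yr), diagnostics, and the forcings applied.
    """

    frame: pd.DataFrame
    params: ModelParameters
    clamp_points: int = 0
    grid_Myr: float = 1.0
    metadata: dict = field(default_factory=dict)

    @property
    def clamp_Myr(self) -> float:
        """Cumulative duration (Myr, grid resolution) of the mccb >= 0 clamp."""
        return self.clamp_points * self.grid_Myr

    @property
    def valid(self) -> bool:
        """False when the carbonate-burial clamp persisted beyond 1 Myr."""
        return self.clamp_Myr <= 1.0

    def final_state(self) -> ReservoirState:
        row = self.frame.iloc[-1]
        return ReservoirState(
            t_model=row["t_Ma"],
            P=row["P"], N=row["N"], O=row["O"], A=row["A"], S=row["S"],
            OSr=row["OSr"], SSr=row["SSr"],
            moment_A_d13C=row["moment_A_d13C"],
            moment_S_d34S=row["moment_S_d34S"],
            moment_OSr_ratio=row["moment_OSr_ratio"],
            moment_SSr_ratio=row["moment_SSr_ratio"],
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


RESERVOIR_COLUMNS = (
    "P", "N", "O", "A", "S", "OSr", "SSr",
    "moment_A_d13C", "moment_S_d34S", "moment_OSr_ratio", "moment_SSr_ratio",
)
RELATIVE_COLUMNS = ("p_rel", "n_rel", "o2_pal", "a_rel", "s_rel", "osr_rel", "ssr_rel")


def _trajectory_rows(
    p: ModelParameters,
    times_Ma: np.ndarray,
    vectors: np.ndarray,
    forcing_at: Callable[[float], ForcingSnapshot],
    rb_elapsed_of: Callable[[float], float],
) -> tuple[pd.DataFrame, int]:
    records = []
    clamp_points = 0
    for t_Ma, vec in zip(times_Ma, vectors):
        state = ReservoirState.from_vector(t_Ma, vec)
        snap = forcing_at(t_Ma)
        fx, diag = diagnostics_at(t_Ma, state, snap, p, rb_elapsed_of(t_Ma))
        if fx.mccb_clamped:
            clamp_points += 1
        row = {"t_Ma": t_Ma}
        row.update({name: getattr(state, name) for name in RESERVOIR_COLUMNS})
        row.update(
            p_rel=state.P / p.P0, n_rel=state.N / p.N0, o2_pal=state.O / p.O0,
            a_rel=state.A / p.A0, s_rel=state.S / p.S0,
            osr_rel=state.OSr / p.sr.OSr0, ssr_rel=state.SSr / p.sr.SSr0,
        )
        row.update({name: getattr(fx, name) for name in FLUX_FIELDS})
        row.update({name: getattr(diag, name) for name in DIAG_FIELDS})
        row.update(D=snap.D, U=snap.U)
        records.append(row)
    return pd.DataFrame.from_records(records), clamp_points


def integrate(
    initial_state: ReservoirState,
    t_start_Ma: float,
    t_end_Ma: float,
    forcing: Callable[[float], ForcingSnapshot],
    p: ModelParameters,
    solver: SolverOptions | None = None,
    rb_zero_Ma: float | None = None,
) -> Trajectory:
    """Integrate the model from ``t_start_Ma`` down to ``t_end_Ma``.

    The forcing provider is re-evaluated continuously; any declared forcing
    discontinuities (degassing resampling steps) restart the adaptive
    solver.  ``rb_zero_Ma`` anchors the sedimentary Rb-decay clock (None
    freezes it, as during spin-up).
    """
    if not t_start_Ma > t_end_Ma:
        raise ValueError("time must decrease toward the present (t_start > t_end)")
    solver = solver or SolverOptions()
    scales = _scales(p)
    y0 = _to_transformed(initial_state.to_vector(), scales)

    def t_Ma_of(tau: float) -> float:
        return t_start_Ma - tau / 1.0e6

    if rb_zero_Ma is None:
        def rb_of_tau(tau: float) -> float:
            return 0.0

        def rb_of_t(t_Ma: float) -> float:
            return 0.0
    else:
        def rb_of_tau(tau: float) -> float:
            return max(0.0, (rb_zero_Ma - t_start_Ma) * 1.0e6 + tau)

        def rb_of_t(t_Ma: float) -> float:
            return max(0.0, (rb_zero_Ma - t_Ma) * 1.0e6)

    disc = sorted(
        (t for t in getattr(forcing, "discontinuities", ()) if t_end_Ma < t < t_start_Ma),
        reverse=True,
    )
    seg_edges = [t_start_Ma] + disc + [t_end_Ma]
    n_grid = int(round((t_start_Ma - t_end_Ma) / solver.grid_Myr)) + 1
    grid = t_start_Ma - solver.grid_Myr * np.arange(n_grid)

    times_out: list[float] = []
    vecs_out: list[np.ndarray] = []
    y = y0
    for hi, lo in zip(seg_edges[:-1], seg_edges[1:]):
        # freeze forcing lookups just inside the segment so that the step
        # function is single-valued across the solver's endpoint evaluations
        def seg_forcing(t_Ma: float, _hi=hi, _lo=lo):
            return forcing(min(max(t_Ma, _lo + 1e-9), _hi - 1e-9))

        fun = _transformed_rhs(p, scales, seg_forcing, t_Ma_of, rb_of_tau)
        tau0, tau1 = (t_start_Ma - hi) * 1e6, (t_start_Ma - lo) * 1e6
        t_eval = [(t_start_Ma - t) * 1e6 for t in grid if lo < t <= hi or
                  (lo == seg_edges[-1] and t == lo)]
        sol = solve_ivp(
            fun, (tau0, tau1), y, method=solver.method,
            rtol=solver.rtol, atol=solver.atol, t_eval=sorted(t_eval),
            max_step=solver.max_step_yr, dense_output=False,
        )
        if not sol.success and solver.method != "BDF":
            # rare hard failures at forcing steps: retry the segment fully
            # implicit before giving up
            sol = solve_ivp(
                fun, (tau0, tau1), y, method="BDF",
                rtol=solver.rtol, atol=solver.atol, t_eval=sorted(t_eval),
                max_step=solver.max_step_yr, dense_output=False,
            )
        if not sol.success:
            raise SolverFailure(
                f"solver failed in segment [{hi}, {lo}] Ma: {sol.message}",
                t_Ma=t_Ma_of(sol.t[-1]) if len(sol.t) else hi,
                params=p,
            )
        for tau, yy in zip(sol.t, sol.y.T):
            times_out.append(t_Ma_of(tau))
            vecs_out.append(_from_transformed(yy, scales))
        y = sol.y[:, -1]

    frame, clamp_points = _trajectory_rows(
        p, np.array(times_out), np.array(vecs_out), forcing, rb_of_t
    )
    return Trajectory(
        frame=frame, params=p, clamp_points=clamp_points, grid_Myr=solver.grid_Myr,
        metadata={"t_start_Ma": t_start_Ma, "t_end_Ma": t_end_Ma,
                  "rb_zero_Ma": rb_zero_Ma},
    )


# ---------------------------------------------------------------------------
# reference state
# ---------------------------------------------------------------------------

def present_day_forcing() -> ForcingSnapshot:
    """The closure reference forcing: everything at 1, vegetation on."""
    return ForcingSnapshot(V=1.0)


def present_day_state(p: ModelParameters) -> ReservoirState:
    """The present-day reference point: all relative reservoirs 1, isotope
    moments at their analytic steady-state compositions for this draw."""
    total_ocb = p.k2 + p.k5
    d13c = (
        (p.k12 + p.k14) * p.delta_carb_rock
        + (p.k13 + p.k17) * p.delta_org_rock
        + p.k_rgf * p.delta_mantle_c
        + total_ocb * p.Delta_C
    ) / (total_ocb + p.mccb0 + p.k_sfw)
    d34s = (
        (p.k22 + p.k_gypdeg) * p.delta_gyp_rock
        + (p.k21 + p.k_pyrdeg) * p.delta_pyr_rock
        + p.k_mpsb * p.Delta_S
    ) / (p.k_mpsb + p.k_mgsb)
    sr = p.sr
    sr_in = sr.k_granw + sr.k_basw + sr.k_mantle + sr.k_sedw
    sed_ratio0 = 0.708
    ocean_ratio0 = (
        sr.k_granw * sr.present_ratio_granite
        + sr.k_basw * sr.present_ratio_basalt
        + sr.k_mantle * sr.present_ratio_mantle
        + sr.k_sedw * sed_ratio0
    ) / sr_in
    return ReservoirState(
        t_model=0.0,
        P=p.P0, N=p.N0, O=p.O0, A=p.A0, S=p.S0,
        OSr=sr.OSr0, SSr=sr.SSr0,
        moment_A_d13C=p.A0 * d13c,
        moment_S_d34S=p.S0 * d34s,
        moment_OSr_ratio=sr.OSr0 * ocean_ratio0,
        moment_SSr_ratio=sr.SSr0 * sed_ratio0,
    )
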