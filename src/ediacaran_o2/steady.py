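"""Long-run equilibration and steady-state response surfaces.

Steady states are computed by integrating the model under frozen forcings
(and a frozen solar/time term, by default pinned at 541 Ma) for up to
10 Gyr — a relaxation device, not a physical history — followed by a
Newton polish of the fixed point.  Convergence is judged by the maximum
relative time derivative of the state and reported honestly: a
non-converged cell is flagged, never silently returned as converged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .forcings import ConstantForcing, ForcingSnapshot
from .model import (
    Diagnostics,
    FluxVector,
    ReservoirState,
    SolverOptions,
    _from_transformed,
    _scales,
    _to_transformed,
    diagnostics_at,
    present_day_state,
    rhs,
)
from .params import ModelParameters

DEFAULT_HORIZON_YR = 1.0e10
DEFAULT_RESIDUAL_TOL = 1.0e-10  # 1/yr, max relative derivative


def residual_norm(
    t_Ma: float,
    state: ReservoirState,
    forcing: ForcingSnapshot,
    p: ModelParameters,
) -> float:
    """Max relative time derivative (1/yr): |dX/dt|/X for masses and
    |dm/dt| / max(|m|, X) for isotope moments."""
    deriv = rhs(t_Ma, state, forcing, p)
    vec = state.to_vector()
    rel_mass = np.abs(deriv[:7]) / vec[:7]
    # moments are scaled by their host reservoirs (A, S, OSr, SSr)
    rel_mom = np.abs(deriv[7:]) / np.maximum(np.abs(vec[7:]), vec[[3, 4, 5, 6]])
    return float(max(rel_mass.max(), rel_mom.max()))


@dataclass(frozen=True)
class SteadyStateResult:
    forcing: ForcingSnapshot
    state: ReservoirState
    fluxes: FluxVector
    diagnostics: Diagnostics
    converged: bool
    residual: float          # max relative derivative, 1/yr
    integrated_yr: float
    t_climate_Ma: float


def run_to_steady(
    forcing: ForcingSnapshot | ConstantForcing,
    p: ModelParameters,
    horizon_yr: float = DEFAULT_HORIZON_YR,
    t_climate_Ma: float = 541.0,
    tol: float = DEFAULT_RESIDUAL_TOL,
    initial_state: ReservoirState | None = None,
    solver: SolverOptions | None = None,
) -> SteadyStateResult:
    """Equilibrate the model under constant forcing.

    Integrates the autonomous system (forcings, solar term and Sr end
    members all frozen at ``t_climate_Ma``) in expanding chunks until the
    residual drops below ``tol`` or the horizon is exhausted, then polishes
    the fixed point with a Newton solve; the polished point is accepted only
    if it is close to the integrated endpoint and strictly improves the
    residual.
    """
    snap = forcing.snapshot if isinstance(forcing, ConstantForcing) else forcing
    solver = solver or SolverOptions()
    state = initial_state or present_day_state(p)
    scales = _scales(p)
    y = _to_transformed(state.to_vector(), scales)

    def fun(_tau: float, yy: np.ndarray) -> np.ndarray:
        vec = _from_transformed(yy, scales)
        st = ReservoirState.from_vector(t_climate_Ma, vec)
        deriv = rhs(t_climate_Ma, st, snap, p)
        dy = deriv / scales
        dy[:7] = deriv[:7] / vec[:7]
        return dy

    chunk_ends = [c for c in (1e7, 1e8, 1e9, horizon_yr) if c <= horizon_yr]
    if not chunk_ends or chunk_ends[-1] < horizon_yr:
        chunk_ends.append(horizon_yr)

    def try_polish(y_now: np.ndarray, res_now: float):
        """Newton polish of the fixed point, guarded: the candidate must stay
        within the same basin (bounded move in the log coordinates) and must
        strictly improve the residual."""
        polished = root(lambda yy: fun(0.0, yy), y_now, method="hybr", tol=1e-14)
        if not polished.success:
            return y_now, res_now
        if np.any(np.abs(polished.x[:7] - y_now[:7]) > 2.0):
            return y_now, res_now
        if np.any(np.abs(polished.x[7:] - y_now[7:]) > 10.0):
            return y_now, res_now
        cand = ReservoirState.from_vector(
            t_climate_Ma, _from_transformed(polished.x, scales)
        )
        res_cand = residual_norm(t_climate_Ma, cand, snap, p)
        if res_cand < res_now:
            return polished.x, res_cand
        return y_now, res_now

    integrated = 0.0
    res = residual_norm(t_climate_Ma, state, snap, p)
    for end in chunk_ends:
        sol = solve_ivp(
            fun, (integrated, end), y, method=solver.method,
            rtol=solver.rtol, atol=solver.atol,
        )
        if not sol.success:
            break
        y = sol.y[:, -1]
        integrated = float(sol.t[-1])
        state = ReservoirState.from_vector(t_climate_Ma, _from_transformed(y, scales))
        res = residual_norm(t_climate_Ma, state, snap, p)
        # a Newton step from the partially relaxed state often lands on the
        # fixed point directly, short-circuiting slow weak-feedback draws
        y, res = try_polish(y, res)
        state = ReservoirState.from_vector(t_climate_Ma, _from_transformed(y, scales))
        if res < tol:
            break
    converged = res < tol
    res_before = res

    fluxes, diag = diagnostics_at(t_climate_Ma, state, snap, p)
    return SteadyStateResult(
        forcing=snap, state=state, fluxes=fluxes, diagnostics=diag,
        converged=converged, residual=res_before, integrated_yr=integrated,
        t_climate_Ma=t_climate_Ma,
    )


SWEEP_COLUMNS = (
    "D", "U", "converged", "residual",
    "mocb", "mccb", "sfw", "mpsb", "mgsb", "O2_mol", "o2_pal", "RCO2",
    "deltaT", "anox", "d13C_carb", "d34S_sw", "sr_ocean", "f_org", "f_py",
)


def sweep_DU(
    d_values: Sequence[float],
    u_values: Sequence[float],
    p: ModelParameters,
    t_climate_Ma: float = 541.0,
    **kwargs,
) -> pd.DataFrame:
    """Full-factorial steady-state table over degassing and uplift grids.

    Cells are warm-started from the previous steady state along the D axis
    to speed convergence; per-cell failures are flagged, not raised.
    """
    d_values = list(d_values)
    u_values = list(u_values)
    if not d_values or not u_values:
        raise ValueError("D and U grids must be non-empty")
    rows = []
    for u in u_values:
        warm: ReservoirState | None = None
        for d in d_values:
            result = run_to_steady(
                ForcingSnapshot(D=d, U=u), p,
                t_climate_Ma=t_climate_Ma, initial_state=warm, **kwargs,
            )
            warm = result.state
            diag = result.diagnostics
            rows.append(
                dict(
                    D=d, U=u, converged=result.converged, residual=result.residual,
                    mocb=result.fluxes.mocb, mccb=result.fluxes.mccb,
                    sfw=result.fluxes.sfw, mpsb=result.fluxes.mpsb,
                    mgsb=result.fluxes.mgsb, O2_mol=result.state.O,
                    o2_pal=diag.O2_PAL, RCO2=diag.RCO2, deltaT=diag.deltaT,
                    anox=diag.anox, d13C_carb=diag.d13C_carb,
                    d34S_sw=diag.d34S_sw, sr_ocean=diag.sr_ocean,
                    f_org=diag.f_org, f_py=diag.f_py,
                )
            )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
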