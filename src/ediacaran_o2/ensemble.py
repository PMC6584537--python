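"""Monte-Carlo uncertainty engine.

Each ensemble member draws one closed parameter set by flat sampling of the
uncertainty table, draws one degassing path from the envelope (redrawn
every 10 Myr), spins up to steady state under its own start-of-run forcing,
and integrates the transient to the end of the span.  Per-run random
substreams are keyed by (master seed, run index), so results are
bit-reproducible regardless of execution order or worker count, and adding
runs never perturbs existing ones.

Summary products are per-time band statistics (mean, +-0.5 and +-1 sample
standard deviation, matching the published shading convention) and the
distribution of the per-run fractional O2 change between an early and a
late averaging window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .forcings import (
    DEFAULT_T_END_MA,
    DEFAULT_T_START_MA,
    DegassingWindow,
    EdiacaranForcing,
    default_ediacaran_window,
    sample_degassing_path,
)
from .model import SolverFailure, SolverOptions, integrate
from .params import (
    RANGE_FIELDS,
    ClosureError,
    ParameterRanges,
    sample_parameters,
)
from .steady import run_to_steady

#: trajectory variables retained per run
ENSEMBLE_VARIABLES = (
    "o2_pal", "RCO2", "mocb", "mccb", "sfw", "mpsb", "mgsb",
    "f_org", "f_py", "d13C_carb", "d34S_sw", "sr_ocean", "sr_sediment",
    "anox", "SO4_mM", "D", "U",
)

DERIVED_FIELDS = ("k12", "k13", "k17", "silw0", "k_mgsb", "k7", "k3", "mccb0")

EARLY_WINDOW_MA = (640.0, 620.0)
LATE_WINDOW_MA = (560.0, 540.0)


class EnsembleError(RuntimeError):
    pass


@dataclass(frozen=True)
class EnsembleResult:
    """Per-run trajectories on a common grid plus draws and validity flags."""

    t_Ma: np.ndarray
    data: dict[str, np.ndarray]      # variable -> (n_runs, n_times)
    draws: pd.DataFrame              # one row per run
    valid: np.ndarray                # bool, per run
    master_seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.valid)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def window_mean(self, variable: str, window: tuple[float, float]) -> np.ndarray:
        """Per-run time-mean of a variable over an age window (old, young)."""
        old, young = max(window), min(window)
        mask = (self.t_Ma <= old + 1e-9) & (self.t_Ma >= young - 1e-9)
        if not mask.any():
            raise ValueError(f"window {window} Ma outside the trajectory span")
        return self.data[variable][:, mask].mean(axis=1)

    def ensemble_mean(self, variable: str) -> np.ndarray:
        return self.data[variable][self.valid].mean(axis=0)

    def at_time(self, variable: str, t_Ma: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.t_Ma - t_Ma)))
        if abs(self.t_Ma[idx] - t_Ma) > 0.5 * (self.t_Ma[0] - self.t_Ma[1]):
            raise ValueError(f"t={t_Ma} Ma not on the output grid")
        return self.data[variable][:, idx]


def _run_streams(master_seed: int, run_index: int) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(master_seed, spawn_key=(run_index,))
    return tuple(np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(2))


def _single_run(
    run_index: int,
    master_seed: int,
    window: DegassingWindow,
    ranges: ParameterRanges,
    u_start: float,
    u_end: float,
    t_start_Ma: float,
    t_end_Ma: float,
    solver: SolverOptions,
    param_options: dict,
) -> dict:
    """One fully seeded ensemble member.  Never raises for per-run physics
    failures; returns a record with ``valid``/``reason``."""
    param_rng, path_rng = _run_streams(master_seed, run_index)
    rejections: list[str] = []
    record: dict = {"run_index": run_index, "valid": False, "reason": ""}
    try:
        params = sample_parameters(
            ranges, param_rng, rejection_log=rejections, **param_options
        )
    except ClosureError as err:
        record["reason"] = f"sampling: {err}"
        record["n_rejections"] = len(rejections)
        return record
    record["n_rejections"] = len(rejections)
    for name in RANGE_FIELDS + DERIVED_FIELDS:
        record[name] = getattr(params, name)

    path = sample_degassing_path(window, path_rng, t_start_Ma, t_end_Ma)
    forcing = EdiacaranForcing(
        path, t_start_Ma=t_start_Ma, t_end_Ma=t_end_Ma,
        u_start=u_start, u_end=u_end,
    )
    start_snap = forcing(t_start_Ma)
    try:
        spin = run_to_steady(
            start_snap, params, t_climate_Ma=t_start_Ma, solver=solver
        )
        record["spinup_converged"] = spin.converged
        record["spinup_residual"] = spin.residual
        traj = integrate(
            spin.state, t_start_Ma, t_end_Ma, forcing, params,
            solver=solver, rb_zero_Ma=t_start_Ma,
        )
    except (SolverFailure, ValueError, FloatingPointError) as err:
        record["reason"] = f"solver: {err}"
        return record
    record["clamp_Myr"] = traj.clamp_Myr
    if not traj.valid:
        record["reason"] = f"persistent mccb clamp ({traj.clamp_Myr:.0f} Myr)"
        return record
    record["valid"] = True
    record["trajectory"] = {
        var: traj.frame[var].to_numpy() for var in ENSEMBLE_VARIABLES
    }
    record["t_Ma"] = traj.frame["t_Ma"].to_numpy()
    return record


def run_ensemble(
    n_runs: int,
    master_seed: int,
    window: DegassingWindow | None = None,
    ranges: ParameterRanges | None = None,
    u_start: float = 0.5,
    u_end: float = 2.0,
    t_start_Ma: float = DEFAULT_T_START_MA,
    t_end_Ma: float = DEFAULT_T_END_MA,
    solver: SolverOptions | None = None,
    n_jobs: int = 1,
    max_invalid_fraction: float = 0.1,
    **param_options,
) -> EnsembleResult:
    """Run the Monte-Carlo experiment.

    The default configuration is the standard experiment: flat sampling of
    the 17-row uncertainty table, degassing resampled every 10 Myr from the
    default envelope, uplift ramping linearly 0.5 -> 2.0, span 650 -> 540 Ma
    with per-run steady-state spin-up at the 650-Ma forcing.  Set
    ``u_start == u_end`` for the constant-uplift variant.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    window = window or default_ediacaran_window(t_start_Ma, t_end_Ma)
    ranges = ranges or ParameterRanges.default()
    solver = solver or SolverOptions()
    args = (master_seed, window, ranges, u_start, u_end,
            t_start_Ma, t_end_Ma, solver, param_options)
    if n_jobs == 1:
        records = [_single_run(i, *args) for i in range(n_runs)]
    else:
        from joblib import Parallel, delayed

        records = Parallel(n_jobs=n_jobs)(
            delayed(_single_run)(i, *args) for i in range(n_runs)
        )
    records.sort(key=lambda r: r["run_index"])  # order-independence

    valid = np.array([r["valid"] for r in records])
    n_invalid = int((~valid).sum())
    if n_invalid > max_invalid_fraction * n_runs:
        reasons = [r["reason"] for r in records if not r["valid"]][:5]
        raise EnsembleError(
            f"{n_invalid}/{n_runs} runs invalid (> {max_invalid_fraction:.0%}); "
            f"first reasons: {reasons}"
        )
    t_Ma = next(r["t_Ma"] for r in records if r["valid"])
    n_t = len(t_Ma)
    data = {
        var: np.full((n_runs, n_t), np.nan) for var in ENSEMBLE_VARIABLES
    }
    for i, rec in enumerate(records):
        if rec["valid"]:
            for var in ENSEMBLE_VARIABLES:
                data[var][i] = rec["trajectory"][var]
    draw_cols = (
        ["run_index", "valid", "reason", "n_rejections",
         "spinup_converged", "spinup_residual", "clamp_Myr"]
        + list(RANGE_FIELDS) + list(DERIVED_FIELDS)
    )
    draws = pd.DataFrame.from_records(
        [{k: r.get(k) for k in draw_cols} for r in records]
    )
    return EnsembleResult(
        t_Ma=t_Ma, data=data, draws=draws, valid=valid, master_seed=master_seed,
        config={
            "n_runs": n_runs, "u_start": u_start, "u_end": u_end,
            "t_start_Ma": t_start_Ma, "t_end_Ma": t_end_Ma,
            "window": window.to_frame().to_dict("list"),
            "param_options": dict(param_options),
        },
    )


def band_statistics(ens: EnsembleResult, variable: str) -> pd.DataFrame:
    """Per-time mean and +-0.5 / +-1 sample-standard-deviation bands over
    valid runs."""
    if ens.n_valid < 2:
        raise ValueError("band statistics need at least 2 valid runs")
    values = ens.data[variable][ens.valid]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    return pd.DataFrame(
        {
            "t_Ma": ens.t_Ma,
            "mean": mean,
            "sd": sd,
            "lo_half_sd": mean - 0.5 * sd,
            "hi_half_sd": mean + 0.5 * sd,
            "lo_1sd": mean - sd,
            "hi_1sd": mean + sd,
        }
    )


@dataclass(frozen=True)
class O2ChangeDistribution:
    """Per-run fractional O2 change between two averaging windows."""

    changes_percent: np.ndarray  # per valid run
    fraction_positive: float
    fraction_25_75: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    early_window: tuple[float, float]
    late_window: tuple[float, float]


def o2_change_distribution(
    ens: EnsembleResult,
    early_window: tuple[float, float] = EARLY_WINDOW_MA,
    late_window: tuple[float, float] = LATE_WINDOW_MA,
    variable: str = "o2_pal",
    bins: Sequence[float] | None = None,
) -> O2ChangeDistribution:
    """Distribution of 100 * (late-window mean - early-window mean) /
    early-window mean over valid runs."""
    early = ens.window_mean(variable, early_window)[ens.valid]
    late = ens.window_mean(variable, late_window)[ens.valid]
    changes = 100.0 * (late - early) / early
    if bins is None:
        bins = np.arange(-60.0, 160.0 + 1e-9, 10.0)
    counts, edges = np.histogram(changes, bins=bins)
    return O2ChangeDistribution(
        changes_percent=changes,
        fraction_positive=float((changes > 0).mean()),
        fraction_25_75=float(((changes >= 25.0) & (changes <= 75.0)).mean()),
        hist_counts=counts,
        hist_edges=edges,
        early_window=early_window,
        late_window=late_window,
    )
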