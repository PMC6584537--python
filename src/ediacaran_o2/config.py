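"""Run configuration: YAML loading, validation and provenance echoing.

A configuration file selects a stage (``steady`` | ``run`` | ``ensemble`` |
``trend``) and overrides defaults.  Validation is strict: unknown keys are
rejected by name, and ensemble range overrides must lie inside the
canonical uncertainty intervals.  The echoed configuration annotates every
default that originates in the base model rather than this study's own
sampled table, so a run's provenance is auditable from its output alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import (
    BASELINE_DRAW,
    CANONICAL_RANGES,
    ParameterRanges,
    default_parameters,
)

STAGES = ("steady", "run", "ensemble", "trend")

#: defaults adopted from the base model (not sampled in this study)
BASE_MODEL_DEFAULTS = (
    "k1", "k4", "k6", "k_anox", "k_u", "k_sfw", "k_l",
    "CP_sea", "CN_sea", "CP_land", "r_CP", "r_NP",
    "P0", "N0", "O0", "A0", "S0",
    "runoff_coeff_sil", "runoff_exp_sil", "runoff_coeff_carb", "biota_co2_exp",
    "Delta_C", "Delta_S", "delta_carb_rock", "delta_org_rock",
    "delta_mantle_c", "delta_gyp_rock", "delta_pyr_rock",
    "sr.k_mantle", "sr.k_basw", "sr.k_granw", "sr.k_sedw", "sr.k_metam",
    "sr.lambda_rb", "sr.ratio_initial", "sr.present_ratio_granite",
    "sr.present_ratio_basalt", "sr.present_ratio_mantle",
    "sr.crustal_avg_ratio", "sr.OSr0", "sr.SSr0",
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    method: str = "LSODA"
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    grid_Myr: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    stage: str = "run"
    seed: int = 1
    out_dir: str = "results"
    # transient / ensemble span and forcings
    t_start_Ma: float = 650.0
    t_end_Ma: float = 540.0
    u_start: float = 0.5
    u_end: float = 2.0
    window_file: str | None = None   # CSV of (t_Ma, d_min, d_max) nodes
    # ensemble
    n_runs: int = 300
    n_jobs: int = 1
    ranges: dict = field(default_factory=dict)       # row -> [min, max]
    # steady stage
    D: float = 1.0
    U: float = 1.0
    d_grid: tuple = (0.75, 1.0, 1.25, 1.5, 1.75, 2.0)
    u_grid: tuple = (0.5, 1.0, 1.5, 2.0)
    t_climate_Ma: float = 541.0
    # single-run / steady parameter overrides (sampled-row names)
    parameters: dict = field(default_factory=dict)
    # options
    mocb_o2_dependence: bool = False
    capb_anoxia: bool = False
    rgf_o2_equivalent: float = 1.0
    # trend stage
    proxy_file: str | None = None
    proxy_kind: str = "d13C"
    bin_widths: tuple = (0.0, 5.0, 10.0)
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ConfigError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.seed < 0 or self.seed >= 2**31:
            raise ConfigError("seed must be a non-negative 31-bit integer")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        for name, bounds in self.ranges.items():
            if name not in CANONICAL_RANGES:
                raise ConfigError(f"unknown ensemble range key {name!r}")
            lo, hi = float(bounds[0]), float(bounds[1])
            clo, chi = CANONICAL_RANGES[name]
            if lo < clo - 1e-12 * abs(clo) or hi > chi + 1e-12 * abs(chi):
                raise ConfigError(
                    f"range override for {name!r} ([{lo:g}, {hi:g}]) lies outside "
                    f"the canonical uncertainty interval [{clo:g}, {chi:g}]"
                )
        for name in self.parameters:
            if name not in BASELINE_DRAW:
                raise ConfigError(f"unknown parameter override {name!r}")
        if self.window_file is not None and not Path(self.window_file).exists():
            raise ConfigError(f"window_file does not exist: {self.window_file}")
        if self.stage == "trend" and self.proxy_file is not None \
                and not Path(self.proxy_file).exists():
            raise ConfigError(f"proxy_file does not exist: {self.proxy_file}")

    # ---- assembly helpers -------------------------------------------------
    def parameter_ranges(self) -> ParameterRanges:
        merged = dict(CANONICAL_RANGES)
        merged.update({k: (float(v[0]), float(v[1])) for k, v in self.ranges.items()})
        return ParameterRanges(merged)

    def model_parameters(self):
        return default_parameters(
            **self.parameters,
            mocb_o2_dependence=self.mocb_o2_dependence,
            capb_anoxia=self.capb_anoxia,
            rgf_o2_equivalent=self.rgf_o2_equivalent,
        )

    def solver_options(self):
        from .model import SolverOptions

        return SolverOptions(
            method=self.solver.method, rtol=self.solver.rtol,
            atol=self.solver.atol, grid_Myr=self.solver.grid_Myr,
        )

    def echo(self) -> dict:
        """The fully resolved configuration, with provenance annotations."""
        cfg = dataclasses.asdict(self)
        cfg["ranges"] = {k: list(v) for k, v in self.parameter_ranges().items()}
        cfg["provenance"] = {
            "base_model_defaults": list(BASE_MODEL_DEFAULTS),
            "note": (
                "constants listed under base_model_defaults are adopted from "
                "the base biogeochemical model, not from this study's sampled "
                "uncertainty table"
            ),
        }
        return cfg


def _from_mapping(raw: dict) -> RunConfig:
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "solver" in kwargs and isinstance(kwargs["solver"], dict):
        solver_known = {f.name for f in dataclasses.fields(SolverConfig)}
        bad = set(kwargs["solver"]) - solver_known
        if bad:
            raise ConfigError(f"unknown solver keys: {sorted(bad)}")
        kwargs["solver"] = SolverConfig(**kwargs["solver"])
    for tup_key in ("d_grid", "u_grid", "bin_widths"):
        if tup_key in kwargs:
            kwargs[tup_key] = tuple(kwargs[tup_key])
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON, a YAML subset) configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    return _from_mapping(raw)
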