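"""External forcings and synthetic pseudo-proxy data.

The degassing forcing D(t) emulates a reconstruction of global
subduction-zone length: a step-like rise from late-Cryogenian to
early-Phanerozoic levels, carried as an uncertainty envelope
(``DegassingWindow``) from which each Monte-Carlo run samples a step
function, redrawn every 10 Myr.  The published curve is not available as
numbers, so the default window is an explicit synthetic stand-in (midline
1.1 -> 1.5 across 650 -> 541 Ma, half-width 0.1); users with a digitised
node table can supply it as CSV.

The uplift/erosion forcing U(t) is a linear ramp (default 0.5 -> 2.0 across
the run span), chosen to reproduce the magnitude of the observed rise in
seawater 87Sr/86Sr; setting ``u_start == u_end`` gives the constant-uplift
variant experiment.

``synthesize_proxy_series`` generates pseudo-proxy records (d13C / d34S /
87Sr-86Sr) with a configurable secular trend, boxcar excursions and
Gaussian noise, standing in for proxy compilations that are not freely
redistributable; the generating parameters are recorded so that trend-recovery
tests can compare against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: default transient span, Myr before present.  Runs start at 650 Ma so the
#: early averaging window (640-620 Ma) is covered, and end at 540 Ma so the
#: late window (560-540 Ma) is covered.
DEFAULT_T_START_MA = 650.0
DEFAULT_T_END_MA = 540.0
#: the uplift ramp reaches its end value at the era boundary
UPLIFT_RAMP_END_MA = 541.0


@dataclass(frozen=True)
class ForcingSnapshot:
    """External drivers at one instant (all relative to present = 1)."""

    D: float = 1.0        # tectonic degassing
    U: float = 1.0        # uplift / erosion
    PG: float = 1.0       # paleogeography weathering factor
    a_gran: float = 1.0   # granite land area
    a_bas: float = 1.0    # basalt land area
    a_carb: float = 1.0   # carbonate land area
    V: float = 0.0        # vegetation (off throughout the Precambrian)
    B: float = 1.0        # carbonate-burial forcing
    c_cal: float = 1.0    # calcium forcing

    def __post_init__(self) -> None:
        if self.D <= 0 or self.U <= 0:
            raise ValueError(f"forcings D, U must be positive (D={self.D}, U={self.U})")
        for name in ("PG", "a_gran", "a_bas", "a_carb", "B", "c_cal"):
            if getattr(self, name) < 0:
                raise ValueError(f"forcing {name} must be non-negative")


def uplift_forcing(
    t_Ma: float,
    t_start_Ma: float = DEFAULT_T_START_MA,
    t_end_Ma: float = UPLIFT_RAMP_END_MA,
    u_start: float = 0.5,
    u_end: float = 2.0,
) -> float:
    """Linear uplift ramp between ``u_start`` at ``t_start_Ma`` and ``u_end``
    at ``t_end_Ma`` (time in Myr before present, decreasing toward 0)."""
    if not (t_end_Ma <= t_Ma <= t_start_Ma):
        raise ValueError(
            f"t={t_Ma} Ma outside the forcing span [{t_end_Ma}, {t_start_Ma}] Ma"
        )
    frac = (t_start_Ma - t_Ma) / (t_start_Ma - t_end_Ma) if t_start_Ma != t_end_Ma else 0.0
    return u_start + (u_end - u_start) * frac


@dataclass(frozen=True)
class DegassingWindow:
    """Uncertainty envelope for the degassing forcing.

    ``node_times`` are strictly decreasing ages (Myr before present);
    the envelope is linearly interpolated between nodes.
    """

    node_times: tuple[float, ...]
    d_min: tuple[float, ...]
    d_max: tuple[float, ...]
    resample_interval: float = 10.0  # Myr

    def __post_init__(self) -> None:
        t = np.asarray(self.node_times, dtype=float)
        lo = np.asarray(self.d_min, dtype=float)
        hi = np.asarray(self.d_max, dtype=float)
        if t.size == 0:
            raise ValueError("degassing window has no nodes")
        if not (t.size == lo.size == hi.size):
            raise ValueError("node_times, d_min, d_max must have equal length")
        if t.size > 1 and not np.all(np.diff(t) < 0):
            raise ValueError("node_times must be strictly decreasing ages")
        if np.any(lo <= 0) or np.any(hi <= 0):
            raise ValueError("degassing bounds must be positive")
        if np.any(lo > hi):
            raise ValueError("d_min must not exceed d_max")
        if self.resample_interval <= 0:
            raise ValueError("resample_interval must be positive")

    def _interp(self, values: Sequence[float], t_Ma: float) -> float:
        # np.interp needs increasing x; ages decrease
        t = np.asarray(self.node_times, dtype=float)
        return float(np.interp(-t_Ma, -t, np.asarray(values, dtype=float)))

    def bounds(self, t_Ma: float) -> tuple[float, float]:
        return self._interp(self.d_min, t_Ma), self._interp(self.d_max, t_Ma)

    def midline(self, t_Ma: float) -> float:
        lo, hi = self.bounds(t_Ma)
        return 0.5 * (lo + hi)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, resample_interval: float = 10.0):
        frame = frame.sort_values("t_Ma", ascending=False)
        return cls(
            node_times=tuple(frame["t_Ma"]),
            d_min=tuple(frame["d_min"]),
            d_max=tuple(frame["d_max"]),
            resample_interval=resample_interval,
        )

    @classmethod
    def from_csv(cls, path, resample_interval: float = 10.0):
        return cls.from_frame(pd.read_csv(path), resample_interval=resample_interval)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_Ma": self.node_times, "d_min": self.d_min, "d_max": self.d_max}
        )


def default_ediacaran_window(
    t_start_Ma: float = DEFAULT_T_START_MA,
    t_end_Ma: float = DEFAULT_T_END_MA,
    half_width: float = 0.1,
) -> DegassingWindow:
    """The package-default synthetic degassing envelope.

    Relative degassing rises monotonically from ~1.0-1.2 at 650 Ma to
    ~1.4-1.6 at 541 Ma (a ~40-60% rise in the midline across the Ediacaran),
    an explicit approximation of the subduction-length reconstruction which
    is not available numerically.
    """
    nodes = np.arange(t_start_Ma, t_end_Ma - 1e-9, -10.0)
    if nodes[-1] != t_end_Ma:
        nodes = np.append(nodes, t_end_Ma)
    mid = 1.1 + 0.4 * (t_start_Ma - nodes) / (t_start_Ma - UPLIFT_RAMP_END_MA)
    return DegassingWindow(
        node_times=tuple(nodes),
        d_min=tuple(mid - half_width),
        d_max=tuple(mid + half_width),
    )


@dataclass(frozen=True)
class DegassingPath:
    """One sampled degassing realisation: a step function on 10-Myr segments."""

    boundaries: tuple[float, ...]  # decreasing ages; len = n_segments + 1
    values: tuple[float, ...]      # one D per segment
    blend: bool = False            # linear blending between segment midpoints

    def __call__(self, t_Ma: float) -> float:
        b = np.asarray(self.boundaries)
        if not (b[-1] - 1e-9 <= t_Ma <= b[0] + 1e-9):
            raise ValueError(f"t={t_Ma} Ma outside the sampled path span")
        if self.blend:
            mids = 0.5 * (b[:-1] + b[1:])
            return float(np.interp(-t_Ma, -mids, np.asarray(self.values)))
        idx = int(np.searchsorted(-b, -t_Ma, side="right") - 1)
        idx = min(max(idx, 0), len(self.values) - 1)
        return self.values[idx]

    @property
    def discontinuities(self) -> tuple[float, ...]:
        """Interior segment boundaries (integration restart points)."""
        return () if self.blend else self.boundaries[1:-1]


def sample_degassing_path(
    window: DegassingWindow,
    rng: np.random.Generator,
    t_start_Ma: float = DEFAULT_T_START_MA,
    t_end_Ma: float = DEFAULT_T_END_MA,
    blend: bool = False,
) -> DegassingPath:
    """Draw one step-function degassing path from the envelope.

    One uniform draw per ``resample_interval`` segment, evaluated at the
    segment midpoint, held constant within the segment.
    """
    step = window.resample_interval
    bounds = list(np.arange(t_start_Ma, t_end_Ma, -step)) + [t_end_Ma]
    values = []
    for hi_t, lo_t in zip(bounds[:-1], bounds[1:]):
        lo, hi = window.bounds(0.5 * (hi_t + lo_t))
        values.append(float(rng.uniform(lo, hi)) if hi > lo else 0.5 * (lo + hi))
    return DegassingPath(boundaries=tuple(bounds), values=tuple(values), blend=blend)


class ConstantForcing:
    """Time-independent forcing provider (steady-state experiments)."""

    def __init__(self, **kwargs) -> None:
        self.snapshot = ForcingSnapshot(**kwargs)
        self.discontinuities: tuple[float, ...] = ()

    def __call__(self, t_Ma: float) -> ForcingSnapshot:
        return self.snapshot


class EdiacaranForcing:
    """Transient forcing provider: sampled degassing path + uplift ramp.

    Pure function of (t, path, ramp parameters); land-area, paleogeography and
    carbonate forcings are held at present-day values and vegetation is off.
    """

    def __init__(
        self,
        degassing_path: DegassingPath,
        t_start_Ma: float = DEFAULT_T_START_MA,
        t_end_Ma: float = DEFAULT_T_END_MA,
        u_start: float = 0.5,
        u_end: float = 2.0,
        u_ramp_end_Ma: float = UPLIFT_RAMP_END_MA,
    ) -> None:
        self.degassing_path = degassing_path
        self.t_start_Ma = t_start_Ma
        self.t_end_Ma = t_end_Ma
        self.u_start = u_start
        self.u_end = u_end
        self.u_ramp_end_Ma = u_ramp_end_Ma
        self.discontinuities = tuple(
            t for t in degassing_path.discontinuities if t_end_Ma < t < t_start_Ma
        )

    def __call__(self, t_Ma: float) -> ForcingSnapshot:
        # the ramp holds its end value over any post-boundary tail
        t_ramp = max(t_Ma, self.u_ramp_end_Ma)
        u = uplift_forcing(
            t_ramp, self.t_start_Ma, self.u_ramp_end_Ma, self.u_start, self.u_end
        )
        return ForcingSnapshot(D=self.degassing_path(t_Ma), U=u)


# ---------------------------------------------------------------------------
# synthetic pseudo-proxy records
# ---------------------------------------------------------------------------

PROXY_KINDS = ("d13C", "d34S", "sr")


@dataclass(frozen=True)
class ProxySeries:
    """A proxy record: (age, value) pairs with generator metadata."""

    kind: str
    frame: pd.DataFrame = field(repr=False)  # columns: age_Ma, value
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PROXY_KINDS:
            raise ValueError(f"kind must be one of {PROXY_KINDS}, got {self.kind!r}")
        if not {"age_Ma", "value"} <= set(self.frame.columns):
            raise ValueError("proxy frame needs columns age_Ma, value")
        if not np.all(np.isfinite(self.frame["value"])):
            raise ValueError("proxy values must be finite")

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age_Ma"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path, kind: str = "d13C") -> "ProxySeries":
        return cls(kind=kind, frame=pd.read_csv(path))


def synthesize_proxy_series(
    kind: str = "d13C",
    trend_per_Myr: float = 0.0,
    intercept: float = 0.0,
    noise_sd: float = 1.0,
    n_points: int = 500,
    age_span: tuple[float, float] = (1000.0, 541.0),
    excursions: Sequence[tuple[float, float, float]] = (),
    seed: int | np.random.Generator = 0,
) -> ProxySeries:
    """Generate a pseudo-proxy record with known ground truth.

    ``value(age) = intercept + trend_per_Myr * (old_end - age) + excursions
    + N(0, noise_sd)``, with ages drawn uniformly over ``age_span``.  A
    positive ``trend_per_Myr`` therefore means values increasing toward the
    present.  ``excursions`` are boxcars ``(centre_age, half_width,
    amplitude)`` emulating superimposed isotope excursions.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    old, young = max(age_span), min(age_span)
    if old == young:
        raise ValueError("age_span must have nonzero extent")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages = np.sort(rng.uniform(young, old, size=n_points))[::-1]
    values = intercept + trend_per_Myr * (old - ages)
    for centre, half_width, amplitude in excursions:
        values = values + amplitude * (np.abs(ages - centre) <= half_width)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_points)
    frame = pd.DataFrame({"age_Ma": ages, "value": values})
    meta = {
        "trend_per_Myr": trend_per_Myr,
        "intercept": intercept,
        "noise_sd": noise_sd,
        "age_span": (old, young),
        "excursions": tuple(excursions),
        "total_change": trend_per_Myr * (old - young),
    }
    return ProxySeries(kind=kind, frame=frame, metadata=meta)
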