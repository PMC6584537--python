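"""Secular-trend regression of proxy records.

Ordinary least squares of proxy value on age, on the raw record and on
records binned into fixed-width (5 or 10 Myr) groups.  The slope is
reported per Myr *toward the present*: a positive slope means values
increasing as age decreases.  Bins are anchored at the old end of the
record's span and empty bins are dropped; bin means are unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .forcings import ProxySeries


@dataclass(frozen=True)
class TrendFit:
    slope: float            # per Myr, positive = increase toward the present
    intercept: float        # value at age 0 under the fitted line
    slope_stderr: float
    p_value: float          # two-sided t-test on the slope
    ci_low: float           # 95% CI on the slope
    ci_high: float
    n_used: int
    bin_width_Myr: float    # 0 = raw data
    span_Myr: float
    total_change: float     # slope * span

    def summary(self) -> dict:
        return {
            "slope_per_Myr": self.slope,
            "slope_stderr": self.slope_stderr,
            "p_value": self.p_value,
            "ci95_low": self.ci_low,
            "ci95_high": self.ci_high,
            "n_used": self.n_used,
            "bin_width_Myr": self.bin_width_Myr,
            "span_Myr": self.span_Myr,
            "total_change": self.total_change,
        }


def bin_series(series: ProxySeries, width_Myr: float) -> ProxySeries:
    """Average a record into fixed-width age bins.

    Bins are anchored at the oldest age; each non-empty bin contributes
    (bin-midpoint age, unweighted mean value, count).
    """
    if width_Myr <= 0:
        raise ValueError("bin width must be positive")
    if len(series) == 0:
        raise ValueError("cannot bin an empty series")
    ages = series.ages
    old = ages.max()
    idx = np.floor((old - ages) / width_Myr).astype(int)
    # points exactly at the young edge of the span join the last covered bin
    span = old - ages.min()
    n_bins = max(1, int(np.ceil(span / width_Myr)))
    idx = np.minimum(idx, n_bins - 1)
    frame = pd.DataFrame({"bin": idx, "value": series.values})
    grouped = frame.groupby("bin")["value"].agg(["mean", "count"]).reset_index()
    mid_ages = old - (grouped["bin"] + 0.5) * width_Myr
    binned = pd.DataFrame(
        {"age_Ma": mid_ages, "value": grouped["mean"], "n": grouped["count"]}
    ).sort_values("age_Ma", ascending=False, ignore_index=True)
    meta = dict(series.metadata)
    meta["binned_from_n"] = len(series)
    meta["bin_width_Myr"] = width_Myr
    return ProxySeries(kind=series.kind, frame=binned, metadata=meta)


def fit_trend(series: ProxySeries, bin_width_Myr: float = 0.0) -> TrendFit:
    """OLS secular trend of a proxy record (optionally binned first)."""
    if bin_width_Myr > 0:
        series = bin_series(series, bin_width_Myr)
    ages = series.ages
    values = series.values
    if len(ages) < 3:
        raise ValueError("trend fit needs at least 3 points")
    if np.unique(ages).size < 2:
        raise ValueError("trend fit needs at least 2 distinct ages")
    X = sm.add_constant(ages)
    fit = sm.OLS(values, X).fit()
    # regression is on age; the reported slope is per Myr toward the present
    slope = -float(fit.params[1])
    ci = fit.conf_int(alpha=0.05)
    ci_low, ci_high = -float(ci[1][1]), -float(ci[1][0])
    span = float(ages.max() - ages.min())
    return TrendFit(
        slope=slope,
        intercept=float(fit.params[0]),
        slope_stderr=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        ci_low=ci_low,
        ci_high=ci_high,
        n_used=len(ages),
        bin_width_Myr=bin_width_Myr,
        span_Myr=span,
        total_change=slope * span,
    )


def fit_report(series: ProxySeries, widths: tuple[float, ...] = (0.0, 5.0, 10.0)) -> pd.DataFrame:
    """The standard report: whole-dataset fit plus 5- and 10-Myr-binned fits."""
    rows = []
    for w in widths:
        fit = fit_trend(series, bin_width_Myr=w)
        rows.append({"kind": series.kind, **fit.summary()})
    return pd.DataFrame(rows)
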