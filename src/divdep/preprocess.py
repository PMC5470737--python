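"""From purchase events to the preprocessed divorce-centred prevalence series.

Pipeline: bin individual purchases into 3-month prevalences (several
purchases by one individual in a bin count once), remove the never-divorced
stratum's linear secular trend from the divorced stratum's divorce-centred
series, subtract the resulting minimum so the series touches zero, and
attach Wald confidence intervals to raw prevalences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .series import BIN_MONTHS, PrevalenceSeries, divorce_centred_grid
from .synth import PurchaseTable


def bin_prevalence(
    purchases: PurchaseTable,
    centring: str = "divorce",
    window: tuple[float, float] | None = None,
) -> PrevalenceSeries:
    """Per-bin proportion of individuals with at least one purchase.

    ``centring="divorce"``: only divorced individuals contribute; purchase
    times are re-expressed relative to each individual's divorce month and
    binned on the divorce-centred lattice over ``window`` (default -60..+60,
    41 bins). ``centring="calendar"``: never-divorced individuals, calendar
    bins over the study span. Bins are half-open [t, t+3), labelled by the
    left edge; every contributing individual counts in every bin's
    denominator (the synthetic register has no attrition).
    """
    persons = purchases.persons
    merged = purchases.purchases.merge(
        persons[["person_id", "divorce_month"]], on="person_id", how="left"
    )
    if centring == "divorce":
        if window is None:
            window = (-60.0, 60.0)
        grid = divorce_centred_grid(window)
        contrib = persons["divorce_month"].notna()
        n_contrib = int(contrib.sum())
        if n_contrib == 0:
            raise ValueError("no divorced individuals contribute to a divorce-centred series")
        rows = merged[merged["divorce_month"].notna()]
        rel = rows["purchase_month"].to_numpy() - rows["divorce_month"].to_numpy()
        pid = rows["person_id"].to_numpy()
    elif centring == "calendar":
        if window is not None and (window[0] % BIN_MONTHS or window[1] % BIN_MONTHS):
            raise ValueError("window endpoints must be multiples of the 3-month bin width")
        hi = purchases.study_months if window is None else window[1]
        lo = 0.0 if window is None else window[0]
        grid = np.arange(lo, hi, BIN_MONTHS)
        contrib = persons["divorce_month"].isna()
        n_contrib = int(contrib.sum())
        if n_contrib == 0:
            raise ValueError("no never-divorced individuals contribute to a calendar series")
        rows = merged[merged["divorce_month"].isna()]
        rel = rows["purchase_month"].to_numpy()
        pid = rows["person_id"].to_numpy()
    else:
        raise ValueError(f"unknown centring {centring!r}")

    # half-open bins [t, t+3): a purchase at rel month r falls in bin floor(r/3)*3
    bin_left = np.floor(rel / BIN_MONTHS) * BIN_MONTHS
    inside = (bin_left >= grid[0]) & (bin_left <= grid[-1])
    bin_idx = ((bin_left[inside] - grid[0]) / BIN_MONTHS).astype(int)
    # distinct individuals per bin: dedupe (person, bin) pairs
    pairs = np.unique(np.stack([pid[inside], bin_idx]), axis=1)
    counts = np.bincount(pairs[1].astype(int), minlength=grid.size)
    values = counts / n_contrib
    denominators = np.full(grid.size, n_contrib, dtype=float)
    return PrevalenceSeries(grid, values, denominators, centring=centring, preprocessed=False)


def control_trend_slope(control: PrevalenceSeries) -> float:
    """OLS slope (per month) of the calendar-time control series."""
    if control.n < 3:
        raise ValueError("control series needs at least 3 points")
    t = control.times
    if np.ptp(t) == 0:
        raise ValueError("degenerate control series: constant time")
    X = sm.add_constant(t)
    return float(sm.OLS(control.values, X).fit().params[1])


def detrend_and_baseline(
    divorced: PrevalenceSeries, control: PrevalenceSeries
) -> PrevalenceSeries:
    """Remove the control stratum's linear trend, then subtract the minimum.

    The slope is fitted in calendar time but removed as a function of
    divorce-centred time (slope per month x centred month); the subsequent
    minimum subtraction makes the output touch zero exactly, matching the
    convention that the fitted models predict excess purchasing above the
    divorcees' own baseline.
    """
    if divorced.centring != "divorce":
        raise ValueError("first argument must be a divorce-centred series")
    beta = control_trend_slope(control)
    detrended = divorced.values - beta * divorced.times
    detrended = detrended - detrended.min()
    return divorced.copy_with(values=detrended, preprocessed=True)


Z_95 = 1.959964


def wald_interval(p: float, n: float, level: float = 0.95) -> tuple[float, float]:
    """Wald binomial interval p +/- z * sqrt(p(1-p)/n), truncated to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if not 0.0 < level < 1.0:
        if level == 1.0:
            return (0.0, 1.0)
        raise ValueError("confidence level must lie in (0, 1]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def read_prevalence_csv(
    path,
    column_map: dict[str, str] | None = None,
    centring: str = "divorce",
) -> PrevalenceSeries:
    """Read a prevalence series CSV, adapting to foreign header names.

    ``column_map`` maps the canonical names (time_months, prevalence,
    denominator) to the file's column names. Whether the file holds raw or
    already-preprocessed values is detected from the values themselves
    (negative or zero-minimum values indicate a detrended, baseline-
    subtracted series); a missing denominator column yields zeros.
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return PrevalenceSeries.from_frame(df, centring=centring)
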