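"""Day-of-year climatologies, summer-regime detection and snow offsets.

The seasonal development of each surface-energy-budget variable is
summarized per vegetation type: daily values are averaged per site across
years for each day of year (DOY, leap days dropped so every year maps to
DOY 1-365), then averaged (mean +/- s.e.) across the type's sites, and
smoothed with a centered 15-day circular moving average.

The "summer regime" of a smoothed curve is the longest contiguous run of
days on which the variable exceeds 0 (W m-2 for R_net, H, G; degC for
surface temperature) or, for albedo, stays below the midpoint of the
smoothed curve's annual minimum and maximum.  Latent heat is excluded by
policy since it stays positive essentially year-round.  Regime start and
end dates are compared with the vegetation type's snow-free and snow-onset
dates, and offsets are tested across types with Welch t-tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SMOOTH_WINDOW = 15
#: Minimum non-missing days inside a smoothing window.
SMOOTH_MIN_PRESENT = 8

#: Variables whose summer regime is "above zero".
ABOVE_ZERO_VARS = ("R_net", "H", "G", "T_surf")


def _doy365(dates: pd.Series) -> pd.Series:
    """DOY on a 365-day axis; Feb 29 returns NaN (dropped by callers)."""
    doy = dates.dt.dayofyear.astype(float)
    leap = dates.dt.is_leap_year
    feb29 = leap & (dates.dt.month == 2) & (dates.dt.day == 29)
    doy = doy.where(~(leap & (doy > 59)), doy - 1)
    return doy.mask(feb29)


def doy_climatology(
    daily: pd.DataFrame,
    metadata: pd.DataFrame,
    variables: tuple[str, ...],
    year_min: int = 2000,
    year_max: int | None = None,
    exclude_types: tuple[str, ...] = ("barren",),
) -> pd.DataFrame:
    """Per-vegetation-type DOY climatology (mean +/- s.e. across sites).

    Returns a long frame: vegetation_type, variable, doy, mean, se,
    n_sites, n_site_years.
    """
    df = daily.merge(
        metadata[["site_id", "vegetation_type"]], on="site_id", how="inner"
    )
    df = df[~df["vegetation_type"].isin(exclude_types)]
    dates = pd.to_datetime(df["date"])
    df = df.assign(year=dates.dt.year, doy=_doy365(dates))
    df = df[df["year"] >= year_min]
    if year_max is not None:
        df = df[df["year"] <= year_max]
    df = df.dropna(subset=["doy"])
    df["doy"] = df["doy"].astype(int)

    rows = []
    for var in variables:
        if var not in df.columns:
            continue
        site_doy = (
            df.groupby(["vegetation_type", "site_id", "doy"])[var]
            .agg(["mean", "count"])
            .reset_index()
        )
        grp = site_doy.groupby(["vegetation_type", "doy"])["mean"]
        out = grp.agg(["mean", "std", "count"]).reset_index()
        yrs = site_doy.groupby(["vegetation_type", "doy"])["count"].sum().reset_index()
        out = out.merge(yrs, on=["vegetation_type", "doy"])
        out["se"] = out["std"] / np.sqrt(out["count_x"])
        rows.append(
            pd.DataFrame(
                {
                    "vegetation_type": out["vegetation_type"],
                    "variable": var,
                    "doy": out["doy"],
                    "mean": out["mean"],
                    "se": out["se"].fillna(0.0),
                    "n_sites": out["count_x"],
                    "n_site_years": out["count_y"],
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["vegetation_type", "variable", "doy", "mean", "se", "n_sites", "n_site_years"]
        )
    return pd.concat(rows, ignore_index=True)


def smooth_15d(values: np.ndarray, window: int = SMOOTH_WINDOW,
               min_present: int = SMOOTH_MIN_PRESENT) -> np.ndarray:
    """Centered circular moving average on a DOY 1..365 series.

    The window wraps across the year boundary (DOY 1 neighbors DOY 365).
    Missing values inside a window are ignored; a smoothed value requires at
    least ``min_present`` non-missing days in its window.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    half = window // 2
    finite = np.isfinite(x)
    xz = np.where(finite, x, 0.0)
    num = np.zeros(n)
    cnt = np.zeros(n)
    for k in range(-half, half + 1):
        num += np.roll(xz, -k)
        cnt += np.roll(finite.astype(float), -k)
    out = np.where(cnt >= min(min_present, window), num / np.maximum(cnt, 1), np.nan)
    return out


def smooth_curves(climatology: pd.DataFrame) -> pd.DataFrame:
    """Smooth every (vegetation type, variable) curve of a climatology frame.

    Curves are aligned to the full DOY 1..365 axis before smoothing; the
    output carries a ``smoothed`` column alongside the raw mean.
    """
    full = np.arange(1, 366)
    parts = []
    for (vt, var), g in climatology.groupby(["vegetation_type", "variable"], sort=False):
        g = g.set_index("doy").reindex(full)
        g["vegetation_type"] = vt
        g["variable"] = var
        g["smoothed"] = smooth_15d(g["mean"].to_numpy())
        g["se_smoothed"] = smooth_15d(g["se"].to_numpy())
        parts.append(g.rename_axis("doy").reset_index())
    return pd.concat(parts, ignore_index=True)


def detect_summer_regime(
    doy: np.ndarray, smoothed: np.ndarray, variable: str
) -> tuple[float, float] | None:
    """Start/end DOY of the summer regime of one smoothed curve.

    For fluxes and surface temperature the condition is value > 0; for
    albedo it is value < (annual min + annual max)/2 of the smoothed curve.
    The regime is the longest contiguous run of days satisfying the
    condition; returns None when no day qualifies.
    """
    doy = np.asarray(doy)
    y = np.asarray(smoothed, dtype=float)
    if variable == "albedo":
        lo, hi = np.nanmin(y), np.nanmax(y)
        cond = y < 0.5 * (lo + hi)
    elif variable == "LE":
        raise ValueError("latent heat is excluded from summer-regime detection")
    else:
        cond = y > 0.0
    cond = cond & np.isfinite(y)
    if not cond.any():
        return None
    padded = np.concatenate(([False], cond, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[0::2], edges[1::2] - 1
    longest = np.argmax(ends - starts)
    return float(doy[starts[longest]]), float(doy[ends[longest]])


def snow_dates_by_type(
    phenology: pd.DataFrame,
    metadata: pd.DataFrame,
    year_min: int = 2000,
    year_max: int = 2020,
) -> pd.DataFrame:
    """Type-level snow-free and snow-onset DOY.

    Per-site medians across ``year_min``..``year_max`` are averaged across
    the sites of each vegetation type.
    """
    ph = phenology[(phenology["year"] >= year_min) & (phenology["year"] <= year_max)]
    site_med = ph.groupby("site_id")[["snow_free_doy", "snow_onset_doy"]].median()
    merged = site_med.reset_index().merge(
        metadata[["site_id", "vegetation_type"]], on="site_id"
    )
    return (
        merged.groupby("vegetation_type")[["snow_free_doy", "snow_onset_doy"]]
        .mean()
        .reset_index()
    )


def regime_offsets(
    smoothed_curves: pd.DataFrame,
    type_snow_dates: pd.DataFrame,
    variables: tuple[str, ...] = ("R_net", "H", "G", "T_surf", "albedo"),
) -> pd.DataFrame:
    """Summer-regime timing relative to snow dates, per type and variable.

    ``start_offset = start_doy - snow_free_doy`` (negative: the regime
    starts before the surface is snow-free); ``end_offset = end_doy -
    snow_onset_doy``.  Types without snow phenology are skipped.
    """
    snow = type_snow_dates.set_index("vegetation_type")
    rows = []
    for (vt, var), g in smoothed_curves.groupby(["vegetation_type", "variable"], sort=False):
        if var not in variables or vt not in snow.index:
            continue
        regime = detect_summer_regime(
            g["doy"].to_numpy(), g["smoothed"].to_numpy(), var
        )
        if regime is None:
            continue
        start, end = regime
        free = float(snow.loc[vt, "snow_free_doy"])
        onset = float(snow.loc[vt, "snow_onset_doy"])
        rows.append(
            {
                "vegetation_type": vt,
                "variable": var,
                "start_doy": start,
                "end_doy": end,
                "snow_free_doy": free,
                "snow_onset_doy": onset,
                "start_offset": start - free,
                "end_offset": end - onset,
            }
        )
    return pd.DataFrame(rows)


def welch_offset_test(group_a, group_b) -> tuple[float, float, float]:
    """Two-sample Welch t-test: statistic, Satterthwaite df, two-sided p.

    Used to compare regime-timing DOYs against snow DOYs across vegetation
    types.  Degenerate zero-variance samples with equal means return
    ``(0, n_a + n_b - 2, 1)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return np.inf, float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    na, nb = len(a), len(b)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)
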