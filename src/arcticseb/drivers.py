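"""Site-level drivers of the surface energy budget.

Assembles the 15-driver table used by the variance-partitioning analysis:
five categorical drivers taken from site metadata (vegetation type, CAVM
type, CAVM subzone, permafrost extent, permafrost ground-ice content) and
ten numeric drivers, of which four are computed here from climate and snow
series (Conrad continentality, summer warmth index, snow amount, snow
duration) and the rest are read from metadata (mean annual temperature and
precipitation, cloud cover, cloud-top temperature, latitude, altitude).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORICAL_DRIVERS = (
    "vegetation_type",
    "cavm_type",
    "cavm_subzone",
    "permafrost_extent",
    "permafrost_ice",
)
NUMERIC_DRIVERS = (
    "temperature",
    "summer_warmth",
    "continentality",
    "precipitation",
    "snow_amount",
    "snow_duration",
    "cloud_cover",
    "cloud_temperature",
    "latitude",
    "altitude",
)
ALL_DRIVERS = CATEGORICAL_DRIVERS + NUMERIC_DRIVERS

#: Season windows (inclusive DOY bounds) used to locate snow transitions:
#: the spring search covers DOY 1-212, the autumn search DOY 182-366, so a
#: brief midsummer snow event cannot masquerade as the seasonal transition.
SPRING_WINDOW = (1, 212)
AUTUMN_WINDOW = (182, 366)


def conrad_continentality(
    monthly_temperature, latitude_deg: float, angle_unit: str = "degrees"
) -> float:
    """Conrad continentality index from monthly mean air temperatures.

    ``CCI = 1.7 * (T_max - T_min) / sin(phi + 10 deg) - 14`` where T_max and
    T_min are the warmest- and coldest-month mean temperatures and phi is
    latitude.  The classical formulation evaluates the sine with the
    latitude-plus-10 offset in degrees; set ``angle_unit="radians"`` to add
    the offset to a latitude expressed in radians instead (not recommended;
    kept switchable because some texts print the formula that way).

    Accepts a 12-vector (one climatological year) or an (n_years, 12) array;
    multi-year input returns the across-year mean of yearly indices.
    """
    t = np.atleast_2d(np.asarray(monthly_temperature, dtype=float))
    if t.shape[1] != 12:
        raise ValueError(f"need 12 monthly means per year, got shape {t.shape}")
    if angle_unit == "degrees":
        s = np.sin(np.deg2rad(latitude_deg + 10.0))
    elif angle_unit == "radians":
        s = np.sin(np.deg2rad(latitude_deg) + 10.0)
    else:
        raise ValueError(f"angle_unit must be 'degrees' or 'radians', got {angle_unit!r}")
    if s == 0.0:
        raise ValueError(f"sin(lat + 10) is zero at latitude {latitude_deg}")
    yearly = 1.7 * (t.max(axis=1) - t.min(axis=1)) / s - 14.0
    return float(yearly.mean())


def summer_warmth_index(monthly_temperature) -> float:
    """Summer warmth index: annual sum of monthly means above 0 degC.

    Multi-year input ((n_years, 12)) returns the across-year mean.
    """
    t = np.atleast_2d(np.asarray(monthly_temperature, dtype=float))
    if t.shape[1] != 12:
        raise ValueError(f"need 12 monthly means per year, got shape {t.shape}")
    yearly = np.clip(t, 0.0, None).sum(axis=1)
    return float(yearly.mean())


def snow_amount(daily_temperature, daily_precip, years=None) -> float:
    """Annual snow water equivalent: precipitation on days with T <= 0 degC.

    The 0 degC bound is inclusive.  With a ``years`` vector the snowfall is
    summed per year and averaged across years; otherwise the total is scaled
    by 365.25/n_days to an annual rate (mm per year).
    """
    t = np.asarray(daily_temperature, dtype=float)
    p = np.asarray(daily_precip, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: T has {t.shape}, precip has {p.shape}")
    snow = np.where(t <= 0.0, p, 0.0)
    if years is None:
        return float(snow.sum() * 365.25 / len(t))
    yearly = pd.Series(snow).groupby(np.asarray(years)).sum()
    return float(yearly.mean())


def _transitions(doys: np.ndarray, cats: np.ndarray, lo: int, hi: int, kind: str):
    """(snow-side DOY, no-snow-side DOY) of category transitions in a window.

    ``kind="melt"`` finds snow -> no-snow transitions, ``kind="onset"``
    no-snow -> snow, scanning consecutive *observed* days (missing days may
    separate the two sides of a transition).
    """
    inside = (doys >= lo) & (doys <= hi)
    d, c = doys[inside], cats[inside]
    out = []
    for i in range(len(d) - 1):
        if kind == "melt" and c[i] == "snow" and c[i + 1] == "no snow":
            out.append((d[i], d[i + 1]))
        elif kind == "onset" and c[i] == "no snow" and c[i + 1] == "snow":
            out.append((d[i + 1], d[i]))
    return out


def snow_phenology(daily_snow: pd.DataFrame) -> pd.DataFrame:
    """Per site-year snow-free date, snow-onset date and snow duration.

    Input columns: ``site_id``, ``date``, ``category`` ("snow"/"no snow").
    The spring snow-free date is the mean of the DOY of the last spring
    "snow" day and of the first following "no snow" day (the *last* melt
    transition inside the spring window), the autumn snow-onset date the
    mean of the last autumn "no snow" day and the first "snow" day (the
    *first* onset transition inside the autumn window).  Years without a
    usable transition are returned with missing values.
    """
    df = daily_snow.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year
    doy = dates.dt.dayofyear.to_numpy(dtype=float)
    df["doy"] = np.where(dates.dt.is_leap_year & (doy > 59), doy - 1.0, doy)

    rows = []
    for (site, year), g in df.groupby(["site_id", "year"], sort=True):
        g = g.sort_values("doy")
        doys = g["doy"].to_numpy()
        cats = g["category"].to_numpy()
        melts = _transitions(doys, cats, *SPRING_WINDOW, kind="melt")
        onsets = _transitions(doys, cats, *AUTUMN_WINDOW, kind="onset")
        free = float(np.mean(melts[-1])) if melts else np.nan
        onset = float(np.mean(onsets[0])) if onsets else np.nan
        if np.isfinite(free) and np.isfinite(onset) and not free < onset:
            # a transient event in the window overlap produced an inverted
            # pair: the year carries no usable phenology
            free = onset = np.nan
        rows.append(
            {
                "site_id": site,
                "year": year,
                "snow_free_doy": free,
                "snow_onset_doy": onset,
                "duration": onset - free,
            }
        )
    return pd.DataFrame(rows)


def monthly_means(climate: pd.DataFrame) -> pd.DataFrame:
    """Per site-year-month mean air temperature from a daily climate table."""
    df = climate.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year
    df["month"] = dates.dt.month
    return (
        df.groupby(["site_id", "year", "month"], sort=True)["t_air"]
        .mean()
        .reset_index()
    )


def assemble_driver_table(
    metadata: pd.DataFrame,
    climate: pd.DataFrame,
    daily_snow: pd.DataFrame,
) -> pd.DataFrame:
    """Build the 15-driver table, one row per site.

    Categorical drivers, cloud drivers, latitude and altitude come from
    ``metadata``; temperature, precipitation, summer warmth, continentality
    and snow amount are computed from the daily ``climate`` series; snow
    duration is the per-site median of yearly durations from ``daily_snow``.
    """
    monthly = monthly_means(climate)
    clim_rows = []
    for site, g in climate.groupby("site_id", sort=True):
        dates = pd.to_datetime(g["date"])
        years = dates.dt.year.to_numpy()
        m = monthly[monthly["site_id"] == site]
        tmat = m.pivot_table(index="year", columns="month", values="t_air")
        tmat = tmat.dropna()  # complete years only
        lat = float(metadata.loc[metadata["site_id"] == site, "latitude"].iloc[0])
        n_years = years.max() - years.min() + 1
        clim_rows.append(
            {
                "site_id": site,
                "temperature": float(g["t_air"].mean()),
                "precipitation": float(g["precip"].sum() / n_years),
                "summer_warmth": summer_warmth_index(tmat.to_numpy()),
                "continentality": conrad_continentality(tmat.to_numpy(), lat),
                "snow_amount": snow_amount(
                    g["t_air"].to_numpy(), g["precip"].to_numpy(), years
                ),
            }
        )
    clim = pd.DataFrame(clim_rows)

    pheno = snow_phenology(daily_snow)
    dur = (
        pheno.groupby("site_id")["duration"].median().rename("snow_duration")
    ).reset_index()

    table = (
        metadata[
            ["site_id", "latitude", "altitude", "cloud_cover", "cloud_temperature"]
            + list(CATEGORICAL_DRIVERS)
        ]
        .merge(clim, on="site_id", how="left")
        .merge(dur, on="site_id", how="left")
    )
    missing = set(ALL_DRIVERS) - set(table.columns)
    if missing:
        raise ValueError(f"driver table incomplete, missing {sorted(missing)}")
    return table[["site_id", *ALL_DRIVERS]]
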