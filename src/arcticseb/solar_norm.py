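"""Potential incoming shortwave radiation and flux normalization.

Daily surface-energy fluxes can be expressed as a percentage of the day's
maximum potential incoming shortwave radiation, which removes the first-order
latitudinal/seasonal gradient in available solar energy.  "Potential" here is
top-of-atmosphere irradiance on a horizontal surface at the day's minimum
solar zenith angle (i.e. at true solar noon); no atmospheric transmissivity
or horizon shading is modelled, since the normalization only requires a
consistent astronomical scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Solar constant, W m^-2.
SOLAR_CONSTANT = 1361.0

#: Fluxes that get an "n."-prefixed normalized counterpart.
NORMALIZABLE = ("R_net", "SW_net", "LW_net", "H", "LE", "G")

#: Minimum potential irradiance for a defined normalized flux (numerical
#: guard near polar night).
SPOT_FLOOR = 1.0


def solar_declination(doy: np.ndarray | float) -> np.ndarray | float:
    """Solar declination in radians (Spencer's Fourier series).

    Parameters
    ----------
    doy : day of year, 1-based (1..366).
    """
    g = 2.0 * np.pi * (np.asarray(doy, dtype=float) - 1.0) / 365.0
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )


def eccentricity_factor(doy: np.ndarray | float) -> np.ndarray | float:
    """Squared ratio of mean to actual sun-earth distance (Spencer)."""
    g = 2.0 * np.pi * (np.asarray(doy, dtype=float) - 1.0) / 365.0
    return (
        1.00011
        + 0.034221 * np.cos(g)
        + 0.00128 * np.sin(g)
        + 0.000719 * np.cos(2 * g)
        + 0.000077 * np.sin(2 * g)
    )


def cos_zenith(latitude_deg: float, doy, hour_angle_rad) -> np.ndarray:
    """Cosine of the solar zenith angle.

    ``cos z = sin(lat) sin(dec) + cos(lat) cos(dec) cos(H)`` with hour angle
    ``H`` = 0 at true solar noon.
    """
    lat = np.deg2rad(latitude_deg)
    dec = solar_declination(doy)
    return np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(
        hour_angle_rad
    )


def max_potential_sw(latitude_deg: float, longitude_deg: float, dates) -> np.ndarray:
    """Daily maximum potential incoming shortwave radiation, W m^-2.

    The maximum of ``S0 * E0 * cos(z)`` over the day is attained at the
    day's minimum zenith, i.e. at solar noon where the hour angle is zero and
    ``cos(z) = cos(lat - dec)``.  Returns 0 on days the sun never rises.
    Longitude is accepted for interface symmetry; it shifts the clock time of
    solar noon but not the noon zenith.

    Parameters
    ----------
    latitude_deg : site latitude, degrees N in [-90, 90].
    longitude_deg : site longitude, degrees E (unused in the daily maximum).
    dates : DatetimeIndex / array of dates.
    """
    if not -90.0 <= latitude_deg <= 90.0:
        raise ValueError(f"latitude {latitude_deg!r} outside [-90, 90]")
    dates = pd.DatetimeIndex(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    # keep the annual phase stable in leap years
    doy = np.where(dates.is_leap_year & (doy > 59), doy - 1.0, doy)
    cz = cos_zenith(latitude_deg, doy, 0.0)
    return SOLAR_CONSTANT * np.asarray(eccentricity_factor(doy)) * np.clip(cz, 0.0, None)


def potential_sw_table(metadata: pd.DataFrame, dates) -> pd.DataFrame:
    """Per-site-date table of daily maximum potential SW.

    ``metadata`` must carry ``site_id``, ``latitude``, ``longitude`` columns.
    """
    dates = pd.DatetimeIndex(dates)
    out = []
    for row in metadata.itertuples():
        out.append(
            pd.DataFrame(
                {
                    "site_id": row.site_id,
                    "date": dates,
                    "s_pot_max": max_potential_sw(row.latitude, row.longitude, dates),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def normalize_fluxes(
    daily: pd.DataFrame,
    metadata: pd.DataFrame,
    fluxes: tuple[str, ...] = NORMALIZABLE,
    floor: float = SPOT_FLOOR,
) -> pd.DataFrame:
    """Attach normalized fluxes ``n.X = 100 * X / s_pot_max`` to a daily table.

    Days with ``s_pot_max`` below ``floor`` (polar night) get missing values.
    The input frame needs ``site_id`` and ``date`` columns.
    """
    daily = daily.copy()
    pot = potential_sw_table(
        metadata[metadata["site_id"].isin(daily["site_id"].unique())],
        pd.DatetimeIndex(daily["date"].unique()),
    )
    daily = daily.merge(pot, on=["site_id", "date"], how="left")
    denom = daily["s_pot_max"].where(daily["s_pot_max"] >= floor)
    for flux in fluxes:
        if flux in daily.columns:
            daily[f"n.{flux}"] = 100.0 * daily[flux] / denom
    return daily
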