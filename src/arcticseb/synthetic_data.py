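"""Synthetic circumpolar flux-tower network generator.

Emulates the observation structure of a multi-network, multi-site Arctic
surface-energy-budget (SEB) synthesis: half-hourly/hourly radiation and
turbulent-flux records per site, site metadata with vegetation classes,
daily snow-category series, and daily climate series.  The generator is the
ground truth for recovery tests: every simulated flux follows an annual
cosine cycle whose daily and seasonal means are available in closed form.

Simulated structure
-------------------
* 7 surface classes: barren, graminoid, prostrate-shrub, erect-shrub,
  wetland, boreal peat bog, glacier; each with its own annual cycles and a
  target summer Bowen ratio (H/LE).
* Incoming shortwave follows solar geometry (zero at night); outgoing
  shortwave is albedo-scaled, with a snow/snow-free albedo step tied to each
  site-year's snow phenology draw.
* Outgoing longwave is the Stefan-Boltzmann emission of the simulated
  surface temperature (emissivity 1), so the radiative-consistency identity
  holds exactly on noise-free data.
* Additive Gaussian noise, contiguous data gaps, gross outliers beyond the
  downstream QC bounds, replicated sensors, and sites reported under two
  overlapping networks.

Not simulated: spatial correlation among sites, atmospheric transmissivity
variation (clear-sky only), physical closure of the turbulent fluxes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solar_norm import cos_zenith, eccentricity_factor, SOLAR_CONSTANT

STEFAN_BOLTZMANN = 5.670374419e-8
KELVIN = 273.15

VEG_TYPES = (
    "barren",
    "graminoid",
    "prostrate-shrub",
    "erect-shrub",
    "wetland",
    "boreal peat bog",
    "glacier",
)

#: Non-leap JJA day-of-year window (inclusive).
JJA_DOYS = np.arange(152, 244)


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class VegProfile:
    """Annual-cycle parameters for one vegetation class.

    ``cycles`` maps a variable name to ``(mean, amplitude, peak_doy)`` of a
    cosine in day of year: ``mean + amplitude * cos(2*pi*(doy - peak)/365)``.
    H is not parameterized directly: its cycle shares LE's peak and is scaled
    so that the noise-free JJA mean Bowen ratio equals ``bowen_target``.
    """

    vegetation_type: str
    cycles: dict[str, tuple[float, float, float]]
    bowen_target: float
    h_amplitude: float
    snow_free_doy_mean: float
    snow_free_doy_sd: float
    snow_onset_doy_mean: float
    snow_onset_doy_sd: float
    albedo_snow: float
    albedo_free: float
    transmissivity: float = 0.75

    def __post_init__(self):
        for var, (m, a, peak) in self.cycles.items():
            if not 1 <= peak <= 365:
                raise ConfigError(f"cycles[{var}]: peak DOY {peak} outside 1..365")
        if not self.snow_free_doy_mean < self.snow_onset_doy_mean:
            raise ConfigError(
                "snow_free_doy_mean must precede snow_onset_doy_mean "
                f"({self.snow_free_doy_mean} >= {self.snow_onset_doy_mean})"
            )


def _cycle(doy, mean, amplitude, peak):
    return mean + amplitude * np.cos(2.0 * np.pi * (np.asarray(doy, float) - peak) / 365.0)


def _jja_cos_factor(peak: float) -> float:
    return float(np.mean(np.cos(2.0 * np.pi * (JJA_DOYS - peak) / 365.0)))


def h_cycle_params(profile: VegProfile) -> tuple[float, float, float]:
    """Derived (mean, amplitude, peak) of the sensible-heat cycle.

    The mean level is solved from ``bowen_target`` so that the JJA mean of H
    equals ``bowen_target`` times the JJA mean of LE.
    """
    le_mean, le_amp, le_peak = profile.cycles["LE"]
    le_jja = le_mean + le_amp * _jja_cos_factor(le_peak)
    h_mean = profile.bowen_target * le_jja - profile.h_amplitude * _jja_cos_factor(le_peak)
    return (h_mean, profile.h_amplitude, le_peak)


def expected_daily_mean(profile: VegProfile, variable: str, doy) -> np.ndarray:
    """Noise-free daily mean of ``variable`` on day(s) ``doy`` (the oracle)."""
    if variable == "H":
        m, a, p = h_cycle_params(profile)
    elif variable == "LW_out":
        t = _cycle(doy, *profile.cycles["T_surf"])
        return STEFAN_BOLTZMANN * (t + KELVIN) ** 4
    else:
        m, a, p = profile.cycles[variable]
    return _cycle(doy, m, a, p)


def expected_jja_mean(profile: VegProfile, variable: str) -> float:
    """Noise-free JJA mean of ``variable`` (closed-form recovery oracle)."""
    return float(np.mean(expected_daily_mean(profile, variable, JJA_DOYS)))


def default_profiles() -> dict[str, VegProfile]:
    """Default class profiles.

    Magnitudes follow observed Arctic summer flux levels: net radiation and
    latent heat highest over boreal peat bogs, sensible heat dominant over
    shrub tundra, negative summer H over barren and glacier surfaces.  The
    summer Bowen targets are ordered peat bog < graminoid < wetland <
    erect-shrub < prostrate-shrub among vegetated classes.
    """

    def cyc(le, le_amp, lw_in, t_air, t_surf, g, g_amp=None):
        return {
            "LE": (le, le_amp, 200.0),
            "LW_in": (lw_in, 60.0, 195.0),
            "T_air": (t_air[0], t_air[1], 200.0),
            "T_surf": (t_surf[0], t_surf[1], 200.0),
            "G": (g, g_amp if g_amp is not None else abs(g) + 8.0, 190.0),
        }

    common = dict(snow_free_doy_sd=8.0, snow_onset_doy_sd=8.0)
    return {
        "barren": VegProfile(
            "barren",
            cyc(2.0, 3.0, 250.0, (-12.0, 16.0), (-11.0, 17.0), 0.0, 6.0),
            bowen_target=-4.0,
            h_amplitude=10.0,
            snow_free_doy_mean=165.0,
            snow_onset_doy_mean=265.0,
            albedo_snow=0.8,
            albedo_free=0.25,
            **common,
        ),
        "graminoid": VegProfile(
            "graminoid",
            cyc(18.0, 22.0, 265.0, (-9.0, 17.0), (-8.0, 18.0), 1.0, 9.0),
            bowen_target=0.6,
            h_amplitude=22.0,
            snow_free_doy_mean=155.0,
            snow_onset_doy_mean=272.0,
            albedo_snow=0.8,
            albedo_free=0.18,
            **common,
        ),
        "prostrate-shrub": VegProfile(
            "prostrate-shrub",
            cyc(10.0, 11.0, 260.0, (-11.0, 17.0), (-10.0, 18.0), 1.0, 9.0),
            bowen_target=1.6,
            h_amplitude=30.0,
            snow_free_doy_mean=160.0,
            snow_onset_doy_mean=268.0,
            albedo_snow=0.8,
            albedo_free=0.17,
            **common,
        ),
        "erect-shrub": VegProfile(
            "erect-shrub",
            cyc(10.0, 12.0, 270.0, (-7.0, 16.0), (-6.0, 17.0), 1.5, 10.0),
            bowen_target=1.5,
            h_amplitude=32.0,
            snow_free_doy_mean=152.0,
            snow_onset_doy_mean=275.0,
            albedo_snow=0.75,
            albedo_free=0.15,
            **common,
        ),
        "wetland": VegProfile(
            "wetland",
            cyc(13.0, 15.0, 270.0, (-8.0, 16.0), (-7.0, 17.0), 1.0, 9.0),
            bowen_target=1.1,
            h_amplitude=26.0,
            snow_free_doy_mean=154.0,
            snow_onset_doy_mean=274.0,
            albedo_snow=0.8,
            albedo_free=0.16,
            **common,
        ),
        "boreal peat bog": VegProfile(
            "boreal peat bog",
            cyc(30.0, 36.0, 280.0, (-3.0, 15.0), (-2.0, 16.0), 0.5, 8.0),
            bowen_target=0.1,
            h_amplitude=14.0,
            snow_free_doy_mean=140.0,
            snow_onset_doy_mean=290.0,
            albedo_snow=0.75,
            albedo_free=0.13,
            **common,
        ),
        "glacier": VegProfile(
            "glacier",
            cyc(4.0, 4.0, 255.0, (-14.0, 14.0), (-12.0, 13.0), 1.0, 5.0),
            bowen_target=-3.0,
            h_amplitude=8.0,
            snow_free_doy_mean=190.0,
            snow_onset_doy_mean=245.0,
            albedo_snow=0.85,
            albedo_free=0.45,
            **common,
        ),
    }


DEFAULT_LAT_RANGES = {
    "barren": (70.0, 79.0),
    "graminoid": (65.0, 74.0),
    "prostrate-shrub": (68.0, 78.0),
    "erect-shrub": (64.0, 70.0),
    "wetland": (64.0, 72.0),
    "boreal peat bog": (60.0, 64.0),
    "glacier": (61.0, 80.0),
}

DEFAULT_NOISE_SD = {
    "SW_in": 15.0,
    "SW_out": 8.0,
    "LW_in": 10.0,
    "LW_out": 8.0,
    "H": 12.0,
    "LE": 10.0,
    "G": 4.0,
    "T_air": 1.0,
    "T_surf": 1.0,
}

UNITS = {
    "SW_in": "W m-2",
    "SW_out": "W m-2",
    "LW_in": "W m-2",
    "LW_out": "W m-2",
    "H": "W m-2",
    "LE": "W m-2",
    "G": "W m-2",
    "T_air": "degC",
    "T_surf": "degC",
}


@dataclass(frozen=True)
class SimConfig:
    """Seeded configuration of the synthetic observation network."""

    n_sites_per_vegtype: int = 3
    vegetation_types: tuple[str, ...] = VEG_TYPES
    years: tuple[int, int] = (1994, 2021)
    timestep: int = 60
    lat_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LAT_RANGES)
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    gap_fraction: float = 0.05
    mean_gap_length_hours: float = 3.0
    outlier_rate: float = 0.001
    gapfilled_fraction: float = 0.01
    replicate_probability: float = 0.2
    network_overlap_probability: float = 0.2
    network_labels: tuple[str, ...] = ("FLUXNET", "AmeriFlux", "PROMICE")
    variables: tuple[str, ...] = tuple(UNITS)
    seed: int = 0

    def __post_init__(self):
        if 1440 % self.timestep != 0:
            raise ConfigError(f"timestep: {self.timestep} does not divide 1440")
        if not self.years[0] <= self.years[1]:
            raise ConfigError(f"years: empty range {self.years}")
        for name in (
            "gap_fraction",
            "outlier_rate",
            "replicate_probability",
            "network_overlap_probability",
            "gapfilled_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: {v} outside [0, 1]")
        if self.n_sites_per_vegtype < 1:
            raise ConfigError(f"n_sites_per_vegtype: {self.n_sites_per_vegtype} < 1")
        for vt in self.vegetation_types:
            if vt not in VEG_TYPES:
                raise ConfigError(f"vegetation_types: unknown type {vt!r}")
        unknown = set(self.variables) - set(UNITS)
        if unknown:
            raise ConfigError(f"variables: unknown {sorted(unknown)}")


# --- categorical driver pools used for the metadata table -----------------

_CAVM_TYPE = {
    "barren": "B",
    "graminoid": "G",
    "prostrate-shrub": "P",
    "erect-shrub": "S",
    "wetland": "W",
    "boreal peat bog": "W",
    "glacier": "GL",
}
_SUBZONES = {
    "barren": ("A", "B"),
    "graminoid": ("C", "D"),
    "prostrate-shrub": ("B", "C"),
    "erect-shrub": ("D", "E"),
    "wetland": ("D", "E"),
    "boreal peat bog": ("non-Arctic",),
    "glacier": ("glacier",),
}
_PERMAFROST_EXTENT = {
    "barren": ("C",),
    "graminoid": ("C", "D"),
    "prostrate-shrub": ("C",),
    "erect-shrub": ("C", "D"),
    "wetland": ("D", "Si"),
    "boreal peat bog": ("Si", "o"),
    "glacier": ("g",),
}
_PERMAFROST_ICE = {
    "barren": ("l",),
    "graminoid": ("m", "h"),
    "prostrate-shrub": ("m", "l"),
    "erect-shrub": ("m", "l"),
    "wetland": ("h", "m"),
    "boreal peat bog": ("l", "o"),
    "glacier": ("g",),
}


def _doy_365(dates: pd.DatetimeIndex) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(dtype=float)
    return np.where(dates.is_leap_year & (doy > 59), doy - 1.0, doy)


def _snow_dates(profile: VegProfile, years: np.ndarray, rng) -> pd.DataFrame:
    free = np.round(
        rng.normal(profile.snow_free_doy_mean, profile.snow_free_doy_sd, len(years))
    )
    onset = np.round(
        rng.normal(profile.snow_onset_doy_mean, profile.snow_onset_doy_sd, len(years))
    )
    free = np.clip(free, 60, 240)
    onset = np.clip(np.maximum(onset, free + 20), None, 350)
    return pd.DataFrame({"year": years, "first_free_doy": free, "first_snow_doy": onset})


def _site_snow_series(dates: pd.DatetimeIndex, snow_dates: pd.DataFrame) -> np.ndarray:
    """Daily categories: snow before the first snow-free day and from the
    autumn onset day on; "no snow" in between."""
    doy = _doy_365(dates)
    year = dates.year.to_numpy()
    lookup = snow_dates.set_index("year")
    free = lookup.loc[year, "first_free_doy"].to_numpy()
    onset = lookup.loc[year, "first_snow_doy"].to_numpy()
    return np.where((doy >= free) & (doy < onset), "no snow", "snow")


def generate_network(config: SimConfig):
    """Generate the full synthetic observation set.

    Returns
    -------
    records : DataFrame
        Long-format sub-daily records: site_id, timestamp, variable, value,
        qc_flag, network, replicate_id, unit.
    metadata : DataFrame
        One row per site: coordinates, vegetation and permafrost classes,
        network membership, cloud and altitude drivers.
    snow : DataFrame
        Daily snow-category series: site_id, date, category.
    climate : DataFrame
        Daily site climate: site_id, date, t_air, precip.
    truth : DataFrame
        Per-site generating parameters (noise-free JJA means, snow-date
        means, Bowen target) for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    profiles = default_profiles()

    y0, y1 = config.years
    stamps = pd.date_range(
        f"{y0}-01-01",
        f"{y1}-12-31 23:59",
        freq=f"{config.timestep}min",
    )
    days = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy_sub = _doy_365(stamps)
    doy_day = _doy_365(days)
    years = np.arange(y0, y1 + 1)
    hour_angle = (
        2.0
        * np.pi
        * (stamps.hour.to_numpy() + stamps.minute.to_numpy() / 60.0 - 12.0)
        / 24.0
    )

    rec_parts, meta_rows, snow_parts, climate_parts, truth_rows = [], [], [], [], []
    site_num = 0
    for vt in config.vegetation_types:
        prof = profiles[vt]
        lat_lo, lat_hi = config.lat_ranges[vt]
        for _ in range(config.n_sites_per_vegtype):
            site_num += 1
            site_id = f"S{site_num:03d}"
            lat = rng.uniform(lat_lo, lat_hi)
            lon = rng.uniform(-165.0, 165.0)
            network = config.network_labels[site_num % len(config.network_labels)]

            snow_dates = _snow_dates(prof, years, rng)
            snow_cat = _site_snow_series(days, snow_dates)
            snow_parts.append(
                pd.DataFrame({"site_id": site_id, "date": days, "category": snow_cat})
            )

            # daily climate (independent noise; precip as wet-day exponential)
            t_air_day = expected_daily_mean(prof, "T_air", doy_day) + rng.normal(
                0.0, config.noise_sd.get("T_air", 1.0), len(days)
            )
            wet = rng.random(len(days)) < 0.35
            precip = np.where(wet, rng.exponential(2.5, len(days)), 0.0)
            climate_parts.append(
                pd.DataFrame(
                    {
                        "site_id": site_id,
                        "date": days,
                        "t_air": t_air_day,
                        "precip": precip,
                    }
                )
            )

            # sub-daily truth per variable, noise added per sensor copy below
            day_index = stamps.normalize()
            snow_sub = pd.Series(snow_cat, index=days).reindex(day_index).to_numpy()
            albedo_sub = np.where(snow_sub == "snow", prof.albedo_snow, prof.albedo_free)
            cz = np.clip(cos_zenith(lat, doy_sub, hour_angle), 0.0, None)
            clean = {}
            for var in config.variables:
                if var == "SW_in":
                    clean[var] = (
                        SOLAR_CONSTANT
                        * eccentricity_factor(doy_sub)
                        * cz
                        * prof.transmissivity
                    )
                elif var == "SW_out":
                    clean[var] = clean.get("SW_in", 0.0) * albedo_sub
                else:
                    clean[var] = np.broadcast_to(
                        expected_daily_mean(prof, var, doy_sub), len(stamps)
                    ).copy()

            copies = [(network, "r1")]
            if rng.random() < config.replicate_probability:
                copies.append((network, "r2"))
            if (
                len(config.network_labels) > 1
                and rng.random() < config.network_overlap_probability
            ):
                other = config.network_labels[
                    (site_num + 1) % len(config.network_labels)
                ]
                copies.append((other, "r1"))
            meta_rows.append(
                {
                    "site_id": site_id,
                    "latitude": lat,
                    "longitude": lon,
                    "altitude": rng.uniform(5.0, 900.0),
                    "vegetation_type": vt,
                    "cavm_type": _CAVM_TYPE[vt],
                    "cavm_subzone": rng.choice(_SUBZONES[vt]),
                    "permafrost_extent": rng.choice(_PERMAFROST_EXTENT[vt]),
                    "permafrost_ice": rng.choice(_PERMAFROST_ICE[vt]),
                    "cloud_cover": rng.uniform(55.0, 85.0),
                    "cloud_temperature": rng.uniform(-35.0, -15.0),
                    "network": network,
                    "networks": ";".join(sorted({c[0] for c in copies})),
                }
            )

            for net, rep in copies:
                offset = rng.normal(0.0, 2.0) if (net, rep) != (network, "r1") else 0.0
                for var in config.variables:
                    sd = config.noise_sd.get(var, 0.0)
                    vals = clean[var] + offset * (var not in ("T_air", "T_surf"))
                    if sd > 0:
                        vals = vals + rng.normal(0.0, sd, len(stamps))
                    if var in ("SW_in", "SW_out"):
                        vals = np.clip(vals, 0.0, None)
                        vals[clean["SW_in"] == 0.0] = 0.0
                    qc = np.where(
                        rng.random(len(stamps)) < config.gapfilled_fraction,
                        "gap-filled",
                        "measured",
                    )
                    if config.outlier_rate > 0:
                        hit = rng.random(len(stamps)) < config.outlier_rate
                        if var in ("SW_in", "SW_out", "LW_in", "LW_out"):
                            vals = np.where(hit, 1450.0 + rng.exponential(200.0, len(stamps)), vals)
                        elif var in ("T_air", "T_surf"):
                            vals = np.where(hit, -150.0, vals)
                        else:
                            vals = np.where(hit, vals + 800.0, vals)
                    rec_parts.append(
                        pd.DataFrame(
                            {
                                "site_id": site_id,
                                "timestamp": stamps,
                                "variable": var,
                                "value": vals,
                                "qc_flag": qc,
                                "network": net,
                                "replicate_id": rep,
                                "unit": UNITS[var],
                            }
                        )
                    )

            truth = {
                "site_id": site_id,
                "vegetation_type": vt,
                "latitude": lat,
                "bowen_target": prof.bowen_target,
                "snow_free_doy_mean": prof.snow_free_doy_mean,
                "snow_onset_doy_mean": prof.snow_onset_doy_mean,
            }
            for var in config.variables:
                if var not in ("SW_in", "SW_out"):
                    truth[f"jja_mean_{var}"] = expected_jja_mean(prof, var)
            truth_rows.append(truth)

    records = pd.concat(rec_parts, ignore_index=True)
    if config.gap_fraction > 0:
        records = inject_gaps(
            records,
            config.gap_fraction,
            config.mean_gap_length_hours,
            seed=rng.integers(0, 2**31 - 1),
            timestep=config.timestep,
        )
    return (
        records,
        pd.DataFrame(meta_rows),
        pd.concat(snow_parts, ignore_index=True),
        pd.concat(climate_parts, ignore_index=True),
        pd.DataFrame(truth_rows),
    )


def inject_gaps(
    records: pd.DataFrame,
    gap_fraction: float,
    mean_gap_length_hours: float,
    seed: int,
    timestep: int | None = None,
) -> pd.DataFrame:
    """Remove a fraction of time slots in contiguous runs.

    Gaps are drawn per sensor stream (site, network, replicate) and apply to
    all of that stream's variables at once, emulating logger dropouts.  Run
    lengths are geometric with the requested mean.
    """
    if not 0.0 <= gap_fraction <= 1.0:
        raise ValueError(f"gap_fraction {gap_fraction} outside [0, 1]")
    if mean_gap_length_hours <= 0:
        raise ValueError(f"mean_gap_length_hours must be positive, got {mean_gap_length_hours}")
    if gap_fraction == 0.0 or records.empty:
        return records
    if gap_fraction == 1.0:
        return records.iloc[0:0]

    rng = np.random.default_rng(seed)
    if timestep is None:
        ts = np.sort(records["timestamp"].unique())
        timestep = int(pd.Series(ts).diff().dropna().min().total_seconds() // 60)
    slots_per_gap = max(mean_gap_length_hours * 60.0 / timestep, 1.0)

    keep = np.ones(len(records), dtype=bool)
    groups = records.groupby(["site_id", "network", "replicate_id"], sort=False)
    for _, idx in groups.indices.items():
        sub = records.iloc[idx]
        stamps = np.sort(sub["timestamp"].unique())
        n = len(stamps)
        target = gap_fraction * n
        removed = np.zeros(n, dtype=bool)
        while removed.sum() < target:
            length = rng.geometric(1.0 / slots_per_gap)
            start = rng.integers(0, n)
            removed[start : start + length] = True
        dropped = set(stamps[removed])
        keep[idx] = ~sub["timestamp"].isin(dropped).to_numpy()
    return records[keep].reset_index(drop=True)


def simulate_importance_table(
    seed: int,
    n_sites_per_type: int = 40,
    response: str = "LE",
    vegetation_variance: float = 1.0,
    other_variance_ratio: float = 4.0,
    noise_sd: float = 0.5,
):
    """Site-mean table with a known dominant driver, for recovery tests.

    Draws one seasonal site mean per site for ``response`` from a linear
    model in which vegetation type contributes ``other_variance_ratio``
    times the response variance of every other driver (all drivers mutually
    independent here, unlike the fully confounded network generator).

    The default of 40 sites per class keeps the experiment identifiable:
    with plain (unadjusted) R^2, a k-level categorical driver picks up a
    spurious share of roughly (k-1)/n of the residual variance in a
    2-predictor model, so small networks let chance correlations of
    nuisance drivers overtake the true dominant driver.

    Returns ``(site_means, driver_table)`` in the shapes expected by
    :func:`arcticseb.varpart.run_all_pairs`.
    """
    rng = np.random.default_rng(seed)
    veg = [vt for vt in VEG_TYPES if vt != "glacier"][:5]
    n = n_sites_per_type * len(veg)
    site_ids = [f"S{i:03d}" for i in range(1, n + 1)]
    vt = np.repeat(veg, n_sites_per_type)

    # centered type effects scaled to the requested between-class variance
    raw = rng.normal(0.0, 1.0, len(veg))
    raw -= raw.mean()
    raw *= np.sqrt(vegetation_variance / raw.var())
    y = np.asarray([raw[veg.index(v)] for v in vt], dtype=float)

    numeric = {}
    b = np.sqrt(vegetation_variance / other_variance_ratio)
    from .drivers import NUMERIC_DRIVERS

    for name in NUMERIC_DRIVERS:
        x = rng.normal(0.0, 1.0, n)
        numeric[name] = x
        y = y + b * x
    cat_pools = {
        "cavm_type": ("B", "G", "P", "S", "W"),
        "cavm_subzone": ("A", "B", "C", "D", "E"),
        "permafrost_extent": ("C", "D", "Si"),
        "permafrost_ice": ("h", "m", "l"),
    }
    cats = {}
    for name, pool in cat_pools.items():
        codes = rng.integers(0, len(pool), n)
        effects = rng.normal(0.0, 1.0, len(pool))
        effects -= effects.mean()
        effects *= np.sqrt((vegetation_variance / other_variance_ratio) / effects.var())
        cats[name] = np.asarray(pool)[codes]
        y = y + effects[codes]
    y = y + rng.normal(0.0, noise_sd, n)

    driver_table = pd.DataFrame(
        {"site_id": site_ids, "vegetation_type": vt, **cats, **numeric}
    )
    site_means = pd.DataFrame(
        {
            "site_id": site_ids,
            "season": "JJA",
            "response": response,
            "value": y,
            "n_years": 3,
        }
    )
    return site_means, driver_table


def write_csvs(outdir, records, metadata, snow, climate, truth=None) -> None:
    """Write the generated tables as plain CSV files under ``outdir``."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "records.csv", index=False)
    metadata.to_csv(out / "metadata.csv", index=False)
    snow.to_csv(out / "snow.csv", index=False)
    climate.to_csv(out / "climate.csv", index=False)
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)
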