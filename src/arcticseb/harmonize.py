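"""Harmonization of sub-daily flux-tower records to daily site series.

The processing chain mirrors standard practice for multi-network
surface-energy-budget syntheses:

1. keep directly measured values only (drop gap-filled-flagged records);
2. plausibility filtering (radiation > 1400 W m-2, negative incoming or
   outgoing radiation, albedo outside [0, 1], temperatures below -100 degC);
3. daily (24 h) mean/min/max where at least 65% of the day's nominal slots
   are present and the longest internal gap is at most 4.8 h;
4. averaging across replicated sensors within a network, then across
   networks reporting the same site;
5. flux-direction harmonization (H, LE, G positive away from the surface);
6. derivation of SW_net, LW_net, R_net and albedo from the daily radiation
   components where not directly measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIABLES = (
    "SW_in",
    "SW_out",
    "LW_in",
    "LW_out",
    "R_net",
    "H",
    "LE",
    "G",
    "T_air",
    "T_surf",
    "albedo",
    "precip",
)

RADIATION = ("SW_in", "SW_out", "LW_in", "LW_out")
TURBULENT = ("H", "LE", "G")

#: Daily-aggregation completeness rules.
MIN_COMPLETENESS = 0.65
MAX_GAP_HOURS = 4.8

RADIATION_MAX = 1400.0
TEMPERATURE_MIN = -100.0

#: Stefan-Boltzmann constant and surface emissivity used by the radiative
#: consistency check R_net = SW_in*(1-albedo) + LW_in - eps*sigma*T_surf^4.
SIGMA = 5.670374419e-8
EMISSIVITY = 1.0


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`quality_filter`."""

    gap_filled: int = 0
    radiation_above_max: int = 0
    radiation_negative: int = 0
    albedo_out_of_range: int = 0
    temperature_below_min: int = 0

    def total(self) -> int:
        return (
            self.gap_filled
            + self.radiation_above_max
            + self.radiation_negative
            + self.albedo_out_of_range
            + self.temperature_below_min
        )


def quality_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop gap-filled and physically implausible records.

    Rules (each with its own count in the returned report):

    * ``qc_flag == "gap-filled"`` removed;
    * shortwave/longwave radiation values > 1400 W m-2 removed;
    * negative incoming/outgoing radiation removed (turbulent fluxes may be
      negative and are untouched);
    * albedo outside [0, 1] removed;
    * air/surface temperature < -100 degC removed.

    Raises ``ValueError`` listing accepted names if an unknown variable
    appears.
    """
    unknown = set(records["variable"].unique()) - set(VARIABLES)
    if unknown:
        raise ValueError(
            f"unknown variable(s) {sorted(unknown)}; accepted: {list(VARIABLES)}"
        )
    report = FilterReport()
    var = records["variable"]
    val = records["value"]

    drop_gf = records["qc_flag"].eq("gap-filled")
    is_rad = var.isin(RADIATION)
    drop_hi = is_rad & (val > RADIATION_MAX) & ~drop_gf
    drop_neg = is_rad & (val < 0.0) & ~drop_gf
    is_alb = var.eq("albedo")
    drop_alb = is_alb & ((val < 0.0) | (val > 1.0)) & ~drop_gf
    is_temp = var.isin(("T_air", "T_surf"))
    drop_temp = is_temp & (val < TEMPERATURE_MIN) & ~drop_gf

    report.gap_filled = int(drop_gf.sum())
    report.radiation_above_max = int(drop_hi.sum())
    report.radiation_negative = int(drop_neg.sum())
    report.albedo_out_of_range = int(drop_alb.sum())
    report.temperature_below_min = int(drop_temp.sum())

    keep = ~(drop_gf | drop_hi | drop_neg | drop_alb | drop_temp)
    return records[keep].reset_index(drop=True), report


def harmonize_sign_convention(
    records: pd.DataFrame, toward_surface_positive: bool = False
) -> pd.DataFrame:
    """Flip turbulent fluxes declared positive-toward-surface.

    The harmonized convention is positive *away* from the surface for H, LE
    and G.  Call with ``toward_surface_positive=True`` for input declared in
    the opposite convention; applying the flip twice restores the input.
    """
    if not toward_surface_positive:
        return records
    records = records.copy()
    flip = records["variable"].isin(TURBULENT)
    records.loc[flip, "value"] = -records.loc[flip, "value"]
    return records


def max_gap_hours_of_day(
    slot_idx: np.ndarray, slots_per_day: int, timestep: int
) -> float:
    """Longest run of consecutive missing slots within one civil day, hours.

    The day boundary closes runs: leading and trailing missing blocks count
    as gaps of their own length.  Direct boolean-run scan; used as the
    reference for the vectorized aggregation path.
    """
    present = np.zeros(slots_per_day, dtype=bool)
    present[slot_idx] = True
    missing = ~present
    padded = np.concatenate(([False], missing, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    if len(edges) == 0:
        return 0.0
    runs = edges[1::2] - edges[0::2]
    return float(runs.max()) * timestep / 60.0


def aggregate_daily(
    records: pd.DataFrame,
    timestep_minutes: int,
    min_completeness: float = MIN_COMPLETENESS,
    max_gap_hours: float = MAX_GAP_HOURS,
) -> pd.DataFrame:
    """Daily mean/min/max per (site, date, variable) with completeness rules.

    A sensor-stream day qualifies only if at least ``min_completeness`` of
    the nominal slots (1440/timestep per 24 h) are present *and* the longest
    run of consecutive missing slots is at most ``max_gap_hours``.  Daily
    values are then averaged across replicates within each network and
    finally across networks.

    Returns a wide frame indexed by (site_id, date) with one column per
    variable (daily mean) plus ``<var>_min`` / ``<var>_max`` columns.
    """
    if 1440 % timestep_minutes != 0:
        raise ValueError(f"timestep {timestep_minutes} does not divide 1440")
    slots_per_day = 1440 // timestep_minutes

    df = records.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["date"] = ts.dt.normalize()
    minute_of_day = ts.dt.hour * 60 + ts.dt.minute
    if (minute_of_day % timestep_minutes != 0).any():
        raise ValueError(
            "timestamps not aligned to the stated timestep; mixed timesteps?"
        )
    df["slot"] = minute_of_day // timestep_minutes

    stream = ["site_id", "network", "replicate_id", "variable", "date"]
    df = df.sort_values(stream + ["slot"], kind="stable")
    grouped = df.groupby(stream, sort=False, observed=True)
    agg = grouped["value"].agg(["mean", "min", "max", "count"])

    # longest missing run per stream-day: the largest of (slots before the
    # first observation, slots after the last, consecutive-slot jumps - 1)
    gid = grouped.ngroup().to_numpy()
    slot = df["slot"].to_numpy()
    jump = np.diff(slot, prepend=slot[:1]) - 1
    jump[np.diff(gid, prepend=gid[:1]) != 0] = 0
    max_jump = pd.Series(jump).groupby(gid).max().to_numpy()
    first_slot = grouped["slot"].first().to_numpy()
    last_slot = grouped["slot"].last().to_numpy()
    gap_slots = np.maximum.reduce(
        [max_jump, first_slot, slots_per_day - 1 - last_slot]
    )
    gaps = gap_slots * timestep_minutes / 60.0

    completeness = agg["count"].to_numpy() / slots_per_day
    ok = (completeness >= min_completeness) & (gaps <= max_gap_hours)
    agg = agg[ok]
    if agg.empty:
        return pd.DataFrame(columns=["site_id", "date"])

    agg = agg.reset_index()
    # step (vii): replicate average within network, then (vi): across networks
    within = agg.groupby(
        ["site_id", "network", "variable", "date"], sort=False, observed=True
    )[["mean", "min", "max"]].mean()
    across = within.groupby(
        ["site_id", "variable", "date"], sort=False, observed=True
    ).mean()

    wide = across.unstack("variable")
    out = pd.DataFrame(index=wide.index)
    for var in wide["mean"].columns:
        out[var] = wide[("mean", var)]
        out[f"{var}_min"] = wide[("min", var)]
        out[f"{var}_max"] = wide[("max", var)]
    return out.reset_index().sort_values(["site_id", "date"]).reset_index(drop=True)


def derive_radiation(
    daily: pd.DataFrame, albedo_sw_floor: float = 10.0
) -> pd.DataFrame:
    """Fill SW_net, LW_net, R_net and albedo from daily radiation components.

    Directly measured values are preserved; derived values fill the gaps
    ("if not otherwise available").  Daily albedo is the ratio of the daily
    mean outgoing to incoming shortwave, undefined when daily mean SW_in is
    below ``albedo_sw_floor`` (W m-2) to avoid low-sun blow-ups.
    """
    daily = daily.copy()
    for col in ("SW_net", "LW_net", "R_net", "albedo"):
        if col not in daily.columns:
            daily[col] = np.nan

    def have(col):
        return daily[col] if col in daily.columns else pd.Series(np.nan, index=daily.index)

    sw_net = have("SW_in") - have("SW_out")
    lw_net = have("LW_in") - have("LW_out")
    daily["SW_net"] = daily["SW_net"].fillna(sw_net)
    daily["LW_net"] = daily["LW_net"].fillna(lw_net)
    daily["R_net"] = daily["R_net"].fillna(daily["SW_net"] + daily["LW_net"])
    alb = (have("SW_out") / have("SW_in")).where(have("SW_in") >= albedo_sw_floor)
    daily["albedo"] = daily["albedo"].fillna(alb)
    if {"T_surf", "T_air"}.issubset(daily.columns):
        daily["T_surf-T_air"] = daily["T_surf"] - daily["T_air"]
    return daily


def harmonize_pipeline(
    records: pd.DataFrame,
    timestep_minutes: int,
    toward_surface_positive: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full chain: QC filter -> sign convention -> daily aggregation ->
    radiation derivation.  Returns the daily table and the filter report."""
    filtered, report = quality_filter(records)
    filtered = harmonize_sign_convention(filtered, toward_surface_positive)
    daily = aggregate_daily(filtered, timestep_minutes)
    daily = derive_radiation(daily)
    return daily, report
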