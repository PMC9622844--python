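"""All-pairs variance partitioning of seasonal flux means.

Ranks drivers of the surface energy budget by the variance they explain in
site-level seasonal flux means.  Every unordered pair of drivers is fitted
as a 2-predictor ordinary-least-squares model; for each predictor the
explained variance is recorded when fitted first (its marginal R^2), when
fitted last (the R^2 increment over the partner alone) and averaged over
the two orderings.  With two predictors the order-averaged share is exactly
the LMG (Lindeman-Merenda-Gold) decomposition.

With 15 drivers that is C(15,2) = 105 pairs per response, and 105 x 2
orderings x 14 responses = 2940 ordered model evaluations for the standard
response set.

Categorical drivers enter as full dummy blocks, so a category's share is
the block's joint contribution.  R^2 is plain (not adjusted); negative
last-shares, which collinearity can produce, are floored at zero for
reporting but kept raw internally so the decomposition identity
``first(A) + last(B) = 100 * R^2(A,B)`` remains exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

#: The 14 standard responses: six fluxes, their normalized versions, albedo
#: and surface temperature.
DEFAULT_RESPONSES = (
    "R_net",
    "H",
    "LE",
    "G",
    "SW_net",
    "LW_net",
    "n.R_net",
    "n.H",
    "n.LE",
    "n.G",
    "n.SW_net",
    "n.LW_net",
    "albedo",
    "T_surf",
)

SEASON_MONTHS = {
    "JJA": (6, 7, 8),
    "Y": tuple(range(1, 13)),
    **{m: (i,) for i, m in enumerate(
        ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
         "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"), start=1)},
}

MIN_COVERAGE = 0.8


def seasonal_site_means(
    daily: pd.DataFrame,
    season: str = "JJA",
    responses: tuple[str, ...] = DEFAULT_RESPONSES,
    min_coverage: float = MIN_COVERAGE,
) -> pd.DataFrame:
    """Across-year site means of seasonal flux means.

    A site-year enters only when at least ``min_coverage`` of the season's
    days carry a value for that response; the site value is the mean over
    qualifying years.  Returns a long frame: site_id, season, response,
    value, n_years.
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}; one of {sorted(SEASON_MONTHS)}")
    months = SEASON_MONTHS[season]
    df = daily.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year
    df["month"] = dates.dt.month
    df = df[df["month"].isin(months)]

    rows = []
    present = [r for r in responses if r in df.columns]
    for resp in present:
        counts = df.groupby(["site_id", "year"])[resp].count()
        season_days = np.array(
            [_season_length(y, months) for y in counts.index.get_level_values("year")]
        )
        ok = counts / season_days >= min_coverage
        means = df.groupby(["site_id", "year"])[resp].mean()[ok]
        site_means = means.groupby("site_id").mean()
        n_years = means.groupby("site_id").size()
        for site, val in site_means.items():
            rows.append(
                {
                    "site_id": site,
                    "season": season,
                    "response": resp,
                    "value": val,
                    "n_years": int(n_years[site]),
                }
            )
    return pd.DataFrame(rows)


def _season_length(year: int, months: tuple[int, ...]) -> int:
    days = 0
    for m in months:
        days += pd.Period(f"{year}-{m:02d}").days_in_month
    return days


def _design_block(values: pd.Series) -> np.ndarray:
    """Numeric column or full dummy block for a categorical driver."""
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(dtype=float).reshape(-1, 1)
    dummies = pd.get_dummies(values.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _r2(y: np.ndarray, blocks: list[np.ndarray]) -> float:
    """Plain R^2 of an intercept + blocks OLS fit."""
    n = len(y)
    x = np.hstack([np.ones((n, 1))] + blocks)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / tss


@dataclass
class PairPartition:
    """Raw decomposition of one driver pair for one response (in % points)."""

    driver_a: str
    driver_b: str
    first_a: float
    last_a: float
    first_b: float
    last_b: float
    r2_ab: float  # joint model R^2, in %
    n_sites: int

    @property
    def average_a(self) -> float:
        return 0.5 * (self.first_a + self.last_a)

    @property
    def average_b(self) -> float:
        return 0.5 * (self.first_b + self.last_b)


def partition_pair(
    response_values: pd.Series, driver_a: pd.Series, driver_b: pd.Series,
    name_a: str = "A", name_b: str = "B",
) -> PairPartition:
    """First/last/average explained-variance decomposition for one pair.

    ``first(A) = 100*R^2(A)``; ``last(A) = 100*(R^2(A,B) - R^2(B))``;
    ``average`` is the mean of the two.  All inputs must be aligned and
    complete (listwise deletion happens in :func:`run_all_pairs`).
    """
    y = np.asarray(response_values, dtype=float)
    a = _design_block(driver_a)
    b = _design_block(driver_b)
    n_coef = 1 + a.shape[1] + b.shape[1]
    if len(y) < n_coef + 3:
        raise ValueError(
            f"need at least {n_coef + 3} observations for {n_coef} coefficients, got {len(y)}"
        )
    r2_a = 100.0 * _r2(y, [a])
    r2_b = 100.0 * _r2(y, [b])
    r2_ab = 100.0 * _r2(y, [a, b])
    return PairPartition(
        driver_a=name_a,
        driver_b=name_b,
        first_a=r2_a,
        last_a=r2_ab - r2_b,
        first_b=r2_b,
        last_b=r2_ab - r2_a,
        r2_ab=r2_ab,
        n_sites=len(y),
    )


def run_all_pairs(
    site_means: pd.DataFrame,
    driver_table: pd.DataFrame,
    drivers: tuple[str, ...] | None = None,
    responses: tuple[str, ...] | None = None,
    floor_negative: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """All 2-predictor models for every driver pair and response.

    Parameters
    ----------
    site_means : long frame from :func:`seasonal_site_means`.
    driver_table : one row per site with driver columns.
    drivers, responses : subsets to use; default all driver columns /
        all responses present in ``site_means``.
    floor_negative : floor negative order shares at 0 in the summary.

    Returns
    -------
    summary : frame with one row per (response, driver): mean/min/max of the
        order-averaged share across the driver's pairs, plus bookkeeping
        (n_models, mean_sites, mean_site_years).
    bookkeeping : dict with n_drivers, n_responses, n_pairs (unordered pairs
        per response), n_ordered_models (pairs x 2 orderings x responses)
        and n_skipped (singular/underdetermined models).
    """
    from . import drivers as drv

    if drivers is None:
        drivers = tuple(c for c in drv.ALL_DRIVERS if c in driver_table.columns)
    missing = [d for d in drivers if d not in driver_table.columns]
    if missing:
        raise ValueError(f"driver column(s) missing from driver table: {missing}")
    if responses is None:
        responses = tuple(site_means["response"].unique())

    pairs = list(combinations(drivers, 2))
    rows = []
    n_skipped = 0
    n_evaluated_pairs = 0
    for resp in responses:
        sub = site_means[site_means["response"] == resp][
            ["site_id", "value", "n_years"]
        ]
        merged = sub.merge(driver_table, on="site_id", how="inner")
        per_driver: dict[str, list[PairPartition]] = {d: [] for d in drivers}
        for a, b in pairs:
            data = merged[["value", "n_years", a, b]].dropna()
            try:
                part = partition_pair(data["value"], data[a], data[b], a, b)
            except (ValueError, np.linalg.LinAlgError):
                n_skipped += 1
                continue
            part.mean_years = float(data["n_years"].mean())  # bookkeeping rider
            per_driver[a].append(part)
            per_driver[b].append(part)
            n_evaluated_pairs += 1
        for d in drivers:
            parts = per_driver[d]
            if not parts:
                continue
            shares = np.array(
                [p.average_a if p.driver_a == d else p.average_b for p in parts]
            )
            if floor_negative:
                shares = np.clip(shares, 0.0, None)
            rows.append(
                {
                    "response": resp,
                    "driver": d,
                    "mean_explained": shares.mean(),
                    "min_explained": shares.min(),
                    "max_explained": shares.max(),
                    "n_models": 2 * len(parts),
                    "mean_sites": float(np.mean([p.n_sites for p in parts])),
                    "mean_site_years": float(
                        np.mean(
                            [p.n_sites * getattr(p, "mean_years", np.nan) for p in parts]
                        )
                    ),
                }
            )
    summary = pd.DataFrame(rows)
    bookkeeping = {
        "n_drivers": len(drivers),
        "n_responses": len(responses),
        "n_pairs": len(pairs),
        "n_ordered_models": 2 * len(pairs) * len(responses),
        "n_ordered_models_evaluated": 2 * n_evaluated_pairs,
        "n_skipped": n_skipped,
    }
    return summary, bookkeeping


def rank_drivers(summary: pd.DataFrame, response: str) -> pd.DataFrame:
    """Drivers of one response ordered by mean order-averaged share."""
    sub = summary[summary["response"] == response]
    return sub.sort_values("mean_explained", ascending=False).reset_index(drop=True)
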