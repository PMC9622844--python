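"""Per-vegetation-type flux magnitudes from a linear mixed model.

Site-level seasonal flux means are modelled as a function of vegetation
type (fixed effect) with the data-distribution network (FLUXNET, AmeriFlux,
PROMICE, ...) as a random intercept, acknowledging that sites reported by
the same network share instrumentation and processing conventions.  The
module reports estimated marginal means with 95% confidence intervals, an
omnibus F-test of the vegetation-type effect, Bonferroni-corrected pairwise
contrasts, and summer Bowen ratios (H/LE).

Denominator degrees of freedom for mixed-model F-tests have no single
agreed definition; this module uses a residual-type approximation
``n - k - (n_networks - 1)`` by default and leaves the method configurable.
With a single network the model degenerates exactly to a one-way ANOVA on
site means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Standard vegetation classes; the omnibus test is suppressed when three
#: or more of these are absent from the data.
STANDARD_TYPES = (
    "barren",
    "graminoid",
    "prostrate-shrub",
    "erect-shrub",
    "wetland",
    "boreal peat bog",
    "glacier",
)


@dataclass
class MagnitudeFit:
    """Fitted per-type magnitudes for one flux and season."""

    season: str
    flux: str
    estimates: pd.DataFrame  # vegetation_type, mean, ci95_halfwidth, n_sites
    effect_F: float
    df_num: int
    df_den: float
    p_value: float
    effect_suppressed: bool
    single_network: bool
    _means: pd.Series = field(repr=False, default=None)
    _cov: pd.DataFrame = field(repr=False, default=None)

    def pairwise(self) -> pd.DataFrame:
        return pairwise_posthoc(self)


def _ols_fit(data: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame, float, float]:
    """Cell-means OLS: returns (means, cov of means, mse, resid df)."""
    types = sorted(data["vegetation_type"].unique())
    means = data.groupby("vegetation_type")["value"].mean()[types]
    n = data.groupby("vegetation_type")["value"].size()[types]
    k, ntot = len(types), len(data)
    resid = data["value"] - means[data["vegetation_type"]].to_numpy()
    df_den = ntot - k
    mse = float((resid**2).sum() / df_den) if df_den > 0 else np.nan
    cov = pd.DataFrame(np.diag(mse / n.to_numpy(dtype=float)), index=types, columns=types)
    return means, cov, mse, df_den


def _gls_means_cov(
    data: pd.DataFrame, types: list[str], var_re: float, scale: float
) -> tuple[pd.Series, pd.DataFrame]:
    """GLS type means and covariance at given variance components.

    V = scale*I + var_re*ZZ' with Z the network indicator; inverted per
    network block via Sherman-Morrison.  Always positive definite, unlike
    the observed-information covariance of a boundary REML fit.
    """
    x = pd.get_dummies(data["vegetation_type"])[types].to_numpy(dtype=float)
    y = data["value"].to_numpy(dtype=float)
    xtvx = np.zeros((len(types), len(types)))
    xtvy = np.zeros(len(types))
    for _, idx in data.groupby("network").indices.items():
        xg, yg = x[idx], y[idx]
        ng = len(idx)
        shrink = var_re / (scale + ng * var_re)
        xs, ys = xg.sum(axis=0), yg.sum()
        xtvx += (xg.T @ xg - shrink * np.outer(xs, xs)) / scale
        xtvy += (xg.T @ yg - shrink * xs * ys) / scale
    cov = np.linalg.inv(xtvx)
    means = pd.Series(cov @ xtvy, index=types)
    return means, pd.DataFrame(cov, index=types, columns=types)


def fit_magnitude_model(
    site_means: pd.DataFrame,
    metadata: pd.DataFrame,
    season: str = "JJA",
    flux: str = "LE",
    df_method: str = "residual",
) -> MagnitudeFit:
    """Fit per-type magnitudes of one flux with network as random effect.

    Parameters
    ----------
    site_means : long frame (site_id, season, response, value) as produced
        by :func:`arcticseb.varpart.seasonal_site_means`.
    metadata : site table with ``vegetation_type`` and ``network`` columns.
    df_method : "residual" (default) computes the denominator df as
        ``n - k - (n_networks - 1)``; "n-k" ignores the network term.

    With a single network (or zero between-network variance) the estimates
    equal ordinary per-type means of site means and the omnibus F equals the
    one-way ANOVA F.
    """
    sub = site_means[
        (site_means["season"] == season) & (site_means["response"] == flux)
    ][["site_id", "value"]]
    data = sub.merge(
        metadata[["site_id", "vegetation_type", "network"]], on="site_id", how="inner"
    ).dropna(subset=["value"])
    if data.empty:
        raise ValueError(f"no site means for flux {flux!r}, season {season!r}")
    types = sorted(data["vegetation_type"].unique())
    k = len(types)
    if k < 2:
        raise ValueError("need at least 2 vegetation types with sites")
    networks = data["network"].unique()
    single_network = len(networks) == 1

    if single_network:
        means, cov, _, df_den = _ols_fit(data)
    else:
        import statsmodels.formula.api as smf

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value ~ 0 + C(vegetation_type)", data, groups=data["network"]
            )
            fit = model.fit(reml=True)
        # rebuild means and covariance by GLS at the REML variance
        # components: equal to the model output away from the boundary,
        # and well-defined when the between-network variance hits zero
        means, cov = _gls_means_cov(
            data, types, float(fit.cov_re.iloc[0, 0]), float(fit.scale)
        )
        if df_method == "residual":
            df_den = len(data) - k - (len(networks) - 1)
        elif df_method == "n-k":
            df_den = len(data) - k
        else:
            raise ValueError(f"unknown df_method {df_method!r}")
        df_den = max(df_den, 1)

    # omnibus Wald F for equality of type means
    L = np.zeros((k - 1, k))
    L[:, 0] = 1.0
    L[np.arange(k - 1), np.arange(1, k)] = -1.0
    lb = L @ means.to_numpy()
    lcov = L @ cov.to_numpy() @ L.T
    try:
        effect_F = float(lb @ np.linalg.solve(lcov, lb) / (k - 1))
    except np.linalg.LinAlgError:
        effect_F = np.nan
    p_value = (
        float(stats.f.sf(effect_F, k - 1, df_den)) if np.isfinite(effect_F) else np.nan
    )

    n_missing = len(set(STANDARD_TYPES) - set(types))
    suppressed = n_missing >= 3

    n_sites = data.groupby("vegetation_type")["value"].size()[types]
    tcrit = stats.t.ppf(0.975, df_den)
    estimates = pd.DataFrame(
        {
            "vegetation_type": types,
            "mean": means.to_numpy(),
            # boundary REML fits can yield tiny negative variance estimates
            "ci95_halfwidth": tcrit * np.sqrt(np.clip(np.diag(cov.to_numpy()), 0, None)),
            "n_sites": n_sites.to_numpy(),
        }
    )
    return MagnitudeFit(
        season=season,
        flux=flux,
        estimates=estimates,
        effect_F=effect_F if not suppressed else np.nan,
        df_num=k - 1,
        df_den=float(df_den),
        p_value=p_value if not suppressed else np.nan,
        effect_suppressed=suppressed,
        single_network=single_network,
        _means=means,
        _cov=cov,
    )


def pairwise_posthoc(fit: MagnitudeFit) -> pd.DataFrame:
    """All pairwise type contrasts with Bonferroni-adjusted p-values.

    Raw two-sided p-values from t-statistics on the fit's denominator df are
    multiplied by the number of comparisons (C(k,2)) and capped at 1.
    """
    types = list(fit._means.index)
    k = len(types)
    n_comp = k * (k - 1) // 2
    rows = []
    cov = fit._cov.to_numpy()
    means = fit._means.to_numpy()
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
            if se == 0.0:
                t, p_raw = 0.0, 1.0
            else:
                t = diff / se
                p_raw = 2.0 * float(stats.t.sf(abs(t), fit.df_den))
            rows.append(
                {
                    "type_i": types[i],
                    "type_j": types[j],
                    "difference": diff,
                    "se": se,
                    "t": t,
                    "p_raw": p_raw,
                    "p_adjusted": min(1.0, p_raw * n_comp),
                }
            )
    return pd.DataFrame(rows)


def bowen_ratio(h_mean: float, le_mean: float) -> float:
    """Bowen ratio H/LE.  Raises ``ZeroDivisionError`` when LE is zero."""
    if le_mean == 0.0:
        raise ZeroDivisionError("Bowen ratio undefined for LE = 0")
    return h_mean / le_mean


def bowen_ratio_display(h_mean: float, le_mean: float) -> str:
    """Bowen ratio formatted at one decimal, with the conventional
    "<0" label when LE is zero and H negative."""
    if le_mean == 0.0:
        return "<0" if h_mean < 0 else "undefined"
    return f"{round(bowen_ratio(h_mean, le_mean), 1):.1f}"


def magnitude_table(
    site_means: pd.DataFrame,
    metadata: pd.DataFrame,
    season: str = "JJA",
    fluxes: tuple[str, ...] = ("R_net", "H", "LE", "G", "SW_net", "LW_net"),
) -> pd.DataFrame:
    """Per-type mean +/- CI for several fluxes in one table (long format)."""
    rows = []
    for flux in fluxes:
        try:
            fit = fit_magnitude_model(site_means, metadata, season=season, flux=flux)
        except (ValueError, np.linalg.LinAlgError):
            # saturated or degenerate design for this flux; skip it
            continue
        for rec in fit.estimates.to_dict("records"):
            rows.append(
                {
                    "season": season,
                    "flux": flux,
                    **rec,
                    "effect_F": fit.effect_F,
                    "df_num": fit.df_num,
                    "df_den": fit.df_den,
                    "p_value": fit.p_value,
                }
            )
    return pd.DataFrame(rows)
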