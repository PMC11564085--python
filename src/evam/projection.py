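"""Log-linear mortality trend fitting and projection.

Each cell (an age–cause or age–sex–cause series for the frontier, or a
country–sex–age–cause series for country surfaces) is fitted by ordinary
least squares of log(rate) on calendar year over the fit window, then
projected forward as rate(t) = exp(intercept + slope * (t - ref)).

Zero-rate years are excluded from the fit; a series with fewer than two
positive years degenerates to a flat line at its last positive value, and
an all-zero series projects zero.  Fits weight all years equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .causes import CauseTree
from .frontier import nested_rescale

__all__ = ["LogLinearFit", "fit_loglinear", "project", "fit_surface", "project_surface"]


@dataclass(frozen=True)
class LogLinearFit:
    intercept: float
    slope: float
    n_obs: int
    reference_year: int
    all_zero: bool = False


def fit_loglinear(series: pd.Series, reference_year: int | None = None) -> LogLinearFit:
    """OLS of log(rate) on year for a single ``year -> rate`` series.

    ``series`` is indexed by calendar year.  Only strictly positive rates
    enter the fit.
    """
    if len(series) == 0:
        raise ValueError("fit window is empty")
    years = np.asarray(series.index, dtype=float)
    rates = np.asarray(series.values, dtype=float)
    ref = int(reference_year if reference_year is not None else years.min())
    pos = rates > 0
    n = int(pos.sum())
    if n == 0:
        return LogLinearFit(-np.inf, 0.0, 0, ref, all_zero=True)
    if n == 1:
        return LogLinearFit(float(np.log(rates[pos][-1])), 0.0, 1, ref)
    x = years[pos] - ref
    y = np.log(rates[pos])
    slope, intercept = np.polyfit(x, y, 1)
    return LogLinearFit(float(intercept), float(slope), n, ref)


def project(fit: LogLinearFit, years: Iterable[int]) -> pd.Series:
    """Evaluate the fitted line: rate(t) = exp(b0 + b1*(t - ref))."""
    years = np.asarray(list(years), dtype=float)
    if fit.all_zero:
        vals = np.zeros_like(years)
    else:
        vals = np.exp(fit.intercept + fit.slope * (years - fit.reference_year))
    return pd.Series(vals, index=years.astype(int))


def fit_surface(
    df: pd.DataFrame,
    cell_cols: Sequence[str],
    fit_window: tuple[int, int],
    value_col: str = "rate",
    reference_year: int | None = None,
) -> pd.DataFrame:
    """Vectorized per-cell OLS over a long table.

    Returns one row per cell with columns ``intercept, slope, n_obs,
    all_zero``.  Identical to :func:`fit_loglinear` applied cell by cell.
    """
    cell_cols = list(cell_cols)
    ref = int(reference_year if reference_year is not None else fit_window[0])
    win = df[(df["year"] >= fit_window[0]) & (df["year"] <= fit_window[1])]
    universe = win[cell_cols].drop_duplicates()

    pos = win[win[value_col] > 0].copy()
    pos["_x"] = pos["year"].astype(float) - ref
    pos["_y"] = np.log(pos[value_col].astype(float))
    # two-pass centered OLS: slope = S_(x-xbar)(y-ybar) / S_(x-xbar)^2
    g = pos.groupby(cell_cols, sort=False)
    means = g.agg(n_obs=("_x", "size"), xbar=("_x", "mean"), ybar=("_y", "mean")).reset_index()
    pos = pos.merge(means, on=cell_cols)
    pos["_cxx"] = (pos["_x"] - pos["xbar"]) ** 2
    pos["_cxy"] = (pos["_x"] - pos["xbar"]) * (pos["_y"] - pos["ybar"])
    agg = (
        pos.groupby(cell_cols, sort=False)
        .agg(sxx=("_cxx", "sum"), sxy=("_cxy", "sum"))
        .reset_index()
        .merge(means, on=cell_cols)
    )
    last_pos = (
        pos.sort_values("year").groupby(cell_cols, sort=False)["_y"].last().rename("last_log")
    ).reset_index()
    agg = agg.merge(last_pos, on=cell_cols)

    n = agg["n_obs"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = agg["sxy"].to_numpy() / agg["sxx"].to_numpy()
        intercept = agg["ybar"].to_numpy() - slope * agg["xbar"].to_numpy()
    single = n < 2
    slope = np.where(single, 0.0, slope)
    intercept = np.where(single, agg["last_log"].to_numpy(), intercept)
    agg["slope"] = slope
    agg["intercept"] = intercept
    agg["all_zero"] = False

    out = universe.merge(
        agg[cell_cols + ["intercept", "slope", "n_obs", "all_zero"]],
        on=cell_cols,
        how="left",
    )
    zero = out["n_obs"].isna()
    out.loc[zero, ["slope", "n_obs"]] = 0.0
    out.loc[zero, "intercept"] = -np.inf
    out.loc[zero, "all_zero"] = True
    out["n_obs"] = out["n_obs"].astype(int)
    out["reference_year"] = ref
    return out


def project_surface(
    surface: pd.DataFrame,
    cell_cols: Sequence[str],
    fit_window: tuple[int, int],
    horizon: tuple[int, int],
    tree: CauseTree | None = None,
    allcause_target: pd.DataFrame | None = None,
    value_col: str = "rate",
    mixed_sex: bool = False,
) -> pd.DataFrame:
    """Fit every cell over ``fit_window`` and extend through ``horizon``.

    Observed rows are passed through (provenance ``observed``); horizon
    rows are the fitted projections (provenance ``projected``).  When
    ``tree`` is given, projected years are rescaled level-wise so causes
    sum to the all-cause series — ``allcause_target`` if provided,
    otherwise the surface's own projected root.
    """
    cell_cols = list(cell_cols)
    fits = fit_surface(surface, cell_cols, fit_window, value_col=value_col)
    years = np.arange(horizon[0], horizon[1] + 1)

    reps = fits.loc[fits.index.repeat(len(years))].reset_index(drop=True)
    reps["year"] = np.tile(years, len(fits))
    with np.errstate(over="ignore"):
        vals = np.exp(
            reps["intercept"].to_numpy()
            + reps["slope"].to_numpy() * (reps["year"].to_numpy() - reps["reference_year"].to_numpy())
        )
    vals = np.where(reps["all_zero"].to_numpy(), 0.0, vals)
    reps[value_col] = vals
    projected = reps[cell_cols + ["year", value_col]]

    if tree is not None:
        target = allcause_target
        if target is not None:
            target = target[
                (target["year"] >= horizon[0]) & (target["year"] <= horizon[1])
            ]
        projected = nested_rescale(
            projected,
            tree,
            target=target,
            value_col=value_col,
            mixed_sex=mixed_sex,
        )

    observed = surface[
        (surface["year"] >= fit_window[0]) & (surface["year"] <= fit_window[1])
    ][cell_cols + ["year", value_col]]
    out = pd.concat(
        [observed.assign(provenance="observed"), projected.assign(provenance="projected")],
        ignore_index=True,
    )
    return out.sort_values(cell_cols + ["year"], ignore_index=True)
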