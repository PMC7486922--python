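"""In-season forecasting and evaluation.

Early (monthly) prediction truncates the cube to the days observed by the
cutoff and uses a model trained at that length; daily forecasting keeps the
observed prefix and fills the remaining days from a per-county climatology.
Predictions are re-trended from the base-year scale to each sample's year,
aggregated to state and Corn-Belt level (acre-weighted when acreage is
known), and scored by MAE, MAPE and error-band fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calendar as cal
from .cube import FeatureCube
from .features import DetrendScheme, recompute_cumulative, retrend_yield

__all__ = [
    "truncate_cube",
    "build_climatology",
    "impute_future",
    "as_of_day_cube",
    "predict_records",
    "aggregate",
    "error_metrics",
    "score",
    "EvalReport",
]


def truncate_cube(cube: FeatureCube, cutoff: str) -> FeatureCube:
    """Keep the days observed by a monthly cutoff (aug/sep/oct/nov).

    Cumulative channels are truncated, not recomputed: a prefix sum over the
    observed days is unaffected by dropping the future.
    """
    if cutoff not in cal.CUTOFF_DAYS:
        raise ValueError(f"unknown cutoff {cutoff!r}; expected one of {sorted(cal.CUTOFF_DAYS)}")
    if cube.n_time != cal.SEASON_DAYS:
        raise ValueError("truncation starts from the full 214-day cube")
    return cube.truncate(cal.CUTOFF_DAYS[cutoff])


def build_climatology(weather, county: str, before_year: int, n_years: int = 10):
    """Per-day channel means over the ``n_years`` seasons before ``before_year``."""
    years = sorted({y for c, y in weather.data if c == county and y < before_year})
    if len(years) < n_years:
        raise ValueError(
            f"need {n_years} prior years of weather for {county}, have {len(years)}"
        )
    use = years[-n_years:]
    chans = weather.data[(county, use[0])].keys()
    return {
        name: np.mean([weather.data[(county, y)][name] for y in use], axis=0) for name in chans
    }


def impute_future(partial: dict[str, np.ndarray], climatology: dict[str, np.ndarray]):
    """Stitch an observed prefix onto climatological expectations.

    The observed days are kept verbatim; the remaining days come from the
    climatology.  Cumulative channels are recomputed over the stitched
    series so they accumulate expected rainfall and degree days.
    """
    daily = {k: v for k, v in climatology.items() if k not in ("cum_rain_in", "cum_gdd")}
    n_obs = None
    out = {}
    for name, clim in daily.items():
        obs = np.asarray(partial.get(name, []), dtype=float)
        if n_obs is None:
            n_obs = obs.size
        elif obs.size != n_obs:
            raise ValueError("observed prefixes differ in length across channels")
        if obs.size > cal.SEASON_DAYS:
            raise ValueError("observed prefix longer than the season window")
        out[name] = np.concatenate([obs, np.asarray(clim, dtype=float)[obs.size :]])
    out.update(recompute_cumulative(out))
    return out


def as_of_day_cube(
    cube: FeatureCube,
    as_of_day: int,
    years,
    n_hist: int = 10,
) -> FeatureCube:
    """Daily-forecast view: keep each target sample's first ``as_of_day`` days,
    fill the rest from its county's per-day mean over the ``n_hist`` prior
    years present in the cube, and recompute cumulative channels.

    The result has the full 214-day length, so the regular full-season model
    scores it -- the daily-update mode reuses the best seasonal model rather
    than retraining one model per calendar day.
    """
    if cube.n_time != cal.SEASON_DAYS:
        raise ValueError("daily forecasting starts from the full-season cube")
    if not 0 <= as_of_day <= cal.SEASON_DAYS:
        raise ValueError(f"as_of_day must be in [0, {cal.SEASON_DAYS}]")
    years = set(years)
    names = cube.var_names
    cum_names = ("cum_rain_in", "cum_gdd")
    by_unit: dict[str, dict[int, int]] = {}
    for j, k in enumerate(cube.sample_keys):
        if not k.augmented:
            by_unit.setdefault(k.unit, {})[k.year] = j
    target_idx = [
        j for j, k in enumerate(cube.sample_keys) if k.year in years and not k.augmented
    ]
    if not target_idx:
        raise ValueError("no samples in the requested forecast years")
    new_values = cube.values.copy()
    for j in target_idx:
        key = cube.sample_keys[j]
        prior = sorted(y for y in by_unit[key.unit] if y < key.year)
        if len(prior) < n_hist:
            raise ValueError(
                f"{key.unit} has {len(prior)} prior years in the cube; need {n_hist}"
            )
        hist = [by_unit[key.unit][y] for y in prior[-n_hist:]]
        clim = cube.values[:, :, hist].mean(axis=2)
        climatology = {name: clim[i] for i, name in enumerate(names)}
        partial = {
            name: cube.values[i, :as_of_day, j]
            for i, name in enumerate(names)
            if name not in cum_names
        }
        stitched = impute_future(partial, climatology)
        for i, name in enumerate(names):
            if name in stitched:
                new_values[i, :, j] = stitched[name]
    mask = np.isin(np.arange(cube.n_samples), target_idx)
    out = cube.subset(mask)
    out.values = new_values[:, :, mask]
    return out


def predict_records(
    results,
    cube: FeatureCube,
    scheme: DetrendScheme,
    cutoff: str = "nov",
) -> pd.DataFrame:
    """Per-county prediction table on the nominal (target-year) yield scale.

    Augmented (pair-averaged) samples are excluded: they exist to enlarge
    training, not to be forecast.  Includes true yields when the cube
    carries targets (re-trended with the same scheme).
    """
    keep = ~cube.augmented
    sub = cube.subset(keep)
    detrended = results.predict(sub)
    rows = []
    for i, key in enumerate(sub.sample_keys):
        pred = float(retrend_yield(detrended[i], key.year, scheme))
        row = {
            "state": key.state,
            "crd": key.crd,
            "county": key.unit,
            "year": key.year,
            "cutoff": cutoff,
            "pred_bu_ac": pred,
        }
        if sub.targets is not None and np.isfinite(sub.targets[i]):
            row["true_bu_ac"] = float(retrend_yield(sub.targets[i], key.year, scheme))
        rows.append(row)
    df = pd.DataFrame(rows)
    if (df["pred_bu_ac"] <= 0).any():
        raise ValueError("non-positive re-trended prediction")
    return df


def aggregate(
    predictions: pd.DataFrame,
    geography=None,
    level: str = "state",
    value_cols: tuple[str, ...] = ("pred_bu_ac", "true_bu_ac"),
) -> pd.DataFrame:
    """Per-year weighted mean of county values at state or Corn-Belt level.

    Weights are harvested acres when the geography provides them; otherwise
    the unweighted county mean (the fallback is logged by the CLI).
    """
    if level not in ("state", "belt"):
        raise ValueError(f"unknown aggregation level {level!r}")
    if predictions.empty:
        raise ValueError("no predictions to aggregate")
    df = predictions.copy()
    acres = geography.acres if geography is not None and geography.acres else None
    if acres is None:
        logging.getLogger("maizecast").warning(
            "no harvested-acre weights available; falling back to unweighted county mean"
        )
    df["_w"] = [acres.get(c, np.nan) for c in df["county"]] if acres else 1.0
    if acres and df["_w"].isna().any():
        df["_w"] = df["_w"].fillna(df["_w"].mean())
    keys = ["year"] if level == "belt" else ["state", "year"]
    cols = [c for c in value_cols if c in df.columns]

    def wmean(g):
        w = g["_w"].to_numpy()
        return pd.Series({c: float(np.average(g[c].to_numpy(), weights=w)) for c in cols})

    return df.groupby(keys).apply(wmean, include_groups=False).reset_index()


def error_metrics(pred, true, bands=(20.0, 30.0)) -> dict:
    """MAE (bu/ac), MAPE (%), and the share of errors within each +-band."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth misaligned")
    if np.any(true == 0):
        raise ValueError("true yield of zero makes MAPE undefined")
    err = np.abs(pred - true)
    out = {
        "mae": float(err.mean()),
        "mape": float(100.0 * np.mean(err / np.abs(true))),
        "n": int(err.size),
    }
    for band in bands:
        out[f"within_{band:g}"] = float(np.mean(err <= band))
    return out


@dataclass
class EvalReport:
    """County-level errors plus state/belt aggregated series and metrics."""

    county_table: pd.DataFrame
    metrics: dict                       # county-level MAE/MAPE/bands
    state_table: pd.DataFrame | None = None
    belt_table: pd.DataFrame | None = None
    state_metrics: dict | None = None   # per state: metrics on yearly aggregates
    belt_metrics: dict | None = None
    bands: tuple[float, ...] = (20.0, 30.0)

    def to_dict(self) -> dict:
        out = {"county": self.metrics, "bands": list(self.bands)}
        if self.state_metrics is not None:
            out["state"] = self.state_metrics
        if self.belt_metrics is not None:
            out["belt"] = self.belt_metrics
        return out


def score(
    predictions: pd.DataFrame,
    geography=None,
    bands: tuple[float, ...] = (20.0, 30.0),
) -> EvalReport:
    """Score a prediction table carrying both pred_bu_ac and true_bu_ac.

    County-level metrics are computed on per-county errors; state and belt
    metrics on the aggregated yearly series (the convention used when
    comparing whole-region estimates year by year).
    """
    if "true_bu_ac" not in predictions.columns:
        raise ValueError("predictions carry no truth column to score against")
    df = predictions.copy()
    df["abs_err"] = (df["pred_bu_ac"] - df["true_bu_ac"]).abs()
    metrics = error_metrics(df["pred_bu_ac"], df["true_bu_ac"], bands)

    state_table = belt_table = None
    state_metrics = belt_metrics = None
    if geography is not None:
        state_table = aggregate(df, geography, level="state")
        belt_table = aggregate(df, geography, level="belt")
        state_metrics = {
            s: error_metrics(g["pred_bu_ac"], g["true_bu_ac"], bands)
            for s, g in state_table.groupby("state")
        }
        belt_metrics = error_metrics(belt_table["pred_bu_ac"], belt_table["true_bu_ac"], bands)
    return EvalReport(
        county_table=df,
        metrics=metrics,
        state_table=state_table,
        belt_table=belt_table,
        state_metrics=state_metrics,
        belt_metrics=belt_metrics,
        bands=tuple(bands),
    )


def plot_predictions(report: EvalReport, path) -> None:
    """Scatter of predicted vs. true county yields with the error bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.county_table
    fig, ax = plt.subplots(figsize=(5, 5))
    lo = min(df["true_bu_ac"].min(), df["pred_bu_ac"].min()) - 5
    hi = max(df["true_bu_ac"].max(), df["pred_bu_ac"].max()) + 5
    line = np.array([lo, hi])
    ax.plot(line, line, "k-", lw=0.8)
    for band, color in zip(report.bands, ("tab:blue", "tab:cyan")):
        ax.plot(line, line + band, color=color, lw=0.8, ls="--")
        ax.plot(line, line - band, color=color, lw=0.8, ls="--",
                label=f"±{band:g} bu/ac")
    ax.scatter(df["true_bu_ac"], df["pred_bu_ac"], s=8, alpha=0.6)
    ax.set_xlabel("actual yield (bu/ac)")
    ax.set_ylabel("predicted yield (bu/ac)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
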