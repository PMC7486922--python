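"""Feature engineering: degree days, de-trending, and the candidate channels.

Turns the raw panels into per-sample daily feature channels: hourly-to-daily
aggregation, growing degree days (GDD, base 50 F / cap 86 F), cumulative
series, genetic-gain de-trending of the yield target, the 28-channel
candidate set and the canonical 10-channel model input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calendar as cal

__all__ = [
    "gdd",
    "DetrendScheme",
    "detrend_yield",
    "retrend_yield",
    "hourly_to_daily",
    "FeaturePanel",
    "build_candidate_features",
    "select_final_channels",
    "recompute_cumulative",
    "CANONICAL_CHANNELS",
    "CANDIDATE_CHANNELS",
]

#: Fixed order of the ten model-input channels (the variable axis of the cube).
CANONICAL_CHANNELS: tuple[str, ...] = (
    "tmax_f",
    "tmin_f",
    "tmean_f",
    "rain_in",
    "wind_mph",
    "rootznaws",
    "droughty",
    "pdsi",
    "cum_rain_in",
    "cum_gdd",
)


def gdd(tmax_f, tmin_f):
    """Growing degree days (F-day) for one or more days.

    GDD = (min(86, Tmax) + max(50, Tmin)) / 2 - 50, floored at zero.  The cap
    and floor reflect maize physiology: development stalls above 86 F and
    below the 50 F base.  Cold days for which the capped average falls below
    the base accumulate zero rather than negative degree days.

    Raises if any raw Tmax < Tmin.
    """
    tmax_f = np.asarray(tmax_f, dtype=float)
    tmin_f = np.asarray(tmin_f, dtype=float)
    if np.any(tmax_f < tmin_f):
        raise ValueError("tmax < tmin")
    val = (np.minimum(86.0, tmax_f) + np.maximum(50.0, tmin_f)) / 2.0 - 50.0
    out = np.maximum(val, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DetrendScheme:
    """Genetic-gain adjustment projecting yields onto a common base year.

    ``percentage`` compounds a fixed annual gain (default 1.5 %/yr);
    ``absolute`` adds fixed increments per year-step: 2.5 bu/ac for steps
    ending in or before 2000, 4.67 bu/ac thereafter.
    """

    kind: str = "percentage"           # "percentage" | "absolute"
    rate: float = 0.015                # /yr (percentage)
    incr_pre2000: float = 2.5          # bu/ac per year-step ending <= 2000
    incr_post2000: float = 4.67        # bu/ac per year-step ending > 2000
    base_year: int = 2013

    def __post_init__(self) -> None:
        if self.kind not in ("percentage", "absolute"):
            raise ValueError(f"unknown de-trending scheme {self.kind!r}")
        if self.rate <= -1:
            raise ValueError("rate must exceed -1")

    def _offset(self, year: int) -> float:
        """Signed cumulative absolute gain from ``year`` up to the base year."""
        step = lambda s: self.incr_pre2000 if s + 1 <= 2000 else self.incr_post2000
        if year <= self.base_year:
            return sum(step(s) for s in range(year, self.base_year))
        return -sum(step(s) for s in range(self.base_year, year))


def detrend_yield(y, year: int, scheme: DetrendScheme):
    """Project a nominal-year yield onto the scheme's base-year scale."""
    if scheme.kind == "percentage":
        return y * (1.0 + scheme.rate) ** (scheme.base_year - year)
    return y + scheme._offset(year)


def retrend_yield(adjusted, year: int, scheme: DetrendScheme):
    """Exact inverse of :func:`detrend_yield`."""
    if scheme.kind == "percentage":
        return adjusted * (1.0 + scheme.rate) ** (year - scheme.base_year)
    return adjusted - scheme._offset(year)


def hourly_to_daily(hourly: pd.DataFrame, allow_partial: bool = False) -> pd.DataFrame:
    """Aggregate an hourly table to the daily weather channels.

    Expects columns county, year, doy, hour, temp_f, rain_in, wind_mph with 24
    rows per county-day.  Temperature aggregates to max/min/mean, rainfall to
    total and max-hourly, wind to the mean.  A day with fewer than 24 hours is
    an error unless ``allow_partial``, which accepts >= 20 hours (means are
    then over the available hours; totals are raw sums).
    """
    counts = hourly.groupby(["county", "year", "doy"])["hour"].count()
    bad = counts[counts != 24]
    if len(bad):
        if not allow_partial or (counts < 20).any():
            raise ValueError(f"{len(bad)} county-days do not have 24 hourly rows")
    g = hourly.groupby(["county", "year", "doy"], sort=True)
    out = pd.DataFrame(
        {
            "tmax_f": g["temp_f"].max(),
            "tmin_f": g["temp_f"].min(),
            "tmean_f": g["temp_f"].mean(),
            "rain_in": g["rain_in"].sum(),
            "rain_max_hr_in": g["rain_in"].max(),
            "wind_mph": g["wind_mph"].mean(),
        }
    )
    return out.reset_index()


@dataclass
class FeaturePanel:
    """Named daily channels per (county, year), plus the de-trended target.

    Every channel is a float array over the 214-day window.  The registry
    records how each channel varies in time: ``daily`` (weather), ``monthly``
    (the drought index, repeated over each month's days) or ``constant``
    (soil attributes and seasonal aggregates, repeated 214 times).
    """

    channels: dict[tuple, dict[str, np.ndarray]]
    registry: dict[str, str]
    target: dict[tuple, float] = field(default_factory=dict)
    n_time: int = cal.SEASON_DAYS

    @property
    def keys(self) -> list[tuple]:
        return list(self.channels)

    @property
    def channel_names(self) -> list[str]:
        return list(self.registry)

    def validate(self) -> None:
        for key, chans in self.channels.items():
            if set(chans) != set(self.registry):
                raise ValueError(f"channel set mismatch for {key}")
            for name, arr in chans.items():
                if len(arr) != self.n_time:
                    raise ValueError(f"{name} for {key} has length {len(arr)} != {self.n_time}")
                if self.registry[name] == "constant" and np.ptp(arr) != 0:
                    raise ValueError(f"constant channel {name} varies in time for {key}")

    def subset(self, names) -> "FeaturePanel":
        names = list(names)
        missing = [n for n in names if n not in self.registry]
        if missing:
            raise KeyError(f"channels not in panel: {missing}")
        return FeaturePanel(
            channels={k: {n: v[n] for n in names} for k, v in self.channels.items()},
            registry={n: self.registry[n] for n in names},
            target=dict(self.target),
            n_time=self.n_time,
        )


def recompute_cumulative(chans: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Prefix-sum channels derived from the dailies: cumulative rain and GDD."""
    return {
        "cum_rain_in": np.cumsum(chans["rain_in"]),
        "cum_gdd": np.cumsum(gdd(chans["tmax_f"], chans["tmin_f"])),
    }


def build_candidate_features(weather, soil, pdsi_daily, acres_ratio) -> FeaturePanel:
    """Assemble the 28 candidate channels per county-year.

    14 soil constants + drought index + the six daily weather channels +
    cumulative rain and GDD + July rainfall and July max temperature
    (broadcast as constants) + the corn-acres ratio + two interaction
    channels (Tmax x droughty, Tmax x PDSI).

    ``pdsi_daily`` maps (county, year) -> length-214 daily drought series
    (see :func:`maizecast.cube.broadcast_pdsi`); ``acres_ratio`` maps
    county -> corn-acres share.
    """
    from .synth import SOIL_COLUMNS  # local import avoids a cycle at module load

    ones = np.ones(cal.SEASON_DAYS)
    registry: dict[str, str] = {name: "constant" for name in SOIL_COLUMNS}
    registry["pdsi"] = "monthly"
    for name in ("tmax_f", "tmin_f", "tmean_f", "rain_in", "wind_mph", "rain_max_hr_in"):
        registry[name] = "daily"
    registry["cum_rain_in"] = "daily"
    registry["cum_gdd"] = "daily"
    registry["july_rain_in"] = "constant"
    registry["july_tmax_f"] = "constant"
    registry["corn_acres_ratio"] = "constant"
    registry["tmax_x_droughty"] = "daily"
    registry["tmax_x_pdsi"] = "daily"
    assert len(registry) == 28

    channels: dict[tuple, dict[str, np.ndarray]] = {}
    for (county, year), w in weather.data.items():
        if county not in soil.table.index:
            raise KeyError(f"soil constants missing for {county}")
        if (county, year) not in pdsi_daily:
            raise KeyError(f"daily PDSI missing for {(county, year)}")
        soil_row = soil.table.loc[county]
        pdsi = np.asarray(pdsi_daily[(county, year)], dtype=float)
        chans: dict[str, np.ndarray] = {name: float(soil_row[name]) * ones for name in SOIL_COLUMNS}
        chans["pdsi"] = pdsi
        for name in ("tmax_f", "tmin_f", "tmean_f", "rain_in", "wind_mph", "rain_max_hr_in"):
            chans[name] = np.asarray(w[name], dtype=float)
        chans.update(recompute_cumulative(chans))
        chans["july_rain_in"] = float(chans["rain_in"][cal.JULY_SLICE].sum()) * ones
        chans["july_tmax_f"] = float(chans["tmax_f"][cal.JULY_SLICE].max()) * ones
        chans["corn_acres_ratio"] = float(acres_ratio[county]) * ones
        chans["tmax_x_droughty"] = chans["tmax_f"] * float(soil_row["droughty"])
        chans["tmax_x_pdsi"] = chans["tmax_f"] * pdsi
        channels[(county, year)] = chans

    panel = FeaturePanel(channels=channels, registry=registry)
    panel.validate()
    return panel


def select_final_channels(panel: FeaturePanel) -> FeaturePanel:
    """Keep the canonical ten model-input channels in their fixed order."""
    return panel.subset(CANONICAL_CHANNELS)


def attach_detrended_target(panel: FeaturePanel, yields, scheme: DetrendScheme) -> FeaturePanel:
    """Set the panel target to the de-trended (base-year scale) yield."""
    table = yields.table.set_index(["county", "year"])["yield_bu_ac"]
    for key in panel.keys:
        if key not in table.index:
            raise KeyError(f"no yield record for {key}")
        panel.target[key] = float(detrend_yield(table.loc[key], key[1], scheme))
    return panel
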