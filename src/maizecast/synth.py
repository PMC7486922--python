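"""Synthetic county panels: geography, weather, soil, drought index, yields.

The public county-yield record is freely available, but the daily weather
panel the forecasting pipeline consumes is commercial and cannot be bundled.
This module generates all five input panels with the statistical structure
the pipeline assumes -- a state/CRD/county hierarchy, smooth seasonal weather
with within-CRD spatial correlation, time-constant soil attributes, a bounded
monthly drought index shared by all counties of a CRD, and yields that combine
a genetic-gain trend with a nonlinear weather response -- so that every
downstream stage is testable end to end.

All generators are pure functions of (arguments, seed); randomness never
touches global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calendar as cal
from .features import gdd

__all__ = [
    "Geography",
    "WeatherPanel",
    "SoilTable",
    "PDSIPanel",
    "YieldPanel",
    "ResponseConfig",
    "SOIL_COLUMNS",
    "simulate_geography",
    "simulate_weather",
    "simulate_soil",
    "simulate_pdsi",
    "simulate_yield",
    "write_panels",
]

#: The fourteen per-county soil constants carried through the pipeline.
#: Root-zone available water storage (mm) and the drought-vulnerability flag
#: are the two that matter agronomically; the rest are standard soil-survey
#: attributes kept constant per county.
SOIL_COLUMNS: tuple[str, ...] = (
    "rootznaws",
    "droughty",
    "om_pct",
    "clay_pct",
    "sand_pct",
    "silt_pct",
    "awc",
    "ksat",
    "cec",
    "ph_water",
    "slope_pct",
    "bulk_density",
    "water_table_cm",
    "frost_free_days",
)


@dataclass
class Geography:
    """State -> CRD -> county hierarchy with per-county acreage attributes.

    CRDs (crop reporting districts) are the sub-state unit at which the
    drought index is reported and at which augmentation pairs are formed.
    """

    states: list[str]
    crds: dict[str, list[str]]              # state -> CRD ids
    counties: dict[str, list[str]]          # CRD -> county ids
    acres: dict[str, float] | None = None   # county -> harvested acres
    corn_ratio: dict[str, float] | None = None  # county -> corn acres / total acres

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for crd, cs in self.counties.items():
            for c in cs:
                if c in seen:
                    raise ValueError(f"county {c!r} assigned to more than one CRD")
                seen.add(c)
        if self.acres is not None and any(a <= 0 for a in self.acres.values()):
            raise ValueError("harvested acres must be positive")

    @property
    def all_counties(self) -> list[str]:
        return [c for crd in self.all_crds for c in self.counties[crd]]

    @property
    def all_crds(self) -> list[str]:
        return [crd for s in self.states for crd in self.crds[s]]

    def crd_of(self, county: str) -> str:
        for crd, cs in self.counties.items():
            if county in cs:
                return crd
        raise KeyError(county)

    def state_of_crd(self, crd: str) -> str:
        for s, crds in self.crds.items():
            if crd in crds:
                return s
        raise KeyError(crd)

    def state_of(self, county: str) -> str:
        return self.state_of_crd(self.crd_of(county))


#: Daily weather channels, in panel column order.
WEATHER_CHANNELS: tuple[str, ...] = (
    "tmax_f",
    "tmin_f",
    "tmean_f",
    "rain_in",
    "rain_max_hr_in",
    "wind_mph",
)


@dataclass
class WeatherPanel:
    """Daily weather over the 214-day window, keyed by (county, year).

    ``data[(county, year)]`` maps channel name -> float array of length 214.
    ``hourly`` (optional) holds per-key hourly tables from which the daily
    channels were derived.
    """

    data: dict[tuple[str, int], dict[str, np.ndarray]]
    hourly: dict[tuple[str, int], pd.DataFrame] | None = None

    def validate(self) -> None:
        for key, chans in self.data.items():
            for name in WEATHER_CHANNELS:
                if len(chans[name]) != cal.SEASON_DAYS:
                    raise ValueError(f"{name} for {key} has wrong length")
            if not np.all(chans["tmin_f"] <= chans["tmean_f"] + 1e-9):
                raise ValueError(f"tmin > tmean for {key}")
            if not np.all(chans["tmean_f"] <= chans["tmax_f"] + 1e-9):
                raise ValueError(f"tmean > tmax for {key}")
            if np.any(chans["rain_in"] < 0) or np.any(chans["wind_mph"] < 0):
                raise ValueError(f"negative rain or wind for {key}")

    @property
    def keys(self) -> list[tuple[str, int]]:
        return list(self.data)


@dataclass
class SoilTable:
    """Per-county soil constants (one row per county, columns SOIL_COLUMNS)."""

    table: pd.DataFrame  # indexed by county

    def row(self, county: str) -> pd.Series:
        return self.table.loc[county]


@dataclass
class PDSIPanel:
    """Monthly Palmer Drought Severity Index per (CRD, year).

    Values are the standardized index in [-10, +10]; one length-7 array
    (April..October) per CRD-year.
    """

    values: dict[tuple[str, int], np.ndarray]

    def validate(self) -> None:
        for key, v in self.values.items():
            if v.shape != (len(cal.SEASON_MONTHS),):
                raise ValueError(f"PDSI series for {key} must cover the 7 season months")
            if np.any(v < -10) or np.any(v > 10):
                raise ValueError(f"PDSI out of [-10, 10] for {key}")


@dataclass
class YieldPanel:
    """County-year maize yields (bu/ac) as a tidy frame.

    Columns: state, crd, county, year, yield_bu_ac and (optionally) acres.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table["yield_bu_ac"] <= 0).any():
            raise ValueError("yields must be positive")
        if self.table.duplicated(["county", "year"]).any():
            raise ValueError("duplicate county-year records")

    def value(self, county: str, year: int) -> float:
        t = self.table
        row = t[(t["county"] == county) & (t["year"] == year)]
        return float(row["yield_bu_ac"].iloc[0])


# --- reference constants for the weather response ---------------------------
# Season cumulative GDD in central Iowa runs near 2,900 F-day; season rainfall
# near 22 in.  Anomalies are expressed against these fixed centers so the
# response function is a pure function of the panels, not of the sample drawn.
_GDD_CENTER, _GDD_SCALE = 2900.0, 300.0
_RAIN_CENTER, _RAIN_SCALE = 22.0, 6.0
_HEAT_SCALE = 30.0  # F-day of exceedance above 90 F in a hot season


@dataclass
class ResponseConfig:
    """Yield-response parameters for the synthetic generator.

    The detrended (base-year scale) yield for county c in year y is

        base_yield + coef_gdd * z_gdd + coef_rain * z_rain - coef_rain_curv * z_rain**2
                   - coef_heat * droughty_c * heat_cy / 30 + coef_pdsi * mean-PDSI
                   + county effect + noise

    and the genetic-gain trend is applied on top: multiplicatively for the
    percentage scheme (1.5 %/yr by default), additively for the absolute
    scheme (2.5 bu/ac/yr through 2000, 4.67 after).  z_gdd and z_rain are
    season totals standardized against fixed agronomic reference values.
    """

    base_yield: float = 180.0
    trend: str = "percentage"          # "percentage" | "absolute"
    trend_rate: float = 0.015          # /yr, percentage scheme
    trend_incr_pre2000: float = 2.5    # bu/ac/yr, absolute scheme
    trend_incr_post2000: float = 4.67
    base_year: int = 2013
    coef_gdd: float = 8.0              # bu/ac per GDD anomaly s.d.
    coef_rain: float = 5.0             # bu/ac per rainfall anomaly s.d.
    coef_rain_curv: float = 1.5        # concavity: flooding hurts
    coef_heat: float = 6.0             # bu/ac per heat-stress unit on droughty soil
    coef_pdsi: float = 2.5             # bu/ac per PDSI point
    county_sd: float = 5.0             # bu/ac, time-constant county effect
    noise_sd: float = 8.0              # bu/ac, observation noise
    yield_floor: float = 5.0           # bu/ac, keeps MAPE finite
    seed: int = 0

    def __post_init__(self) -> None:
        if self.county_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for f in ("coef_gdd", "coef_rain", "coef_rain_curv", "coef_heat", "coef_pdsi"):
            if not np.isfinite(getattr(self, f)):
                raise ValueError(f"{f} must be finite")
        if self.trend not in ("percentage", "absolute"):
            raise ValueError(f"unknown trend scheme {self.trend!r}")


def simulate_geography(
    n_states: int,
    crds_per_state: int,
    counties_per_crd: int,
    seed: int = 0,
) -> Geography:
    """Build a balanced state/CRD/county hierarchy with per-county acreage.

    Ids follow ``S01``, ``S01-D3``, ``S01-D3-C007``.  Harvested acres and the
    corn-acres ratio are drawn once per county.
    """
    if min(n_states, crds_per_state, counties_per_crd) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    states, crds, counties = [], {}, {}
    acres: dict[str, float] = {}
    ratio: dict[str, float] = {}
    for si in range(n_states):
        state = f"S{si + 1:02d}"
        states.append(state)
        crds[state] = []
        for di in range(crds_per_state):
            crd = f"{state}-D{di + 1}"
            crds[state].append(crd)
            counties[crd] = []
            for ci in range(counties_per_crd):
                county = f"{crd}-C{ci + 1:03d}"
                counties[crd].append(county)
                acres[county] = float(rng.uniform(20_000, 120_000))
                ratio[county] = float(rng.uniform(0.2, 0.6))
    return Geography(states=states, crds=crds, counties=counties, acres=acres, corn_ratio=ratio)


def _diurnal_shape() -> np.ndarray:
    # min at 05:00, max at 17:00; mean exactly 0.5 over 24 equally spaced hours
    h = np.arange(24)
    return (1.0 - np.cos(2 * np.pi * (h - 5) / 24)) / 2.0


def simulate_weather(
    geography: Geography,
    years: list[int],
    seed: int = 0,
    hourly: bool = False,
) -> WeatherPanel:
    """Daily (optionally hourly) weather for every county-year.

    Temperature follows a smooth seasonal curve peaking in mid-July, with a
    year-level shift, an AR(1) CRD-level daily anomaly shared by all counties
    of the CRD (this is what makes within-CRD pair averaging meaningful), and
    county-day noise.  Rainfall is an intermittent process whose wet-day
    probability is modulated by a CRD-level moisture anomaly.  With
    ``hourly=True`` a 24-value profile is emitted per day and the daily
    channels are re-derived from it, so max/min/mean round-trip exactly.
    """
    if len(years) == 0:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed)
    d = np.arange(cal.SEASON_DAYS, dtype=float)
    seasonal_tmax = 52.0 + 34.0 * np.sin(np.pi * (d + 16.0) / 246.0)
    shape = _diurnal_shape()

    data: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    hourly_tables: dict[tuple[str, int], pd.DataFrame] = {}
    for crd in geography.all_crds:
        for year in years:
            year_shift = rng.normal(0.0, 1.5)
            # AR(1) anomalies shared within the CRD
            crd_temp = _ar1(rng, cal.SEASON_DAYS, phi=0.7, sd=5.0)
            crd_moist = _ar1(rng, cal.SEASON_DAYS, phi=0.8, sd=1.0)
            for county in geography.counties[crd]:
                tmax = seasonal_tmax + year_shift + crd_temp + rng.normal(0, 2.0, cal.SEASON_DAYS)
                spread = np.clip(rng.normal(20.0, 3.0, cal.SEASON_DAYS), 5.0, None)
                tmin = tmax - spread
                p_wet = np.clip(0.30 + 0.08 * crd_moist, 0.05, 0.90)
                wet = rng.random(cal.SEASON_DAYS) < p_wet
                rain = np.where(wet, rng.exponential(0.32, cal.SEASON_DAYS), 0.0)
                rain_max_hr = rain * (0.3 + 0.6 * rng.random(cal.SEASON_DAYS))
                wind = np.clip(rng.normal(8.0, 2.5, cal.SEASON_DAYS), 0.0, None)
                if hourly:
                    temps = tmin[:, None] + spread[:, None] * shape[None, :]
                    rain_h = _spread_rain_hourly(rng, rain)
                    wind_h = np.clip(
                        wind[:, None] + rng.normal(0, 1.0, (cal.SEASON_DAYS, 24)), 0.0, None
                    )
                    chans = {
                        "tmax_f": temps.max(axis=1),
                        "tmin_f": temps.min(axis=1),
                        "tmean_f": temps.mean(axis=1),
                        "rain_in": rain_h.sum(axis=1),
                        "rain_max_hr_in": rain_h.max(axis=1),
                        "wind_mph": wind_h.mean(axis=1),
                    }
                    hourly_tables[(county, year)] = pd.DataFrame(
                        {
                            "county": county,
                            "year": year,
                            "doy": np.repeat(np.arange(cal.SEASON_DAYS), 24),
                            "hour": np.tile(np.arange(24), cal.SEASON_DAYS),
                            "temp_f": temps.ravel(),
                            "rain_in": rain_h.ravel(),
                            "wind_mph": wind_h.ravel(),
                        }
                    )
                else:
                    frac = np.clip(rng.normal(0.5, 0.05, cal.SEASON_DAYS), 0.05, 0.95)
                    chans = {
                        "tmax_f": tmax,
                        "tmin_f": tmin,
                        "tmean_f": tmin + frac * spread,
                        "rain_in": rain,
                        "rain_max_hr_in": rain_max_hr,
                        "wind_mph": wind,
                    }
                data[(county, year)] = chans
    panel = WeatherPanel(data=data, hourly=hourly_tables if hourly else None)
    panel.validate()
    return panel


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation ``sd``."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0.0, innov_sd)
    return x


def _spread_rain_hourly(rng: np.random.Generator, daily: np.ndarray) -> np.ndarray:
    """Allocate each day's rain total over 1-4 random hours."""
    out = np.zeros((daily.size, 24))
    for i, total in enumerate(daily):
        if total <= 0:
            continue
        k = int(rng.integers(1, 5))
        hours = rng.choice(24, size=k, replace=False)
        w = rng.dirichlet(np.ones(k))
        out[i, hours] = total * w
    return out


def simulate_soil(geography: Geography, seed: int = 0) -> SoilTable:
    """Per-county soil constants; fixed across years by construction."""
    rng = np.random.default_rng(seed)
    rows = []
    for county in geography.all_counties:
        clay = rng.uniform(10, 35)
        sand = rng.uniform(10, 60)
        silt = max(100.0 - clay - sand, 5.0)
        rows.append(
            {
                "county": county,
                "rootznaws": rng.uniform(120, 330),        # mm root-zone water storage
                "droughty": float(rng.random() < 0.3),     # drought-vulnerability flag
                "om_pct": rng.uniform(1.0, 6.0),
                "clay_pct": clay,
                "sand_pct": sand,
                "silt_pct": silt,
                "awc": rng.uniform(0.10, 0.25),
                "ksat": rng.uniform(2.0, 30.0),
                "cec": rng.uniform(8.0, 30.0),
                "ph_water": rng.uniform(5.5, 7.8),
                "slope_pct": rng.uniform(0.5, 9.0),
                "bulk_density": rng.uniform(1.1, 1.6),
                "water_table_cm": rng.uniform(30, 200),
                "frost_free_days": rng.uniform(140, 190),
            }
        )
    table = pd.DataFrame(rows).set_index("county")[list(SOIL_COLUMNS)]
    return SoilTable(table=table)


def simulate_pdsi(geography: Geography, years: list[int], seed: int = 0) -> PDSIPanel:
    """Monthly drought index per CRD-year: bounded AR(1), clipped to [-10, 10].

    Every county of a CRD shares its CRD's series by construction.
    """
    if len(years) == 0:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed)
    values = {}
    for crd in geography.all_crds:
        for year in years:
            series = _ar1(rng, len(cal.SEASON_MONTHS), phi=0.8, sd=2.5)
            values[(crd, year)] = np.clip(series, -10.0, 10.0)
    panel = PDSIPanel(values=values)
    panel.validate()
    return panel


def _trend_offset_absolute(year: int, cfg: ResponseConfig) -> float:
    """Signed cumulative genetic gain from the base year to ``year`` (bu/ac)."""
    step = lambda s: cfg.trend_incr_pre2000 if s + 1 <= 2000 else cfg.trend_incr_post2000
    if year >= cfg.base_year:
        return sum(step(s) for s in range(cfg.base_year, year))
    return -sum(step(s) for s in range(year, cfg.base_year))


def simulate_yield(
    weather: WeatherPanel,
    soil: SoilTable,
    pdsi: PDSIPanel,
    response: ResponseConfig,
    geography: Geography,
) -> YieldPanel:
    """County-year yields from the weather/soil/drought panels.

    Detrended-scale yield is base + nonlinear weather response + county
    effect + noise; the genetic-gain trend then maps it to the nominal year
    (multiplicatively for the percentage scheme so that percentage
    de-trending removes it exactly).  Deterministic given ``response.seed``.
    """
    rng = np.random.default_rng(response.seed)
    counties = geography.all_counties
    county_eff = dict(zip(counties, rng.normal(0.0, response.county_sd, len(counties))))

    keys = sorted(weather.data)
    for county, year in keys:
        crd = geography.crd_of(county)
        if (crd, year) not in pdsi.values:
            raise ValueError(f"PDSI missing for {(crd, year)}")
        if county not in soil.table.index:
            raise ValueError(f"soil missing for {county}")

    rows = []
    for county, year in keys:
        chans = weather.data[(county, year)]
        crd = geography.crd_of(county)
        g = float(gdd(chans["tmax_f"], chans["tmin_f"]).sum())
        r = float(chans["rain_in"].sum())
        heat = float(np.clip(chans["tmax_f"] - 90.0, 0.0, None).sum())
        droughty = float(soil.table.loc[county, "droughty"])
        pdsi_mean = float(pdsi.values[(crd, year)].mean())
        zg = (g - _GDD_CENTER) / _GDD_SCALE
        zr = (r - _RAIN_CENTER) / _RAIN_SCALE
        f = (
            response.coef_gdd * zg
            + response.coef_rain * zr
            - response.coef_rain_curv * zr**2
            - response.coef_heat * droughty * heat / _HEAT_SCALE
            + response.coef_pdsi * pdsi_mean
        )
        stationary = response.base_yield + f + county_eff[county] + rng.normal(0.0, response.noise_sd)
        if response.trend == "percentage":
            y = stationary * (1.0 + response.trend_rate) ** (year - response.base_year)
        else:
            y = stationary + _trend_offset_absolute(year, response)
        rows.append(
            {
                "state": geography.state_of_crd(crd),
                "crd": crd,
                "county": county,
                "year": year,
                "yield_bu_ac": max(y, response.yield_floor),
                "acres": geography.acres[county] if geography.acres else np.nan,
            }
        )
    return YieldPanel(table=pd.DataFrame(rows))


# --- CSV serialization ------------------------------------------------------

def write_panels(
    outdir,
    geography: Geography,
    weather: WeatherPanel,
    soil: SoilTable,
    pdsi: PDSIPanel,
    yields: YieldPanel,
) -> dict[str, str]:
    """Write the five panels as UTF-8 CSVs; returns name -> path."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    yields.table.to_csv(outdir / "yields.csv", index=False)
    paths["yields"] = str(outdir / "yields.csv")

    frames = []
    for (county, year), chans in sorted(weather.data.items()):
        frames.append(
            pd.DataFrame(
                {"county": county, "year": year, "doy": np.arange(cal.SEASON_DAYS)}
                | {name: chans[name] for name in WEATHER_CHANNELS}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(outdir / "weather_daily.csv", index=False)
    paths["weather_daily"] = str(outdir / "weather_daily.csv")

    soil.table.to_csv(outdir / "soil.csv")
    paths["soil"] = str(outdir / "soil.csv")

    rows = []
    for (crd, year), series in sorted(pdsi.values.items()):
        for month, v in zip(cal.SEASON_MONTHS, series):
            rows.append({"crd": crd, "year": year, "month": month, "pdsi": v})
    pd.DataFrame(rows).to_csv(outdir / "pdsi.csv", index=False)
    paths["pdsi"] = str(outdir / "pdsi.csv")

    if geography.corn_ratio is not None:
        pd.DataFrame(
            {"county": list(geography.corn_ratio), "corn_acres_ratio": list(geography.corn_ratio.values())}
        ).to_csv(outdir / "acres_ratio.csv", index=False)
        paths["acres_ratio"] = str(outdir / "acres_ratio.csv")
    return paths
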