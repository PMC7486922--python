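"""Sample assembly: drought-index broadcast, pair augmentation, the 3-D cube.

A sample is one county-year (or one within-CRD county pair, after
augmentation).  The cube stores samples as a 3-D array (variables x time x
samples) with channel names, a day index, per-sample keys, de-trended
targets, and the per-variable standardization statistics computed on
training samples only.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import calendar as cal
from .features import FeaturePanel

__all__ = [
    "SampleKey",
    "SplitSpec",
    "FeatureCube",
    "broadcast_pdsi",
    "augment_pairs",
    "assemble_cube",
    "split_by_year",
]


class SampleKey(NamedTuple):
    state: str
    crd: str
    unit: str        # county id, or "countyA|countyB" for an averaged pair
    year: int
    augmented: bool


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/test year lists."""

    train_years: tuple[int, ...]
    test_years: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.train_years or not self.test_years:
            raise ValueError("train and test year lists must be nonempty")
        if set(self.train_years) & set(self.test_years):
            raise ValueError("train and test years overlap")


def broadcast_pdsi(pdsi_panel, geography) -> dict[tuple[str, int], np.ndarray]:
    """Expand monthly CRD drought values to daily county series.

    Each county inherits its CRD's monthly value, repeated over the days of
    the month (30/31/30/31/31/30/31 for April..October), giving a length-214
    daily channel.  Counties of one CRD share the series by construction.
    """
    month_lengths = np.array(cal.MONTH_LENGTHS)
    out: dict[tuple[str, int], np.ndarray] = {}
    for (crd, year), series in pdsi_panel.values.items():
        series = np.asarray(series, dtype=float)
        if series.shape != (len(cal.SEASON_MONTHS),):
            raise ValueError(f"PDSI for {(crd, year)} must have all 7 season months")
        daily = np.repeat(series, month_lengths)
        for county in geography.counties[crd]:
            out[(county, year)] = daily
    return out


def augment_pairs(panel: FeaturePanel, geography, years=None) -> FeaturePanel:
    """Add the within-CRD county-pair averages as extra samples.

    For every year (restricted to ``years`` when given -- the caller passes
    the training years; averaging test samples would leak them into training
    counts) and every unordered pair of counties in one CRD present that
    year, one sample is added whose every channel and target is the
    arithmetic mean of the pair's.  Originals are kept, so a CRD-year with n
    counties contributes n + C(n, 2) samples.
    """
    years = None if years is None else set(years)
    new_channels = dict(panel.channels)
    new_target = dict(panel.target)
    by_crd_year: dict[tuple[str, int], list[str]] = {}
    for county, year in panel.channels:
        if "|" in county:
            raise ValueError("panel already contains augmented samples")
        if years is not None and year not in years:
            continue
        by_crd_year.setdefault((geography.crd_of(county), year), []).append(county)

    for (crd, year), counties in sorted(by_crd_year.items()):
        for a, b in itertools.combinations(sorted(counties), 2):
            key = (f"{a}|{b}", year)
            ca, cb = panel.channels[(a, year)], panel.channels[(b, year)]
            new_channels[key] = {n: (ca[n] + cb[n]) / 2.0 for n in panel.registry}
            if (a, year) in panel.target and (b, year) in panel.target:
                new_target[key] = (panel.target[(a, year)] + panel.target[(b, year)]) / 2.0
    return FeaturePanel(
        channels=new_channels, registry=dict(panel.registry), target=new_target, n_time=panel.n_time
    )


@dataclass
class FeatureCube:
    """3-D sample tensor (n_vars x n_time x n_samples) plus metadata.

    ``values`` holds raw (unstandardized) channel values; ``norm_mean`` /
    ``norm_sd`` are per-variable statistics computed over training samples,
    applied on demand by :meth:`standardized`.
    """

    values: np.ndarray
    var_names: list[str]
    day_index: list[int]
    sample_keys: list[SampleKey]
    targets: np.ndarray | None = None
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_vars, n_time, n_samples = self.values.shape
        if n_vars != len(self.var_names) or n_time != len(self.day_index):
            raise ValueError("cube metadata inconsistent with value dimensions")
        if n_samples != len(self.sample_keys):
            raise ValueError("sample key list inconsistent with value dimensions")
        if self.targets is not None and len(self.targets) != n_samples:
            raise ValueError("target length inconsistent")

    n_vars = property(lambda self: self.values.shape[0])
    n_time = property(lambda self: self.values.shape[1])
    n_samples = property(lambda self: self.values.shape[2])

    @property
    def years(self) -> np.ndarray:
        return np.array([k.year for k in self.sample_keys])

    @property
    def augmented(self) -> np.ndarray:
        return np.array([k.augmented for k in self.sample_keys])

    def standardized(self) -> np.ndarray:
        """(n_samples, n_time, n_vars) z-scored array ready for the model."""
        if self.norm_mean is None:
            raise ValueError("cube carries no standardization statistics")
        z = (self.values - self.norm_mean[:, None, None]) / self.norm_sd[:, None, None]
        return np.ascontiguousarray(np.transpose(z, (2, 1, 0)))

    def subset(self, mask: np.ndarray) -> "FeatureCube":
        idx = np.flatnonzero(mask)
        return FeatureCube(
            values=self.values[:, :, idx],
            var_names=list(self.var_names),
            day_index=list(self.day_index),
            sample_keys=[self.sample_keys[i] for i in idx],
            targets=None if self.targets is None else self.targets[idx],
            norm_mean=self.norm_mean,
            norm_sd=self.norm_sd,
        )

    def truncate(self, n_time: int) -> "FeatureCube":
        """Keep the first ``n_time`` days (cumulative channels keep their prefix sums)."""
        if not 1 <= n_time <= self.n_time:
            raise ValueError(f"cannot truncate length-{self.n_time} cube to {n_time}")
        return replace(
            self, values=self.values[:, :n_time, :], day_index=list(self.day_index[:n_time])
        )

    def save(self, path) -> None:
        """Directory format: one binary array file + a JSON metadata sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {"values": self.values}
        if self.targets is not None:
            arrays["targets"] = self.targets
        if self.norm_mean is not None:
            arrays["norm_mean"] = self.norm_mean
            arrays["norm_sd"] = self.norm_sd
        np.savez(path / "arrays.npz", **arrays)
        meta = {
            "var_names": self.var_names,
            "day_index": self.day_index,
            "sample_keys": [list(k) for k in self.sample_keys],
        }
        (path / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "FeatureCube":
        path = Path(path)
        with np.load(path / "arrays.npz") as npz:
            arrays = {k: npz[k] for k in npz.files}
        meta = json.loads((path / "meta.json").read_text())
        return cls(
            values=arrays["values"],
            var_names=meta["var_names"],
            day_index=meta["day_index"],
            sample_keys=[SampleKey(s, c, u, int(y), bool(a)) for s, c, u, y, a in meta["sample_keys"]],
            targets=arrays.get("targets"),
            norm_mean=arrays.get("norm_mean"),
            norm_sd=arrays.get("norm_sd"),
        )


def assemble_cube(
    panel: FeaturePanel,
    var_names,
    geography,
    train_years=None,
    standardize: bool = True,
) -> FeatureCube:
    """Stack a feature panel into the 3-D cube.

    Samples are ordered by (year, unit).  When ``standardize`` is set, the
    per-variable mean and standard deviation are computed over training-year
    samples only (all samples if ``train_years`` is None) and stored on the
    cube; values themselves stay raw so serialization round-trips exactly.
    """
    var_names = list(var_names)
    sub = panel.subset(var_names)
    keys = sorted(sub.channels, key=lambda k: (k[1], k[0]))
    n = len(keys)
    values = np.empty((len(var_names), sub.n_time, n))
    sample_keys = []
    targets = np.full(n, np.nan)
    for j, (unit, year) in enumerate(keys):
        chans = sub.channels[(unit, year)]
        for i, name in enumerate(var_names):
            if len(chans[name]) != sub.n_time:
                raise ValueError(f"ragged channel {name} for {(unit, year)}")
            values[i, :, j] = chans[name]
        county0 = unit.split("|")[0]
        crd = geography.crd_of(county0)
        sample_keys.append(
            SampleKey(geography.state_of_crd(crd), crd, unit, year, "|" in unit)
        )
        if (unit, year) in sub.target:
            targets[j] = sub.target[(unit, year)]

    cube = FeatureCube(
        values=values,
        var_names=var_names,
        day_index=list(range(sub.n_time)),
        sample_keys=sample_keys,
        targets=targets if np.isfinite(targets).any() else None,
    )
    if standardize:
        years = cube.years
        mask = np.ones(n, bool) if train_years is None else np.isin(years, list(train_years))
        if not mask.any():
            raise ValueError("no training samples to standardize on")
        sel = cube.values[:, :, mask]
        cube.norm_mean = sel.mean(axis=(1, 2))
        sd = sel.std(axis=(1, 2))
        cube.norm_sd = np.where(sd > 0, sd, 1.0)  # constant channels pass through centered
    return cube


def split_by_year(cube: FeatureCube, spec: SplitSpec) -> tuple[FeatureCube, FeatureCube]:
    """Partition samples by year; augmented samples may only land in train."""
    years = cube.years
    missing = (set(spec.train_years) | set(spec.test_years)) - set(years.tolist())
    if missing:
        raise ValueError(f"split years not present in cube: {sorted(missing)}")
    train = cube.subset(np.isin(years, spec.train_years))
    test = cube.subset(np.isin(years, spec.test_years))
    if test.augmented.any():
        raise ValueError("augmented samples found in test years")
    return train, test
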