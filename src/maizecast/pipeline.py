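"""End-to-end pipeline: simulate -> featurize -> rank -> cube -> train -> evaluate.

`run_pipeline` drives the full tool from a validated YAML config and writes
per-stage artifacts with a manifest of content hashes, so a rerun with the
same config reproduces the same hashes.  `run_state_experiment` is the
library-level core: one state, one cutoff, search + final fit + scored
predictions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calendar as cal
from .cube import SplitSpec, assemble_cube, augment_pairs, broadcast_pdsi, split_by_year
from .features import (
    CANONICAL_CHANNELS,
    DetrendScheme,
    attach_detrended_target,
    build_candidate_features,
    select_final_channels,
)
from .forecast import EvalReport, predict_records, score, truncate_cube
from .lstm import SearchSpace, TrainConfig
from .model import YieldLSTM, YieldLSTMResults
from .selection import mrmr_rank, summarize_panel
from .synth import (
    ResponseConfig,
    simulate_geography,
    simulate_pdsi,
    simulate_soil,
    simulate_weather,
    simulate_yield,
    write_panels,
)

log = logging.getLogger("maizecast")

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "run_state_experiment"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (detected before any compute)."""


@dataclass
class PipelineConfig:
    """Validated, YAML-serializable pipeline settings."""

    n_states: int = 1
    crds_per_state: int = 5
    counties_per_crd: int = 6
    years: list[int] = field(default_factory=lambda: list(range(1993, 2017)))
    train_years: list[int] | None = None    # default: all but the last 4
    test_years: list[int] | None = None
    detrend: str = "percentage"
    base_year: int = 2013
    variables: str = "canonical10"          # canonical10 | candidates28
    augment: bool = True
    budget: int = 8
    search_epochs: int = 5
    final_epochs: int = 20
    patience: int | None = 4
    cutoffs: list[str] = field(default_factory=lambda: ["nov"])
    seed: int = 1
    response: dict = field(default_factory=dict)  # ResponseConfig overrides
    outdir: str = "maizecast_run"

    def __post_init__(self) -> None:
        if self.train_years is None:
            self.train_years = self.years[:-4]
        if self.test_years is None:
            self.test_years = self.years[-4:]
        if set(self.train_years) & set(self.test_years):
            raise ConfigError("train and test years overlap")
        if not set(self.train_years) <= set(self.years) or not set(self.test_years) <= set(self.years):
            raise ConfigError("split years must be simulated years")
        if self.variables not in ("canonical10", "candidates28"):
            raise ConfigError(f"unknown variable set {self.variables!r}")
        for c in self.cutoffs:
            if c not in cal.CUTOFF_DAYS:
                raise ConfigError(f"unknown cutoff {c!r}")
        if self.budget < 1:
            raise ConfigError("search budget must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e


def _simulate_panels(cfg: PipelineConfig, seed: int):
    rng = np.random.default_rng(seed)
    s = lambda: int(rng.integers(2**31))
    geography = simulate_geography(cfg.n_states, cfg.crds_per_state, cfg.counties_per_crd, seed=s())
    weather = simulate_weather(geography, cfg.years, seed=s())
    soil = simulate_soil(geography, seed=s())
    pdsi = simulate_pdsi(geography, cfg.years, seed=s())
    response = ResponseConfig(base_year=cfg.base_year, seed=s(), **cfg.response)
    yields = simulate_yield(weather, soil, pdsi, response, geography)
    return geography, weather, soil, pdsi, yields, response


def build_panel(cfg: PipelineConfig, geography, weather, soil, pdsi, yields):
    """Candidate features + de-trended target for every county-year."""
    scheme = DetrendScheme(kind=cfg.detrend, base_year=cfg.base_year)
    pdsi_daily = broadcast_pdsi(pdsi, geography)
    panel = build_candidate_features(weather, soil, pdsi_daily, geography.corn_ratio)
    attach_detrended_target(panel, yields, scheme)
    return panel, scheme


def run_state_experiment(
    cfg: PipelineConfig,
    seed: int | None = None,
    cutoff: str = "nov",
    return_artifacts: bool = False,
):
    """Simulate one multi-CRD state and run the full forecasting experiment.

    Search `cfg.budget` hyperparameter draws on the training years (most
    recent 20 % held out for validation), refit the winner, predict the test
    years at the given cutoff, and score county-level accuracy.  Returns the
    EvalReport (plus intermediate artifacts on request).
    """
    from dataclasses import replace as _replace

    cfg = cfg if seed is None else _replace(cfg, seed=seed)
    geography, weather, soil, pdsi, yields, response = _simulate_panels(cfg, cfg.seed)
    panel, scheme = build_panel(cfg, geography, weather, soil, pdsi, yields)
    report, art = _run_cutoff(cfg, panel, scheme, geography, cutoff)
    if return_artifacts:
        art.update(
            geography=geography, weather=weather, soil=soil, pdsi=pdsi,
            yields=yields, panel=panel, scheme=scheme,
        )
        return report, art
    return report


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing artifacts and a manifest under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: %d state(s), years %s-%s, variables=%s, augment=%s",
             config.n_states, min(config.years), max(config.years),
             config.variables, config.augment)

    geography, weather, soil, pdsi, yields, response = _simulate_panels(config, config.seed)
    panel_paths = write_panels(outdir / "panels", geography, weather, soil, pdsi, yields)

    panel, scheme = build_panel(config, geography, weather, soil, pdsi, yields)
    summaries, target = summarize_panel(panel, stat="mean")
    ranks = mrmr_rank(summaries, target)
    ranks.to_frame().to_csv(outdir / "mrmr_ranks.csv", index=False)
    log.info("MRMR top channels: %s", ranks.selected[:5])

    reports = {}
    for cutoff in config.cutoffs:
        report, art = _run_cutoff(config, panel, scheme, geography, cutoff)
        for state, results in art["results"].items():
            results.save(outdir / f"model_{cutoff}" / state)
        art["predictions"].to_csv(outdir / f"predictions_{cutoff}.csv", index=False)
        art["leaderboard"].to_csv(outdir / f"leaderboard_{cutoff}.csv", index=False)
        reports[cutoff] = report.to_dict()
        log.info("cutoff %s: county MAE %.2f bu/ac, within ±20: %.1f%%",
                 cutoff, report.metrics["mae"], 100 * report.metrics["within_20"])
    (outdir / "evaluation.json").write_text(json.dumps(reports, indent=1))

    manifest = {
        "config": asdict(config),
        "hashes": {
            str(p.relative_to(outdir)): _hash_file(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def _restandardize(cube):
    """Recompute per-variable z-scoring statistics over this cube's samples."""
    sel = cube.values
    cube.norm_mean = sel.mean(axis=(1, 2))
    sd = sel.std(axis=(1, 2))
    cube.norm_sd = np.where(sd > 0, sd, 1.0)
    return cube


def _run_cutoff(config, panel, scheme, geography, cutoff):
    """Search+train+predict for one cutoff; one model per state."""
    work = panel
    if config.augment:
        work = augment_pairs(work, geography, years=config.train_years)
    var_names = CANONICAL_CHANNELS if config.variables == "canonical10" else tuple(work.registry)
    work = work.subset(var_names)
    cube = assemble_cube(work, var_names, geography, train_years=config.train_years)
    train_cube, test_cube = split_by_year(
        cube, SplitSpec(tuple(config.train_years), tuple(config.test_years))
    )
    if cutoff != "nov":
        train_cube = truncate_cube(train_cube, cutoff)
        test_cube = truncate_cube(test_cube, cutoff)

    state_results: dict[str, YieldLSTMResults] = {}
    best_configs: dict[str, TrainConfig] = {}
    pred_frames, boards = [], []
    train_states = np.array([k.state for k in train_cube.sample_keys])
    test_states = np.array([k.state for k in test_cube.sample_keys])
    for state in geography.states:
        st_train = _restandardize(train_cube.subset(train_states == state))
        st_test = test_cube.subset(test_states == state)
        # search on the original samples (cheap), refit the winner on the
        # augmented set: augmentation triples the sample count but barely
        # moves the config ranking at short search budgets
        search_model = YieldLSTM.from_cube(
            st_train.subset(~st_train.augmented), dtype=np.float32
        )
        best_cfg, leaderboard = search_model.search(
            SearchSpace(), budget=config.budget, seed=config.seed,
            epochs=config.search_epochs, patience=3,
        )
        final_cfg = TrainConfig(
            **{**asdict(best_cfg), "epochs": config.final_epochs, "patience": config.patience}
        )
        model = YieldLSTM.from_cube(st_train, dtype=np.float32)
        results = model.fit(seed=config.seed, config=final_cfg)
        state_results[state] = results
        best_configs[state] = best_cfg
        leaderboard = leaderboard.assign(state=state)
        boards.append(leaderboard)
        pred_frames.append(predict_records(results, st_test, scheme, cutoff=cutoff))
        log.info("state %s: best config hidden=%d %s lr=%g", state, best_cfg.hidden,
                 best_cfg.optimizer, best_cfg.learning_rate)

    preds = pd.concat(pred_frames, ignore_index=True)
    report = score(preds, geography)
    return report, {
        "results": state_results,
        "predictions": preds,
        "leaderboard": pd.concat(boards, ignore_index=True),
        "best_config": best_configs,
    }
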