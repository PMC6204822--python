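"""End-to-end pipeline: generate -> featurise -> train -> predict ->
segment -> cost -> simulate.

Stages communicate through plain CSV files in a run directory, so any
stage can be re-run or resumed from its predecessors' outputs.  A
manifest records the configuration hash and per-stage row counts.
Internally all timestamps are seconds from deployment start; calendar
day boundaries (for midnight-to-midnight DEE) are applied only in the
energetics stage via the configured deployment start datetime.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import energetics as en
from . import features as ft
from . import segmentation as seg
from . import sensitivity as sens
from . import synthetic as syn
from .types import BEHAVIOURS, AnimalMeta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; thresholds default to the published
    operating points (1 m surface depth, 5 m dive, 10 m trip dive,
    15 s event persistence)."""

    seed: int = 0
    mass_kg: float = 50.0
    season: str = "winter"
    # captive training session
    captive_duration_s: int = 4 * 3600
    behaviour_mix: tuple = (0.25, 0.25, 0.25, 0.25)
    # wild deployment
    wild_days: int = 2
    deployment_start: str = "2014-07-01T00:00:00"
    # feature extraction
    rate_hz: int = 1
    epoch_samples: int = 21
    dba_window_s: float = 3.0
    # training
    class_balance_n: int = 250
    cv_folds: int = 3
    parameter_grid: dict = field(default_factory=lambda: dict(clf.SMALL_GRID))
    include_covariates: bool = True
    # segmentation thresholds
    surface_depth_m: float = 1.0
    dive_min_depth_m: float = 5.0
    trip_min_dive_depth_m: float = 10.0
    event_persistence_s: float = 15.0
    # sensitivity
    sensitivity_days: int = 1000
    water_temp_c: float = 14.0
    low_confidence_threshold: float = 0.80

    def __post_init__(self) -> None:
        if self.mass_kg is None or self.mass_kg <= 0:
            raise ValueError("config field 'mass_kg' must be a positive number")
        if self.season not in ("winter", "summer"):
            raise ValueError("config field 'season' must be winter or summer")

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["behaviour_mix"] = list(self.behaviour_mix)
        d["parameter_grid"] = {k: list(v) for k, v in self.parameter_grid.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "behaviour_mix" in d:
            d["behaviour_mix"] = tuple(d["behaviour_mix"])
        if "parameter_grid" in d:
            d["parameter_grid"] = {k: tuple(v) for k, v in d["parameter_grid"].items()}
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


@_stage("simulate-captive")
def stage_simulate_captive(cfg: PipelineConfig, outdir: str) -> tuple:
    trace, labels = syn.generate_captive_session(
        seed=cfg.seed, duration_s=cfg.captive_duration_s,
        behaviour_mix=cfg.behaviour_mix, rate_hz=cfg.rate_hz,
        animal=AnimalMeta(mass_kg=cfg.mass_kg, season=cfg.season),
    )
    syn.write_session(os.path.join(outdir, "captive"), trace, labels)
    return trace, labels


@_stage("featurise")
def stage_featurise_captive(cfg: PipelineConfig, outdir: str, trace, labels):
    ecfg = ft.EpochConfig(cfg.rate_hz, cfg.epoch_samples, cfg.dba_window_s)
    feats = ft.epoch_features(trace, labels, ecfg)
    ft.write_features(feats, os.path.join(outdir, "features_captive.csv"), ecfg)
    return feats


@_stage("train")
def stage_train(cfg: PipelineConfig, outdir: str, feats: pd.DataFrame):
    tcfg = clf.TrainConfig(
        epoch_samples=cfg.epoch_samples, class_balance_n=cfg.class_balance_n,
        parameter_grid=cfg.parameter_grid, cv_folds=cfg.cv_folds,
        include_covariates=cfg.include_covariates, seed=cfg.seed,
    )
    model, report = clf.train_gbm(feats, tcfg)
    model.save(os.path.join(outdir, "model"))
    with open(os.path.join(outdir, "model_report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return model, report


@_stage("simulate-wild")
def stage_simulate_wild(cfg: PipelineConfig, outdir: str):
    trace = syn.generate_wild_deployment(
        seed=cfg.seed + 1, n_days=cfg.wild_days, mass_kg=cfg.mass_kg,
        season=cfg.season,
    )
    syn.write_session(os.path.join(outdir, "wild"), trace)
    return trace

@_stage("predict")
def stage_predict(cfg: PipelineConfig, outdir: str, model, wild_trace):
    depth = ft.zero_offset_correct(wild_trace.depth, wild_trace.wet)
    location = seg.assign_location(wild_trace.wet, depth, cfg.surface_depth_m)
    ecfg = ft.EpochConfig(cfg.rate_hz, cfg.epoch_samples, cfg.dba_window_s)
    feats = ft.epoch_features(wild_trace, None, ecfg, location=location)
    ft.write_features(feats, os.path.join(outdir, "features_wild.csv"), ecfg)
    preds = clf.predict_epochs(model, feats)
    preds.to_csv(os.path.join(outdir, "predictions.csv"), index=False)
    audit = clf.low_confidence_audit(preds, cfg.low_confidence_threshold)
    audit.to_csv(os.path.join(outdir, "low_confidence_audit.csv"), index=False)
    return feats, preds, depth, location


@_stage("segment")
def stage_segment(cfg: PipelineConfig, outdir: str, preds, feats, wild_trace, depth):
    epoch_s = cfg.epoch_samples / cfg.rate_hz
    beh_s, loc_s = seg.expand_epochs_to_seconds(
        preds["predicted"].to_numpy(), feats["location"].to_numpy(), epoch_s
    )
    events = seg.build_events(
        beh_s, loc_s, min_change_s=cfg.event_persistence_s,
        season=cfg.season, temperature=wild_trace.temperature,
        wet=wild_trace.wet[: len(beh_s)],
    )
    pd.DataFrame(
        [
            {
                "behaviour": e.behaviour, "location": e.location,
                "start_s": e.start_s, "end_s": e.end_s,
                "duration_min": e.duration_min, "season": e.season,
                "water_temp_c": e.water_temp_c,
            }
            for e in events
        ]
    ).to_csv(os.path.join(outdir, "events.csv"), index=False)
    dives = seg.detect_dives(depth, cfg.dive_min_depth_m)
    trips = seg.detect_trips(wild_trace.wet, dives, cfg.trip_min_dive_depth_m)
    pd.DataFrame([dataclasses.asdict(d) for d in dives]).to_csv(
        os.path.join(outdir, "dives.csv"), index=False
    )
    pd.DataFrame([dataclasses.asdict(t) for t in trips]).to_csv(
        os.path.join(outdir, "trips.csv"), index=False
    )
    return events, dives, trips


@_stage("energetics")
def stage_energetics(cfg: PipelineConfig, outdir: str, events):
    start = datetime.fromisoformat(cfg.deployment_start)
    budgets = en.daily_budgets(events, cfg.mass_kg, start=start)
    frame = en.budgets_to_frame(budgets)
    frame.to_csv(os.path.join(outdir, "daily_budgets.csv"), index=False)
    return budgets, frame


@_stage("sensitivity")
def stage_sensitivity(cfg: PipelineConfig, outdir: str):
    props = sens.simulate_proportions(cfg.sensitivity_days, seed=cfg.seed + 2)
    table = sens.dee_response(
        props, mass_kg=cfg.mass_kg, season=cfg.season,
        water_temp_c=cfg.water_temp_c,
    )
    table.to_csv(os.path.join(outdir, "sensitivity.csv"), index=False)
    return table


def run_pipeline(cfg: PipelineConfig, outdir: str) -> dict:
    """Run every stage into ``outdir``; returns the manifest dict."""
    os.makedirs(outdir, exist_ok=True)
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))

    trace, labels = stage_simulate_captive(cfg, outdir)
    feats = stage_featurise_captive(cfg, outdir, trace, labels)
    model, report = stage_train(cfg, outdir, feats)
    wild = stage_simulate_wild(cfg, outdir)
    wfeats, preds, depth, location = stage_predict(cfg, outdir, model, wild)
    events, dives, trips = stage_segment(cfg, outdir, preds, wfeats, wild, depth)
    budgets, budget_frame = stage_energetics(cfg, outdir, events)
    sens_table = stage_sensitivity(cfg, outdir)

    manifest = {
        "config_hash": cfg.config_hash(),
        "rows": {
            "features_captive": len(feats),
            "features_wild": len(wfeats),
            "predictions": len(preds),
            "events": len(events),
            "dives": len(dives),
            "trips": len(trips),
            "daily_budgets": len(budget_frame),
            "sensitivity": len(sens_table),
        },
        "model": {
            "out_of_sample_accuracy": report.out_of_sample_accuracy,
            "kappa": report.kappa,
        },
        "dee_mj_complete_days": [
            b.dee_mj for b in budgets if b.complete
        ],
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
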