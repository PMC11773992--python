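"""End-to-end pipeline: simulate -> features -> panel -> fit -> validate.

`run_all` chains every stage, writes versioned outputs plus a manifest
(config hash, seed, per-file checksums), and is deterministic: re-running
with the same configuration reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import descriptives, glmm, io, panel as panel_mod, validation
from .features import FeatureConfig, compute_daily_features
from .simulate import SimConfig, simulate_cohort, write_cohort

log = logging.getLogger("mobrisk")


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "mobrisk_out"
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    features: FeatureConfig = dataclasses.field(default_factory=FeatureConfig)
    lag: int = 1
    outcome: str = "events"
    n_quad_nodes: int = 25
    n_boot: int = 2000
    between_reps: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "features" in d and isinstance(d["features"], dict):
            d["features"] = FeatureConfig(**d["features"])
        return cls(**d)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(cfg: PipelineConfig) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    d = cfg.to_dict()
    d.pop("out_dir", None)
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the manifest.

    Stages: simulate -> read back -> daily features -> weekly panel (events
    and ideation) -> random-intercept fit -> leave-future-out and
    between-person validation -> bookkeeping counts.  Any stage failure
    propagates with the stage name prepended.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    chash = config_hash(cfg)
    manifest: dict = {"config_hash": chash, "seed": cfg.seed, "stages": {}, "files": {}}
    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        cohort = simulate_cohort(sim_cfg)
        data_dir = os.path.join(cfg.out_dir, "data")
        write_cohort(data_dir, cohort, overwrite=True)
        log.info("simulate: %d fixes, %d ESM rows, %d raw events",
                 len(cohort.gps), len(cohort.esm), len(cohort.events))

        stage = "read"
        tables = io.read_inputs(
            os.path.join(data_dir, "gps.csv"),
            os.path.join(data_dir, "esm.csv"),
            os.path.join(data_dir, "events.csv"),
            os.path.join(data_dir, "baseline.csv"),
        )

        stage = "features"
        daily, homes = compute_daily_features(tables["gps"], cfg.features)
        daily_path = os.path.join(cfg.out_dir, "daily_features.csv")
        daily.to_csv(daily_path, index=False)
        log.info("features: %d participant-days, %d homes", len(daily), len(homes))

        stage = "panel"
        enrollment = tables["baseline"].set_index("participant_id")["enrollment_date"]
        weekly = panel_mod.aggregate_weekly(daily, enrollment, n_weeks=sim_cfg.n_weeks)
        weekly = panel_mod.decompose(weekly)
        outcomes = panel_mod.weekly_outcomes(tables["esm"], tables["events"], enrollment)
        merged = panel_mod.merge_events(tables["events"])
        event_panel = panel_mod.build_panel(weekly, outcomes, lag=cfg.lag, outcome_kind="events")
        ideation_panel = panel_mod.build_panel(weekly, outcomes, lag=cfg.lag, outcome_kind="ideation")
        panel_path = os.path.join(cfg.out_dir, "weekly_panel.csv")
        panel_mod.panel_to_frame(event_panel).to_csv(panel_path, index=False)
        low_gps = int((weekly["n_gps_days"] < panel_mod.MIN_GPS_DAYS).sum())
        log.info(
            "panel: %d event weeks, %d ideation weeks; %d weeks dropped by the "
            "<%d-day rule; %d raw events merged to %d",
            len(event_panel), len(ideation_panel), low_gps, panel_mod.MIN_GPS_DAYS,
            len(tables["events"]), len(merged),
        )

        stage = "fit"
        main_panel = event_panel if cfg.outcome == "events" else ideation_panel
        spec = glmm.GlmmSpec(outcome="outcome", n_quad_nodes=cfg.n_quad_nodes)
        fit_ = glmm.fit(spec, main_panel)
        report = glmm.report_or(fit_)
        fit_json = {
            "terms": fit_.terms,
            "beta": fit_.beta.tolist(),
            "se": fit_.se.tolist(),
            "vcov": fit_.vcov.tolist(),
            "sigma_u": fit_.sigma_u,
            "loglik": fit_.loglik,
            "converged": fit_.converged,
            "penalized": fit_.penalized,
            "n_groups": fit_.n_groups,
            "n_obs": fit_.n_obs,
            "aor_table": report.to_dict(orient="records"),
        }
        _write_json(os.path.join(cfg.out_dir, "fit.json"), fit_json)

        stage = "validate"
        lfo = validation.leave_future_out(
            event_panel, tables["baseline"], outcome="events",
            n_boot=cfg.n_boot, seed=cfg.seed, n_quad_nodes=cfg.n_quad_nodes,
        )
        agg = validation.first_month_aggregate(daily, enrollment)
        y_later = validation.outcome_after_first_month(
            outcomes, kind="events", all_pids=tables["baseline"]["participant_id"]
        )
        try:
            between = validation.between_person(
                agg, tables["baseline"], y_later, outcome="events",
                reps=cfg.between_reps, seed=cfg.seed,
            )
        except ValueError as exc:
            log.warning("between-person validation skipped: %s", exc)
            between = []
        _write_json(
            os.path.join(cfg.out_dir, "validation.json"),
            [r.to_dict() for r in lfo + between],
        )

        stage = "descriptives"
        counts = descriptives.panel_counts(
            daily, event_panel, ideation_panel, merged,
            n_participants=sim_cfg.n_participants, n_weeks=sim_cfg.n_weeks,
        )
        counts["esm_response_fraction"] = float(
            (tables["esm"]["responded"] == 1).mean()
        ) if len(tables["esm"]) else float("nan")
        _write_json(os.path.join(cfg.out_dir, "descriptives.json"), counts)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for root, _, files in os.walk(cfg.out_dir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            p = os.path.join(root, f)
            manifest["files"][os.path.relpath(p, cfg.out_dir)] = _sha256(p)
    manifest["stages"] = {
        "simulate": True, "features": True, "panel": True,
        "fit": True, "validate": True, "descriptives": True,
    }
    _write_json(os.path.join(cfg.out_dir, "manifest.json"), manifest)
    return manifest
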