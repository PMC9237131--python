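"""Umbrella pipeline: simulate -> extract -> train -> predict -> evaluate.

Each stage writes its artifacts under the output directory and is skipped on
re-run when they already exist (delete a stage's outputs to force
re-execution). All randomness flows from the single config seed; two runs
with the same config and seed produce identical artifacts. A manifest
records the config hash, input hashes and per-stage row counts.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .config import PipelineConfig
from .datatypes import SubjectData
from .evaluate import extract_events
from .experiments import (SubjectTask, evaluate_personalized, personalize,
                          train_population)
from .model import GlucoseModel, ModelConfig
from .signals import align_to_grid
from .simulate import generate_cohort
from .train import MamlConfig, SplitSpec, chronological_split
from .features import TargetScaler, prepare_subject_windows


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _subject_dirs(cohort_dir: Path) -> list[Path]:
    return sorted(p for p in Path(cohort_dir).iterdir() if p.is_dir())


def stage_simulate(cfg: PipelineConfig, cohort_dir: Path, manifest) -> None:
    cohort_dir = Path(cohort_dir)
    if _subject_dirs(cohort_dir) if cohort_dir.exists() else []:
        manifest.log_stage("simulate", skipped=True)
        return
    sim = cfg.simulate
    cohort = generate_cohort(sim.n_subjects, sim.days, seed=cfg.seed,
                             wristband_excerpt_hours=sim.wristband_excerpt_hours,
                             apply_gaps=sim.apply_gaps,
                             cgm_gap_fraction=sim.cgm_gap_fraction,
                             wristband_gap_fraction=sim.wristband_gap_fraction)
    for sub in cohort:
        d = cohort_dir / sub.params.subject_id
        gio.write_cgm(d / "cgm.csv", sub.cgm)
        gio.write_events(d / "events.csv", sub.events)
        if sub.wristband is not None:
            gio.write_wristband(d, sub.wristband)
        gio.write_ground_truth(d / "ground_truth.json", sub.ground_truth)
        if sub.grid_physio is not None:
            gio.write_features(d / "features_raw.csv", sub.grid_physio)
    manifest.log_stage("simulate", subjects=len(cohort),
                       rows_out=sum(len(s.cgm) for s in cohort))


def stage_extract(cfg: PipelineConfig, cohort_dir: Path, manifest) -> None:
    """Ensure every subject has grid-level wristband features: reuse the
    simulator's features_raw.csv when present, otherwise run the full
    waveform -> beats/EDA -> grid chain."""
    rows = 0
    for d in _subject_dirs(Path(cohort_dir)):
        out = d / "features_raw.csv"
        if out.exists():
            rows += len(gio.read_features(out))
            continue
        cgm = gio.read_cgm(d / "cgm.csv")
        wb = gio.read_wristband(d)
        grid_feats = align_to_grid(wb, cgm.times,
                                   hrv_min_intervals=cfg.signals.hrv_min_intervals)
        gio.write_features(out, grid_feats)
        rows += len(grid_feats)
    manifest.log_stage("extract", rows_out=rows)


def _load_task(d: Path, cfg: PipelineConfig, horizon: int) -> SubjectTask:
    cgm = gio.read_cgm(d / "cgm.csv")
    events = gio.read_events(d / "events.csv")
    wf = gio.read_features(d / "features_raw.csv") if (d / "features_raw.csv").exists() else None
    fc = cfg.features
    selected = tuple(fc.selected)
    windows, _ = prepare_subject_windows(cgm, events, wf, columns=selected,
                                         l=fc.window_length, horizons=(horizon,),
                                         tail_mode=fc.tail_mode)
    ws = windows[horizon]
    train, val, test = chronological_split(ws, SplitSpec())
    tscaler = TargetScaler.fit(train.y_delta)
    sub = SubjectData(params=None, cgm=cgm, events=events, wristband=None,
                      ground_truth=None, grid_physio=wf)
    return SubjectTask(sub, ws, train, val, test, tscaler)


def _model_cfg(cfg: PipelineConfig, n_features: int) -> ModelConfig:
    m = cfg.model
    return ModelConfig(input_dim=n_features, hidden=m.hidden, hidden2=m.hidden2,
                       v_dim=m.v_dim, reg_coef=m.reg_coef)


def _maml_cfg(cfg: PipelineConfig) -> MamlConfig:
    t = cfg.train
    return MamlConfig(inner_lr=t.inner_lr, outer_lr=t.outer_lr,
                      inner_steps=t.inner_steps, meta_batch=t.meta_batch,
                      finetune_lr=t.finetune_lr, max_epochs=t.max_epochs,
                      patience=t.patience, batch_size=t.batch_size,
                      outer_steps=t.outer_steps)


def stage_train(cfg: PipelineConfig, cohort_dir: Path, out_dir: Path,
                manifest, leave_out: str | None = None) -> None:
    """Leave-one-subject-out: meta-train on all other subjects, fine-tune on
    the held-out subject's training split, calibrate thresholds."""
    out_dir = Path(out_dir)
    dirs = _subject_dirs(Path(cohort_dir))
    names = [d.name for d in dirs]
    target = leave_out or names[0]
    if target not in names:
        raise ValueError(f"unknown subject '{target}'")
    for horizon in cfg.features.horizons_steps:
        ckpt = out_dir / f"personalized_{target}_h{horizon}.npz"
        if ckpt.exists():
            manifest.log_stage("train", horizon=horizon, skipped=True)
            continue
        tasks = [_load_task(d, cfg, horizon) for d in dirs]
        ti = names.index(target)
        mcfg = _model_cfg(cfg, len(tasks[ti].windows.columns))
        maml = _maml_cfg(cfg)
        meta_w = train_population(tasks, ti, mcfg, maml, seed=cfg.seed)
        model = personalize(meta_w, tasks[ti], mcfg, maml, seed=cfg.seed)
        model.target_scaler = tasks[ti].target_scaler
        model.save(ckpt)
        manifest.log_stage("train", horizon=horizon, subject=target,
                           n_train=len(tasks[ti].train), n_val=len(tasks[ti].val))


def stage_predict(cfg: PipelineConfig, cohort_dir: Path, out_dir: Path,
                  manifest, leave_out: str | None = None) -> None:
    out_dir = Path(out_dir)
    dirs = _subject_dirs(Path(cohort_dir))
    target = leave_out or dirs[0].name
    d = next(p for p in dirs if p.name == target)
    frames = []
    reports = {}
    events_rows = []
    for horizon in cfg.features.horizons_steps:
        task = _load_task(d, cfg, horizon)
        model = GlucoseModel.load(out_dir / f"personalized_{target}_h{horizon}.npz")
        model.target_scaler = task.target_scaler
        report, cal, bp = evaluate_personalized(model, task, horizon,
                                                u_inverse=cfg.model.u_inverse)
        out = model.predict(task.test.X)
        frames.append(pd.DataFrame({
            "timestamp": task.test.times, "horizon_min": horizon * 5,
            "g_hat": bp.g_hat, "b_low": bp.b_low, "b_up": bp.b_up,
            "uncertainty": out.u,
        }))
        reports[str(horizon * 5)] = {
            "thresholds": {"k_l": cal.k_l, "k_u": cal.k_u,
                           "warnings": cal.warnings},
            **report.to_dict(),
        }
        cgm = task.subject.cgm
        for kind, bound, thr in (("hypo", bp.b_low, "low"), ("hyper", bp.b_up, "up")):
            pred_grid = np.zeros(len(cgm), bool)
            tgt = task.test.t_idx + horizon
            pred = bound < 70.0 if kind == "hypo" else bound > 180.0
            pred_grid[tgt] = pred
            for ev in extract_events(cgm, kind):
                span = np.arange(ev.start_idx, ev.end_idx + 1)
                events_rows.append({
                    "subject": target, "start": ev.start, "end": ev.end,
                    "type": kind, "horizon_min": horizon * 5,
                    "detected": bool(pred_grid[span].any()),
                })
    gio.write_predictions(out_dir / f"predictions_{target}.csv",
                          pd.concat(frames, ignore_index=True))
    (out_dir / f"report_{target}.json").write_text(json.dumps(reports, indent=2))
    pd.DataFrame(events_rows).to_csv(out_dir / f"events_{target}.csv", index=False)
    manifest.log_stage("predict", subject=target,
                       rows_out=sum(len(f) for f in frames))


def run_pipeline(cfg: PipelineConfig, cohort_dir, out_dir,
                 leave_out: str | None = None) -> gio.RunManifest:
    """Execute all stages; halts with the failing stage name on error."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = gio.RunManifest(cfg.to_yaml(), cfg.seed)
    stages = [
        ("simulate", lambda: stage_simulate(cfg, cohort_dir, manifest)),
        ("extract", lambda: stage_extract(cfg, cohort_dir, manifest)),
        ("train", lambda: stage_train(cfg, cohort_dir, out_dir, manifest, leave_out)),
        ("predict", lambda: stage_predict(cfg, cohort_dir, out_dir, manifest, leave_out)),
    ]
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            manifest.log_stage(name, failed=True, error=str(exc))
            manifest.write(out_dir / "manifest.json")
            raise StageError(name, exc) from exc
    manifest.write(out_dir / "manifest.json")
    return manifest


__all__ = ["run_pipeline", "stage_simulate", "stage_extract", "stage_train",
           "stage_predict", "StageError"]
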