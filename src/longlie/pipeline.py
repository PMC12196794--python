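"""End-to-end orchestration: simulate -> qc -> clean -> dataset -> train
-> evaluate -> monitor demo, with one root seed and a written manifest.

Stage seeds are derived deterministically from the root seed so any
stage can be rerun in isolation and reproduce its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .features import BodySegments, features_table
from .model import EvalReport, evaluate, split_dataset, train_ensemble
from .monitor import MonitorConfig, run_monitor
from .pose_io import PoseSequence, detection_report
from .preprocess import CleaningConfig, clean
from .synthetic import GeneratorConfig, generate_longlie_scenario, generate_study
from .windows import WindowConfig, build_dataset, write_dataset_csv

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Merged configuration for a full pipeline run."""

    seed: int = 42
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    monitor: MonitorConfig = field(default_factory=MonitorConfig)
    cv_folds: int = 5
    test_size: float = 0.2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for fld, factory in (("generator", GeneratorConfig),
                             ("cleaning", CleaningConfig),
                             ("windows", WindowConfig),
                             ("monitor", MonitorConfig)):
            if fld in raw:
                section = dict(raw.pop(fld))
                if "required_keypoints" in section:
                    section["required_keypoints"] = tuple(section["required_keypoints"])
                kwargs[fld] = factory(**section)
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(root: int, stage: str) -> int:
    """A stable per-stage child seed below 2**31 (crc32 keeps it
    independent of interpreter hash randomization)."""
    ss = np.random.SeedSequence([root, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def acb_series(seq: PoseSequence, segments: BodySegments | None = None,
               cleaning: CleaningConfig | None = None,
               smooth: int = 5) -> np.ndarray:
    """Per-frame ACB angle of a cleaned sequence, prepared for the monitor.

    Frames with undefined features are causally forward-filled, then a
    trailing moving average of ``smooth`` frames (default 5 = 0.5 s)
    suppresses single-frame estimator noise: the immobility rule
    compares a scalar angle across minutes, so frame-level jitter must
    not trigger state resets. Both steps are causal.
    """
    cleaned = clean(seq, cleaning or CleaningConfig())
    acb = features_table(cleaned, segments)["acb"].to_numpy()
    out = acb.copy()
    last = np.nan
    for i, v in enumerate(out):
        if np.isfinite(v):
            last = v
        else:
            out[i] = last
    if smooth > 1:
        smoothed = out.copy()
        for i in range(len(out)):
            win = out[max(0, i - smooth + 1):i + 1]
            win = win[np.isfinite(win)]
            if win.size:
                smoothed[i] = win.mean()
        out = smoothed
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages in order and write artifacts under ``outdir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen_cfg = dataclasses.replace(config.generator,
                                  seed=stage_seed(config.seed, "simulate"))

    log.info("stage 1/5: simulate")
    sequences = generate_study(gen_cfg)

    log.info("stage 2/5: qc")
    qc = detection_report(sequences,
                          confidence_threshold=config.cleaning.confidence_threshold)
    qc.to_frame().to_csv(outdir / "qc_report.csv", index=False)

    log.info("stage 3/5: build dataset")
    dataset = build_dataset(sequences, config.cleaning, config.windows)
    write_dataset_csv(dataset, outdir / "dataset.csv")

    log.info("stage 4/5: train + evaluate")
    train, test = split_dataset(dataset, config.test_size, config.seed)
    model, selection = train_ensemble(train, k=config.cv_folds, seed=config.seed)
    model.save(outdir / "model.joblib")
    selection.metrics.to_csv(outdir / "selection_report.csv")
    report: EvalReport = evaluate(model, test)
    (outdir / "eval_report.json").write_text(report.to_json())

    log.info("stage 5/5: monitor demo")
    demo_cfg = dataclasses.replace(
        config.monitor, longlie_time_threshold=min(
            config.monitor.longlie_time_threshold, 60.0))
    seq, truth = generate_longlie_scenario(
        pre_fall=10.0, lie_duration=demo_cfg.longlie_time_threshold + 30.0,
        cfg=gen_cfg, seed=stage_seed(config.seed, "monitor"))
    acb = acb_series(seq, cleaning=config.cleaning)
    events = run_monitor(zip(truth["classifications"], acb), demo_cfg)
    with open(outdir / "monitor_events.jsonl", "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(json.dumps(dataclasses.asdict(ev)) + "\n")

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_sequences": len(sequences),
        "n_fall_sequences": sum(s.label == "fall" for s in sequences),
        "n_adl_sequences": sum(s.label == "adl" for s in sequences),
        "qc_mean_rate": round(qc.mean_rate, 2),
        "qc_sd_rate": round(qc.sd_rate, 2),
        "n_windows": int(len(dataset)),
        "selected_members": selection.selected,
        "eval": {k: (v if isinstance(v, dict) else round(v, 4))
                 for k, v in report.__dict__.items()},
        "monitor_demo_events": [ev.kind for ev in events],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
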