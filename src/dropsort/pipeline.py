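"""End-to-end workflows binding the modules together.

The canonical run is ``simulate -> segment -> decide -> sort -> report``:
render (or load) droplet frames, run the segmentation chain and particle
analysis on each, apply gates or a trained classifier, push the
decisions through the virtual sorter, and score the event log against
the ground-truth manifest.

Per-frame segmentation failures are logged and counted; they do not
abort the run.  Re-running with the same config and seed reproduces the
outputs byte-for-byte (timestamps in the manifest aside).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures, segment, sortsim
from .decide import Decision, GateRule, SingleCellClassifier, apply_gates
from .features import DropletRecord, measure_droplet, records_to_frames
from .fixtures import (FrameGeometry, NoiseSpec, StreamSpec, simulate_stream,
                       scene_for_droplet)
from .micrograph import Micrograph, read_frame
from .segment import SegmentationConfig, SegmentationError
from .sortsim import ActuationConfig
from .stats import metrics


@dataclass
class RunConfig:
    """Reproducible description of one sorting run."""

    seed: int = 0
    n_droplets: int = 500
    lam: float = 1.0
    mean_volume_pl: float = 155.0
    volume_cv: float = 0.05
    droplet_rate_hz: float = 3.5
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    geometry: FrameGeometry = field(default_factory=FrameGeometry)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    gates: list[GateRule] = field(default_factory=lambda: [
        GateRule("cell_count", "eq", 1)])
    actuation: ActuationConfig = field(default_factory=ActuationConfig)
    classifier_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("seed", "n_droplets", "lam", "mean_volume_pl",
                    "volume_cv", "droplet_rate_hz", "classifier_path"):
            if key in raw:
                kwargs[key] = raw[key]
        if "noise" in raw:
            kwargs["noise"] = NoiseSpec(**raw["noise"])
        if "geometry" in raw:
            geo = raw["geometry"]
            for k in ("frame_shape", "cell_axis_ratio_range"):
                if k in geo:
                    geo[k] = tuple(geo[k])
            kwargs["geometry"] = FrameGeometry(**geo)
        if "segmentation" in raw:
            kwargs["segmentation"] = SegmentationConfig(**raw["segmentation"])
        if "gates" in raw:
            kwargs["gates"] = [GateRule.from_dict(g) for g in raw["gates"]]
        if "actuation" in raw:
            kwargs["actuation"] = ActuationConfig(**raw["actuation"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, default_flow_style=None))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


@dataclass
class RunResult:
    records: list[DropletRecord]
    events: list
    counts: "object"            # ConfusionCounts
    metrics: "object"           # SortingMetrics
    truths: list
    failures: list[tuple[int, str]]


def analyze_frame(image: Micrograph, background: Micrograph,
                  cfg: SegmentationConfig, droplet_id: int = 0,
                  timestamp_s: float = 0.0,
                  channel_height_um: float = 30.0) -> DropletRecord:
    """Segmentation chain + particle analysis for one frame."""
    diff = segment.subtract_background(image, background)
    dmask = segment.droplet_mask(diff, cfg)
    cmask = segment.cell_mask(diff, dmask, cfg)
    return measure_droplet(dmask, cmask, image, droplet_id=droplet_id,
                           timestamp_s=timestamp_s,
                           channel_height_um=channel_height_um)


def decide_record(record: DropletRecord, gates: list[GateRule],
                  classifier: SingleCellClassifier | None = None) -> Decision:
    dec = apply_gates(record, gates)
    if dec.decision == "keep" and classifier is not None and record.cells:
        dec = classifier.classify(record)
    return dec


def run_simulated(cfg: RunConfig) -> RunResult:
    """Simulate, segment, decide and sort a droplet stream in memory."""
    stream = StreamSpec(
        n_droplets=cfg.n_droplets,
        cell_concentration=cfg.lam / (cfg.mean_volume_pl * 1e-9),
        mean_volume_pl=cfg.mean_volume_pl, volume_cv=cfg.volume_cv,
        droplet_rate_hz=cfg.droplet_rate_hz, seed=cfg.seed)
    truths = simulate_stream(stream)
    classifier = (SingleCellClassifier.load(cfg.classifier_path)
                  if cfg.classifier_path else None)

    records: list[DropletRecord] = []
    decisions: list[str] = []
    timestamps: list[float] = []
    kept_truths = []
    failures: list[tuple[int, str]] = []
    for t in truths:
        scene = scene_for_droplet(t, cfg.geometry, stream_seed=cfg.seed,
                                  noise=cfg.noise)
        img, bg = fixtures.render_frame(scene, seed=cfg.seed + 1 + t.droplet_id,
                                        static_seed=cfg.seed)
        try:
            rec = analyze_frame(img, bg, cfg.segmentation,
                                droplet_id=t.droplet_id,
                                timestamp_s=t.timestamp_s,
                                channel_height_um=cfg.geometry.channel_height_um)
        except SegmentationError as exc:
            failures.append((t.droplet_id, str(exc)))
            continue
        dec = decide_record(rec, cfg.gates, classifier)
        rec.decision = dec.decision
        rec.decision_rationale = dec.rationale
        records.append(rec)
        decisions.append(dec.decision)
        timestamps.append(t.timestamp_s)
        kept_truths.append(t)

    events = sortsim.run_sorter(timestamps, decisions, cfg.actuation,
                                seed=cfg.seed,
                                droplet_ids=[t.droplet_id for t in kept_truths])
    target_flags = [t.cell_count == 1 for t in kept_truths]
    counts = sortsim.confusion_from_log(events, target_flags)
    return RunResult(records, events, counts, metrics(counts), truths, failures)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> RunResult:
    """Run a simulated sort and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_simulated(cfg)

    drops, cells = records_to_frames(result.records)
    drops.to_csv(out / "droplets.csv", index=False)
    if not cells.empty:
        cells.to_csv(out / "cells.csv", index=False)
    with open(out / "droplets.jsonl", "w") as fh:
        for rec in result.records:
            row = asdict(rec)
            row["schema_version"] = 1
            fh.write(json.dumps(row) + "\n")
    sortsim.log_to_frame(result.events).to_csv(out / "events.csv", index=False)
    fixtures.write_manifest(result.truths, out / "manifest.csv")
    report = {
        "metrics": result.metrics.as_dict(),
        "counts": asdict(result.counts),
        "n_failures": len(result.failures),
    }
    (out / "metrics.json").write_text(json.dumps(report, indent=2))
    (out / "run_manifest.json").write_text(json.dumps({
        "schema_version": 1,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_droplets": cfg.n_droplets,
    }, indent=2))
    if result.failures:
        pd.DataFrame(result.failures,
                     columns=["droplet_id", "error"]).to_csv(
            out / "failures.csv", index=False)
    return result


def report_from_files(events_csv: str | Path, manifest_csv: str | Path) -> dict:
    """Recompute the metrics report from an event log + truth manifest."""
    ev = pd.read_csv(events_csv)
    truth = pd.read_csv(manifest_csv).set_index("droplet_id")
    events = []
    target_flags = []
    for row in ev.itertuples():
        events.append(sortsim.SortEvent(
            droplet_id=int(row.droplet_id), decision=row.decision,
            actuated=bool(row.actuated), actuation_success=bool(row.actuated),
            co_sorted=False, outlet=row.outlet,
            t_detect_s=float(row.t_detect_s),
            t_actuate_s=None if pd.isna(row.t_actuate_s) else float(row.t_actuate_s),
            t_arrive_s=None if pd.isna(row.t_arrive_s) else float(row.t_arrive_s),
            verified=bool(row.verified)))
        target_flags.append(
            int(truth.loc[int(row.droplet_id), "true_cell_count"]) == 1)
    counts = sortsim.confusion_from_log(events, target_flags)
    m = metrics(counts)
    return {"metrics": m.as_dict(), "counts": asdict(counts)}


def segment_files(image_path: str | Path, background_path: str | Path,
                  out_dir: str | Path,
                  cfg: SegmentationConfig | None = None,
                  pixel_size_um: float = 0.25) -> DropletRecord:
    """Segment one frame pair from disk and export the masks."""
    from .micrograph import write_mask

    cfg = cfg or SegmentationConfig()
    image = read_frame(image_path, pixel_size_um=pixel_size_um)
    background = read_frame(background_path, pixel_size_um=pixel_size_um)
    diff = segment.subtract_background(image, background)
    dmask = segment.droplet_mask(diff, cfg)
    cmask = segment.cell_mask(diff, dmask, cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(out / "droplet_mask.png", dmask)
    write_mask(out / "cell_mask.png", cmask)
    return measure_droplet(dmask, cmask, image)
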