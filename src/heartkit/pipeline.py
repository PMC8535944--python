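"""End-to-end pipeline: denoise -> resample -> normalize -> segment ->
features -> select -> train/evaluate.

Every stage error aborts the run with the stage name and the item id
attached; stage-level counters (segments produced, kept, ignored) go to a
JSON-lines run log.  One global seed fans out to fixed per-stage offsets so
a single knob reproduces the whole run.
"""

from __future__ import annotations

import json
import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import segmentation as seg
from .classify import (
    Example,
    EvaluationReport,
    aggregate_folds,
    compute_metrics,
    evaluate,
    kfold_split,
    train_backend,
)
from .config import RunConfig
from .denoise import iir_denoise
from .errors import HeartkitError
from .selection import select_segments
from .signal_io import PCGRecording, normalize_amplitude, read_manifest, read_wav, resample

SEED_SELECTION = 1000
SEED_FOLDS = 2000
SEED_TRAIN = 3000


class StageFailure(HeartkitError):
    def __init__(self, stage: str, item: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for item {item!r}: {cause}")
        self.stage, self.item, self.cause = stage, item, cause


class _RunLog:
    """JSON-lines logger (stderr plus an optional file)."""

    def __init__(self, path: Path | None):
        self.path = path
        self.records: list[dict] = []
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text("")

    def emit(self, **record) -> None:
        self.records.append(record)
        line = json.dumps(record, sort_keys=True)
        print(line, file=sys.stderr)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(line + "\n")


def load_recordings(manifest_path: str | Path) -> list[PCGRecording]:
    """Read every WAV listed in a path-style manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    recs = []
    for e in manifest.entries:
        for p in e.paths:
            recs.append(read_wav(base / p, id=Path(p).stem, label=e.label))
    return recs


def process_recording(
    rec: PCGRecording, cfg: RunConfig
) -> tuple[list[seg.HeartCycleSegment], seg.CycleEstimate]:
    """Denoise, resample, normalize and cut one recording into cycles."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except HeartkitError as exc:
            raise StageFailure(name, rec.id, exc) from exc

    filtered = stage("denoise", iir_denoise, rec, cfg.filter)
    down = stage("resample", resample, filtered, cfg.target_rate)
    norm = stage("normalize", normalize_amplitude, down)
    low = stage("wavelet", seg.wavelet_low_freq_extract, norm, cfg.wavelet)
    env = stage(
        "envelope", seg.shannon_envelope, low, cfg.segmentation.frame_len, cfg.segmentation.hop
    )
    env = stage("standardize", seg.standardize_envelope, env)
    cyc = stage(
        "uacf",
        seg.estimate_cycle_uacf,
        env,
        cfg.segmentation.min_period,
        cfg.segmentation.max_period,
    )
    segments = stage("segment", seg.segment_recording, norm, env, cyc)
    return segments, cyc


def run_pipeline(
    cfg: RunConfig,
    manifest: str | Path | None = None,
    recordings: list[PCGRecording] | None = None,
) -> EvaluationReport:
    """Run the full pipeline and return the cross-validated evaluation report.

    Input is either a manifest CSV (WAV paths resolved relative to it) or an
    in-memory list of recordings.  Intermediates and the report are persisted
    under ``cfg.out_dir`` when set.
    """
    if recordings is None:
        if manifest is None:
            raise ValueError("need a manifest path or a list of recordings")
        recordings = load_recordings(manifest)
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl" if out is not None else None)
    log.emit(stage="start", recordings=len(recordings), seed=cfg.seed)

    all_segments: list[seg.HeartCycleSegment] = []
    seg_meta = []
    for rec in recordings:
        segments, cyc = process_recording(rec, cfg)
        log.emit(
            stage="segment",
            item=rec.id,
            segments=len(segments),
            period_s=round(cyc.period_seconds, 4),
            confidence=round(cyc.confidence, 4),
        )
        all_segments.extend(segments)
        seg_meta.extend(
            {
                "recording_id": s.recording_id,
                "segment_id": s.segment_id,
                "start": s.start,
                "end": s.end,
                "label": s.label,
            }
            for s in segments
        )

    vectors: dict[str, np.ndarray] = {}
    seg_by_id: dict[str, seg.HeartCycleSegment] = {}
    for s in all_segments:
        try:
            m = feat.mfcc(s, cfg.mfcc, sample_rate=cfg.target_rate)
            vectors[s.segment_id] = feat.summarize_segment_features(m)
        except Exception as exc:
            raise StageFailure("features", s.segment_id, exc) from exc
        seg_by_id[s.segment_id] = s
        if cfg.render_images and out is not None:
            img = feat.render_png(m)
            img_dir = out / "images"
            img_dir.mkdir(exist_ok=True)
            feat.save_png(img, img_dir / f"{s.segment_id.replace(':', '_')}.png")
    log.emit(stage="features", segments=len(vectors))

    kept_ids: list[str] = []
    ignored_ids: list[str] = []
    selection_doc = {}
    if cfg.selection.enabled:
        labels = sorted({s.label for s in all_segments})
        pools = (
            {lbl: [s for s in all_segments if s.label == lbl] for lbl in labels}
            if cfg.selection.per_class
            else {"all": all_segments}
        )
        for lbl, pool in pools.items():
            ids = [s.segment_id for s in pool]
            if len(ids) < 2:
                kept_ids.extend(ids)
                continue
            res = select_segments(
                (ids, np.asarray([vectors[i] for i in ids])),
                seed=cfg.seed + SEED_SELECTION,
                tol=cfg.selection.tol,
                max_iter=cfg.selection.max_iter,
            )
            kept_ids.extend(res.kept)
            ignored_ids.extend(res.ignored)
            selection_doc[lbl] = {
                "kept": len(res.kept),
                "ignored": len(res.ignored),
                "total": len(ids),
            }
            log.emit(stage="select", pool=lbl, kept=len(res.kept), ignored=len(res.ignored))
    else:
        kept_ids = [s.segment_id for s in all_segments]
    log.emit(
        stage="selection_total",
        produced=len(all_segments),
        kept=len(kept_ids),
        ignored=len(ignored_ids),
    )

    items = [
        Example(
            x=vectors[sid],
            label=seg_by_id[sid].label,
            group=seg_by_id[sid].recording_id,
            id=sid,
        )
        for sid in kept_ids
    ]
    splits = kfold_split(items, cfg.train.folds, cfg.seed + SEED_FOLDS)
    train_cfg = replace(cfg.train, seed=cfg.seed + SEED_TRAIN)
    matrices = []
    for k, (train_idx, val_idx) in enumerate(splits):
        model = train_backend([items[i] for i in train_idx], train_cfg)
        cm = evaluate(model, [items[i] for i in val_idx])
        matrices.append(cm)
        log.emit(stage="fold", fold=k + 1, accuracy=round(cm.trace_accuracy, 4))
    report = aggregate_folds(matrices, [compute_metrics(cm) for cm in matrices])

    if out is not None:
        (out / "config.json").write_text(cfg.to_json())
        pd.DataFrame(seg_meta).to_csv(out / "segments.csv", index=False)
        rows = [{"segment_id": k, **{f"f{i}": v for i, v in enumerate(vec)}}
                for k, vec in vectors.items()]
        pd.DataFrame(rows).to_csv(out / "features.csv", index=False)
        (out / "selection.json").write_text(
            json.dumps(
                {"kept": kept_ids, "ignored": ignored_ids, "pools": selection_doc},
                sort_keys=True,
                indent=1,
            )
        )
        (out / "report.json").write_text(report.to_json())
        report.to_table().to_csv(out / "report.csv")
    log.emit(stage="done", classes_avg=report.classes_avg)
    return report
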