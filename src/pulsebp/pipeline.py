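"""End-to-end orchestration: signals -> features -> model -> report.

``run_pipeline`` executes the five stages in order — signal extraction
(simulation or CSV), preprocessing, feature/label derivation, model
training, evaluation — writing every intermediate artifact with a JSON
manifest of seeds and per-stage record counts so any run can be
regenerated bit-identically.

``stream_predict`` replays a record cycle-by-cycle, emitting one
(SBP, DBP) estimate per valid cycle and a gap marker for each skipped
cycle, buffering one look-back window so its outputs equal batch
prediction exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from pulsebp import __version__
from pulsebp.dataset import FeatureDataset, assemble, normalize, split
from pulsebp.evaluation import aami_check, bhs_grade, summarize_errors
from pulsebp.features import apply_bp_filters, extract_cycle_features
from pulsebp.fiducials import detect_fiducials
from pulsebp.models import ModelConfig, TrainConfig, TrainedModel, build_model, predict, train
from pulsebp.preprocess import FilterSpec, minmax_normalize, remove_low_freq
from pulsebp.records import SignalRecord
from pulsebp.synthetic import SimConfig, simulate_record

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stream_predict",
           "preprocess_record", "record_features"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from JSON."""

    signal_csvs: list[str] = field(default_factory=list)
    simulate: list[SimConfig] | None = None
    sampling_rate_hz: float = 125.0
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    max_window_samples: int = 200
    split_fraction: float = 0.8
    split_seed: int = 0
    stats_scope: str = "train"
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    model_seed: int = 0
    output_dir: str = "pulsebp_out"

    def validate(self) -> None:
        if not self.signal_csvs and not self.simulate:
            raise ValueError("config must provide signal_csvs or simulate entries")
        if self.model is None:
            raise ValueError("config missing model section")
        for path in self.signal_csvs:
            if not Path(path).exists():
                raise ValueError(f"signal CSV not found: {path}")


@dataclass
class PipelineResult:
    report: dict
    feature_table: pd.DataFrame
    dataset: FeatureDataset
    model: TrainedModel


def preprocess_record(record: SignalRecord, spec: FilterSpec) -> SignalRecord:
    """Baseline-filter ECG and PPG (ABP keeps its mmHg baseline)."""
    fs = record.sampling_rate_hz
    return SignalRecord(
        ecg=remove_low_freq(record.ecg, fs, spec),
        ppg=remove_low_freq(record.ppg, fs, spec),
        abp=record.abp,
        sampling_rate_hz=fs,
        record_id=record.record_id,
    )


def record_features(
    record: SignalRecord,
    spec: FilterSpec | None = None,
    max_window_samples: int | None = 200,
) -> tuple[pd.DataFrame, dict]:
    """Preprocess + detect + extract for one record."""
    spec = spec or FilterSpec()
    clean = preprocess_record(record, spec)
    fiducials = detect_fiducials(clean.ecg, clean.ppg, clean.sampling_rate_hz)
    ppg_norm = minmax_normalize(clean.ppg)
    table, counts = extract_cycle_features(
        clean, fiducials, max_window_samples, ppg_normalized=ppg_norm
    )
    return table, counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; write artifacts and a manifest to output_dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}, "seeds": {
        "split": config.split_seed,
        "model": config.model_seed,
        "training": config.training.seed,
    }}

    # stage 1-2: signals (simulated and/or loaded), preprocessing
    records: list[SignalRecord] = []
    if config.simulate:
        for i, sim_cfg in enumerate(config.simulate):
            rec = simulate_record(sim_cfg, record_id=f"sim{i:03d}")
            rec.signals.to_csv(out / f"{rec.signals.record_id}_signals.csv")
            records.append(rec.signals)
    for path in config.signal_csvs:
        records.append(SignalRecord.from_csv(path, config.sampling_rate_hz))
    manifest["stages"]["extract"] = {"n_records": len(records)}

    # stage 3: features and labels
    tables = []
    total_counts: dict[str, int] = {}
    for record in records:
        try:
            table, counts = record_features(
                record, config.filter_spec, config.max_window_samples
            )
        except Exception as exc:  # per-stage failure with record id
            raise RuntimeError(
                f"feature stage failed for record {record.record_id!r}: {exc}"
            ) from exc
        tables.append(table)
        for key, value in counts.items():
            total_counts[key] = total_counts.get(key, 0) + value
    feature_table = pd.concat(tables, ignore_index=True)
    feature_table, bp_counts = apply_bp_filters(feature_table)
    total_counts["bp_filtered"] = int(sum(bp_counts.values()))
    feature_table.to_csv(out / "features.csv", index=False)
    manifest["stages"]["features"] = {**total_counts, **bp_counts,
                                      "n_cycles": int(len(feature_table))}

    # stage 4: dataset + training
    dataset = assemble(feature_table)
    dataset = split(dataset, config.split_fraction, config.split_seed)
    dataset = normalize(dataset, config.stats_scope)
    dataset.to_csv(out / "dataset.csv")
    network = build_model(config.model, seed=config.model_seed)
    trained = train(network, dataset, config.training, config.model)
    manifest["stages"]["train"] = {
        "model_id": config.model.model_id,
        "epochs": len(trained.training_history),
        "final_loss": trained.training_history[-1],
    }

    # stage 5: evaluation on the held-out columns
    pred = predict(trained, dataset.features)
    truth = dataset.denormalize_targets(dataset.targets)
    test_cols = dataset.test_columns
    report = {"n_test_cycles": int(len(test_cols))}
    for row, name in enumerate(("sbp", "dbp")):
        summary = summarize_errors(pred[row, test_cols], truth[row, test_cols])
        bhs = bhs_grade(np.abs(pred[row, test_cols] - truth[row, test_cols]))
        n_subjects = int(pd.unique(dataset.record_ids).size)
        aami = aami_check(summary, n_subjects)
        report[name] = {
            "me": summary.me_mmhg,
            "mae": summary.mae_mmhg,
            "std": summary.std_mmhg,
            "rmse": summary.rmse_mmhg,
            "bhs_grade": bhs.grade,
            "bhs_pct": list(bhs.percentages),
            "aami_pass": aami.passed,
        }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(
        report=report, feature_table=feature_table, dataset=dataset, model=trained
    )


GAP = None  # marker emitted for skipped cycles


def stream_predict(
    model: TrainedModel,
    feature_stream: "Iterator[np.ndarray | None]",
) -> Iterator[tuple[float, float] | None]:
    """Consume per-cycle feature vectors; emit one (SBP, DBP) per cycle.

    ``feature_stream`` yields a length-7 normalized feature vector per
    valid cycle, or ``None`` for a skipped cycle (signal dropout); the
    corresponding output is a gap marker and the recurrent state (the
    window buffer) is preserved across gaps.  Estimates are flushed one
    look-back window (``sequence_length`` cycles) at a time and equal
    batch prediction on the same sequence.
    """
    window = model.config.sequence_length
    buffer: list[np.ndarray] = []
    order: list[object] = []  # interleaving of cycle slots and gap markers
    out_queue: list[tuple[float, float] | None] = []

    def flush() -> None:
        mmhg = predict(model, np.stack(buffer, axis=1)) if buffer else None
        j = 0
        for pos in order:
            if pos is GAP:
                out_queue.append(GAP)
            else:
                out_queue.append((float(mmhg[0, j]), float(mmhg[1, j])))
                j += 1
        buffer.clear()
        order.clear()
    for item in feature_stream:
        if item is GAP:
            order.append(GAP)
            continue
        vec = np.asarray(item, dtype=float).reshape(-1)
        if vec.size != model.config.n_features:
            raise ValueError("feature vector has wrong dimension")
        buffer.append(vec)
        order.append("cycle")
        if len(buffer) == window:
            flush()
            yield from out_queue
            out_queue.clear()
    flush()
    yield from out_queue
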