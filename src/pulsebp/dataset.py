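"""Feature-matrix assembly, train/test split, and normalization.

The regressors consume a 7xT matrix (rows PTT, HR, RI, ST, UT, SV, DV;
columns = time-ordered cycles) with a 2xT target matrix (SBP, DBP in
mmHg).  Feature rows are z-scored and targets min-max scaled to [0, 1].
Normalization statistics are computed on the *training* columns only by
default (``stats_scope='train'``) so no test-set information leaks into
the scaling; ``stats_scope='all'`` reproduces whole-dataset statistics.
The standard-deviation convention is population (divide by n) throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pulsebp.features import FEATURE_COLUMNS

__all__ = ["FeatureDataset", "assemble", "split", "normalize"]

TARGET_ROWS = ["sbp", "dbp"]


@dataclass
class FeatureDataset:
    """7xT features and 2xT targets with split mask and scaling statistics."""

    features: np.ndarray  # (7, T), raw or normalized depending on `normalized`
    targets: np.ndarray  # (2, T) mmHg, or [0,1] when normalized
    record_ids: np.ndarray
    cycle_indices: np.ndarray
    split_mask: np.ndarray | None = None  # True = train
    seed: int | None = None
    feature_mean: np.ndarray | None = None  # (7,)
    feature_std: np.ndarray | None = None  # (7,)
    target_min: np.ndarray | None = None  # (2,)
    target_max: np.ndarray | None = None  # (2,)
    normalized: bool = False
    stats_scope: str = "train"
    row_names: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))

    @property
    def n_cycles(self) -> int:
        return self.features.shape[1]

    @property
    def train_columns(self) -> np.ndarray:
        if self.split_mask is None:
            raise ValueError("dataset has no split assigned")
        return np.nonzero(self.split_mask)[0]

    @property
    def test_columns(self) -> np.ndarray:
        if self.split_mask is None:
            raise ValueError("dataset has no split assigned")
        return np.nonzero(~self.split_mask)[0]

    # ---- target scaling -------------------------------------------------
    def normalize_targets(self, targets_mmhg: np.ndarray) -> np.ndarray:
        span = self.target_max - self.target_min
        scaled = (targets_mmhg - self.target_min[:, None]) / span[:, None]
        if np.any(scaled < 0) or np.any(scaled > 1):
            warnings.warn("targets outside the training min-max; clipping to [0, 1]")
            scaled = np.clip(scaled, 0.0, 1.0)
        return scaled

    def denormalize_targets(self, scaled: np.ndarray) -> np.ndarray:
        span = self.target_max - self.target_min
        return scaled * span[:, None] + self.target_min[:, None]

    def normalize_features(self, features_raw: np.ndarray) -> np.ndarray:
        return (features_raw - self.feature_mean[:, None]) / self.feature_std[:, None]

    def denormalize_features(self, scaled: np.ndarray) -> np.ndarray:
        return scaled * self.feature_std[:, None] + self.feature_mean[:, None]

    # ---- persistence ----------------------------------------------------
    def to_csv(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the columns as rows of a CSV plus a JSON stats sidecar."""
        csv_path = Path(csv_path)
        df = pd.DataFrame(self.features.T, columns=self.row_names)
        df.insert(0, "record_id", self.record_ids)
        df.insert(1, "cycle_index", self.cycle_indices)
        df["sbp"] = self.targets[0]
        df["dbp"] = self.targets[1]
        if self.split_mask is not None:
            df["split"] = np.where(self.split_mask, "train", "test")
        df.to_csv(csv_path, index=False)
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
        meta = {
            "row_names": self.row_names,
            "seed": self.seed,
            "normalized": self.normalized,
            "stats_scope": self.stats_scope,
            "feature_mean": _tolist(self.feature_mean),
            "feature_std": _tolist(self.feature_std),
            "target_min": _tolist(self.target_min),
            "target_max": _tolist(self.target_max),
        }
        sidecar.write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(
        cls, csv_path: str | Path, sidecar_path: str | Path | None = None
    ) -> "FeatureDataset":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        row_names = meta["row_names"]
        ds = cls(
            features=df[row_names].to_numpy().T,
            targets=df[TARGET_ROWS].to_numpy().T,
            record_ids=df["record_id"].to_numpy(),
            cycle_indices=df["cycle_index"].to_numpy(),
            split_mask=(df["split"] == "train").to_numpy() if "split" in df else None,
            seed=meta["seed"],
            feature_mean=_toarray(meta["feature_mean"]),
            feature_std=_toarray(meta["feature_std"]),
            target_min=_toarray(meta["target_min"]),
            target_max=_toarray(meta["target_max"]),
            normalized=meta["normalized"],
            stats_scope=meta["stats_scope"],
            row_names=row_names,
        )
        if ds.features.shape[0] != len(row_names):
            raise ValueError("feature matrix does not match declared row names")
        if ds.normalized and (ds.targets.min() < -1e-9 or ds.targets.max() > 1 + 1e-9):
            raise ValueError("normalized targets must lie in [0, 1]")
        return ds


def _tolist(arr):
    return None if arr is None else np.asarray(arr).tolist()


def _toarray(lst):
    return None if lst is None else np.asarray(lst, dtype=float)


def assemble(feature_table: pd.DataFrame) -> FeatureDataset:
    """Build the 7xT dataset from a per-cycle feature table.

    Columns are ordered by (record_id, cycle_index); the feature-row
    order is fixed to PTT, HR, RI, ST, UT, SV, DV.
    """
    if len(feature_table) == 0:
        raise ValueError("empty feature table")
    missing = [c for c in (*FEATURE_COLUMNS, *TARGET_ROWS) if c not in feature_table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    df = feature_table.sort_values(["record_id", "cycle_index"], kind="stable")
    return FeatureDataset(
        features=df[list(FEATURE_COLUMNS)].to_numpy(dtype=float).T,
        targets=df[TARGET_ROWS].to_numpy(dtype=float).T,
        record_ids=df["record_id"].to_numpy(),
        cycle_indices=df["cycle_index"].to_numpy(),
    )


def split(dataset: FeatureDataset, fraction: float = 0.8, seed: int = 0) -> FeatureDataset:
    """Random disjoint train/test assignment of cycles (columns).

    ``round(fraction * T)`` columns become training; deterministic for a
    fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    t = dataset.n_cycles
    if t < 2:
        raise ValueError("need at least 2 cycles to split")
    n_train = int(round(fraction * t))
    rng = np.random.default_rng(seed)
    order = rng.permutation(t)
    mask = np.zeros(t, dtype=bool)
    mask[order[:n_train]] = True
    dataset.split_mask = mask
    dataset.seed = seed
    return dataset


def normalize(dataset: FeatureDataset, stats_scope: str = "train") -> FeatureDataset:
    """Z-score feature rows; min-max scale target rows to [0, 1].

    Statistics come from the training columns (``stats_scope='train'``,
    default, leakage-free) or from all columns (``'all'``) and are stored
    on the dataset for inversion at prediction time.
    """
    if dataset.split_mask is None:
        raise ValueError("assign a split before normalizing")
    if dataset.normalized:
        raise ValueError("dataset is already normalized")
    if stats_scope not in ("train", "all"):
        raise ValueError("stats_scope must be 'train' or 'all'")
    cols = dataset.train_columns if stats_scope == "train" else np.arange(dataset.n_cycles)

    feats = dataset.features
    mean = feats[:, cols].mean(axis=1)
    std = feats[:, cols].std(axis=1)  # population convention
    zero_var = np.nonzero(std == 0)[0]
    if zero_var.size:
        names = [dataset.row_names[i] for i in zero_var]
        raise ValueError(f"zero-variance feature rows cannot be z-scored: {names}")

    tmin = dataset.targets[:, cols].min(axis=1)
    tmax = dataset.targets[:, cols].max(axis=1)
    if np.any(tmax <= tmin):
        raise ValueError("degenerate target range")

    dataset.feature_mean, dataset.feature_std = mean, std
    dataset.target_min, dataset.target_max = tmin, tmax
    dataset.features = dataset.normalize_features(feats)
    dataset.targets = dataset.normalize_targets(dataset.targets)
    dataset.normalized = True
    dataset.stats_scope = stats_scope
    return dataset
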