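"""End-to-end orchestration: simulate -> preprocess -> features -> train -> evaluate.

A single :class:`RunConfig` (serializable to/from YAML) drives the whole
pipeline; one master seed determines every source of randomness through
stage-name hashing, so identical configs reproduce identical artifacts. The
leaf-one-out cross-validation trains a fresh model per fold on the
RWC-balanced pool of the 30 (n-1) training leaves and predicts every
interpolated sample of the held-out leaf.
"""

from __future__ import annotations


import logging
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import balance_training_set, leafoo_splits, write_split_manifest
from .errors import ConfigurationError
from .evaluate import EvalReport, build_report, plot_report, write_report
from .features import features_table
from .models import CnnConfig, RfConfig, build_cnn, train_rf
from .preprocess import INTERPOLATION_METHODS, augment_dataset
from .simulate import LeafRecord, NoiseConfig, simulate_dataset, write_dataset_csv

__all__ = ["RunConfig", "child_seed", "assemble_samples", "run_leafoo_cv", "run_pipeline"]

log = logging.getLogger("ncrus")


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed from the master seed by stage-name hashing."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    seed: int = 0
    n_leaves: int = 31
    methods: tuple[str, ...] = INTERPOLATION_METHODS
    n_bins: int = 10
    models: tuple[str, ...] = ("rf", "cnn")
    cnn_epochs: int = 350
    rf_trees: int = 400
    max_folds: int | None = None
    noise_magnitude_db_std: float = 0.5
    noise_phase_rad_std: float = 0.05
    out_dir: str = "runs/default"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.methods = tuple(cfg.methods)
        cfg.models = tuple(cfg.models)
        return cfg


def assemble_samples(
    records: list[LeafRecord], methods: tuple[str, ...] = INTERPOLATION_METHODS
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack the augmented dataset into model-ready arrays.

    Returns ``(x, meta)``: ``x`` is (n_samples, 601, 2) with magnitude and
    phase channels; ``meta`` has one row per sample with leaf_id,
    measurement_idx, method, rwc, the four feature columns and defined_flag.
    """
    samples = [s for s in augment_dataset(records) if s.method in methods]
    if not samples:
        raise ConfigurationError("no samples assembled; check the method list")
    x = np.stack(
        [np.column_stack([s.magnitude_db, s.phase_rad]) for s in samples]
    )
    meta = features_table(samples)
    rwc_map = {
        (rec.leaf_id, idx): m.rwc
        for rec in records
        for idx, m in enumerate(rec.measurements)
    }
    meta["rwc"] = [
        rwc_map[(s.source[0], s.source[1])] for s in samples
    ]
    return x, meta


FEATURE_COLUMNS = [
    "peak_magnitude_db", "peak_frequency_hz", "peak_phase_rad", "norm_bandwidth",
]


def run_leafoo_cv(
    x: np.ndarray,
    meta: pd.DataFrame,
    models: tuple[str, ...] = ("rf", "cnn"),
    seed: int = 0,
    n_bins: int = 10,
    cnn_cfg: CnnConfig | None = None,
    rf_cfg: RfConfig | None = None,
    max_folds: int | None = None,
    manifest_path: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Leaf-one-out cross-validation of the requested model families.

    Balancing is re-drawn independently in every round. Returns, per model
    tag, a per-sample prediction frame (leaf_id, measurement_idx, method,
    true_rwc, predicted_rwc). ``max_folds`` restricts evaluation to the first
    k held-out leaves (training still uses all remaining leaves per round).
    """
    leaf_ids = list(dict.fromkeys(meta["leaf_id"]))
    plan = leafoo_splits(leaf_ids)
    folds = plan.folds if max_folds is None else plan.folds[:max_folds]
    predictions: dict[str, list[pd.DataFrame]] = {m: [] for m in models}
    balanced_sets = []
    for test_leaf, train_leaves in folds:
        train_mask = meta["leaf_id"].isin(train_leaves).to_numpy()
        test_mask = (meta["leaf_id"] == test_leaf).to_numpy()
        train_idx = np.flatnonzero(train_mask)
        pool = [(int(i), float(meta["rwc"].iloc[i])) for i in train_idx]
        bal = balance_training_set(pool, n_bins=n_bins,
                                   seed=child_seed(seed, f"balance/{test_leaf}"))
        balanced_sets.append(bal)
        kept = np.array(bal.kept_sample_ids, dtype=int)
        log.info("fold %s: %d training samples kept of %d", test_leaf, kept.size,
                 train_idx.size)
        test_meta = meta.loc[test_mask, ["leaf_id", "measurement_idx", "method", "rwc"]]

        if "rf" in models:
            cfg = rf_cfg or RfConfig()
            cfg = RfConfig(**{**asdict(cfg), "seed": child_seed(seed, f"rf/{test_leaf}")})
            defined_kept = kept[meta["defined_flag"].to_numpy()[kept]]
            n_dropped = kept.size - defined_kept.size
            if n_dropped:
                log.info("fold %s: %d undefined-bandwidth rows excluded from RF",
                         test_leaf, n_dropped)
            forest = train_rf(
                meta.loc[defined_kept, FEATURE_COLUMNS].to_numpy(),
                meta["rwc"].to_numpy()[defined_kept],
                cfg,
            )
            test_defined = test_mask & meta["defined_flag"].to_numpy()
            pred = forest.predict(meta.loc[test_defined, FEATURE_COLUMNS].to_numpy())
            frame = meta.loc[test_defined, ["leaf_id", "measurement_idx", "method", "rwc"]]
            frame = frame.rename(columns={"rwc": "true_rwc"}).copy()
            frame["predicted_rwc"] = pred
            predictions["rf"].append(frame)

        if "cnn" in models:
            base = cnn_cfg or CnnConfig()
            cfg = CnnConfig(**{**asdict(base), "seed": child_seed(seed, f"cnn/{test_leaf}")})
            model = build_cnn(cfg)
            model.fit(x[kept], meta["rwc"].to_numpy()[kept])
            pred = model.predict(x[test_mask])
            frame = test_meta.rename(columns={"rwc": "true_rwc"}).copy()
            frame["predicted_rwc"] = pred
            predictions["cnn"].append(frame)

    if manifest_path is not None:
        write_split_manifest(SplitSubset(folds), balanced_sets, manifest_path)
    return {
        tag: pd.concat(frames, ignore_index=True) for tag, frames in predictions.items()
    }


@dataclass(frozen=True)
class SplitSubset:
    folds: tuple


def run_pipeline(cfg: RunConfig) -> dict[str, EvalReport]:
    """Run the full pipeline and write all artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    for m in cfg.models:
        if m not in ("rf", "cnn"):
            raise ConfigurationError(f"unknown model tag {m!r}")

    noise = NoiseConfig(magnitude_db_std=cfg.noise_magnitude_db_std,
                        phase_rad_std=cfg.noise_phase_rad_std)
    log.info("simulating %d-leaf dataset", cfg.n_leaves)
    records = simulate_dataset(
        n_leaves=cfg.n_leaves, seed=child_seed(cfg.seed, "simulate"), noise_cfg=noise
    )
    write_dataset_csv(records, out / "dataset", config=asdict(cfg))

    x, meta = assemble_samples(records, tuple(cfg.methods))
    meta.to_csv(out / "features.csv", index=False)
    log.info("assembled %d samples of shape %s", x.shape[0], x.shape[1:])

    preds = run_leafoo_cv(
        x, meta,
        models=tuple(cfg.models),
        seed=cfg.seed,
        n_bins=cfg.n_bins,
        cnn_cfg=CnnConfig(epochs=cfg.cnn_epochs),
        rf_cfg=RfConfig(n_trees=cfg.rf_trees),
        max_folds=cfg.max_folds,
        manifest_path=out / "splits.json",
    )
    reports = {}
    for tag, frame in preds.items():
        report = build_report(frame, tag)
        write_report(report, out / "report")
        plot_report(report, out / "report")
        log.info(
            "%s: R=%.4f RMSE=%.4f (per-measurement R=%.4f RMSE=%.4f)",
            tag, report.global_pearson_r, report.global_rmse,
            report.per_measurement_pearson_r, report.per_measurement_rmse,
        )
        reports[tag] = report
    return reports
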