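"""End-to-end experiment orchestration.

One experiment = one data subset (a synthetic cohort, or EDF files
plus hypnograms) pushed through the full chain: filter-bank design ->
5-level decomposition -> norm features -> optional class balancing ->
bagged-tree classification under repeated stratified 10-fold CV ->
CSV report tables (epoch accounting, ANOVA screening, per-trial
accuracies, pooled confusion matrix, per-class metrics).  Everything
is reproducible from the single master seed in the config.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import anova, balancing, evaluation, features, filterbank, io_epochs, synthetic
from .stages import STAGES

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Flat, YAML-compatible experiment description."""

    # data source: synthetic counts per group, or EDF directory
    synthetic_counts: dict[str, dict[str, int]] | None = None
    edf_dir: str | None = None
    hypnogram_suffix: str = ".txt"
    channels: tuple[str, ...] = synthetic.DEFAULT_CHANNELS
    fs: float = 512.0
    epoch_s: float = 30.0
    # filter design
    L: int = 15
    M: int = 25
    omega_p_pi: float = 0.4  # passband edge as a fraction of pi
    alpha: float = 0.95
    gamma: float = 0.05
    R: int = 2
    V: int = 2
    levels: int = 5
    # balancing: none | whole | strict
    balance: str = "none"
    target_per_class: int | None = None
    # classifier
    n_learners: int = 50
    max_splits: int | None = None
    learning_rate: float | None = None  # accepted, inert (bagging)
    # evaluation
    k: int = 10
    trials: int = 5
    seed: int = 0
    out_dir: str = "somnowave-report"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("channels must be non-empty")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.balance not in ("none", "whole", "strict"):
            raise ValueError("balance must be one of none|whole|strict")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "channels" in raw:
            raw["channels"] = tuple(raw["channels"])
        return cls(**raw)


def _load_epochs(cfg: ExperimentConfig) -> io_epochs.EpochSet:
    if cfg.synthetic_counts is not None:
        spec = synthetic.CohortSpec(
            groups=tuple((g, dict(c)) for g, c in cfg.synthetic_counts.items()),
            fs=cfg.fs, epoch_s=cfg.epoch_s, seed=cfg.seed,
            channels=tuple(cfg.channels),
        )
        return synthetic.generate_cohort(spec)
    if cfg.edf_dir is None:
        raise ValueError("config needs either synthetic_counts or edf_dir")
    root = Path(cfg.edf_dir)
    all_records: list[io_epochs.EpochRecord] = []
    fs_seen = None
    for edf_path in sorted(root.glob("*.edf")):
        hyp_path = edf_path.with_suffix(cfg.hypnogram_suffix)
        if not hyp_path.exists():
            logger.warning("no hypnogram for %s; skipped", edf_path.name)
            continue
        chans = {}
        for ch in cfg.channels:
            data, fs = io_epochs.read_edf_channel(edf_path, ch)
            chans[ch] = data
        fs_seen = fs
        hyp = io_epochs.parse_hypnogram(hyp_path.read_text())
        es = io_epochs.segment_epochs(chans, fs, hyp, subject_id=edf_path.stem)
        all_records.extend(es.records)
    if fs_seen is None:
        raise ValueError(f"no usable EDF/hypnogram pairs under {root}")
    return io_epochs.EpochSet(records=all_records, channels=tuple(cfg.channels),
                              fs=fs_seen)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full chain and write the report bundle to ``cfg.out_dir``.

    Returns a dict with the in-memory artifacts (bank, feature matrix,
    CV result, tables).  Any stage failure propagates with the stage
    named in the log.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    t0 = time.time()
    logger.info("stage: load/generate epochs")
    epochs = _load_epochs(cfg)
    artifacts["epochs"] = epochs
    accounting = io_epochs.epoch_accounting({"dataset": epochs})
    accounting.to_csv(out / "epoch_accounting.csv")
    artifacts["accounting"] = accounting
    logger.info("loaded %d epochs in %.1fs", len(epochs), time.time() - t0)

    logger.info("stage: filter-bank design")
    bank = filterbank.design_filter_bank(
        L=cfg.L, M=cfg.M, omega_p=cfg.omega_p_pi * np.pi,
        alpha=cfg.alpha, gamma=cfg.gamma, R=cfg.R, V=cfg.V,
    )
    (out / "filter_bank.json").write_text(bank.to_json())
    artifacts["bank"] = bank

    logger.info("stage: feature extraction")
    fm = features.build_feature_matrix(epochs, bank, cfg.channels, cfg.levels)
    artifacts["features_unbalanced"] = fm

    logger.info("stage: ANOVA screening")
    screening = anova.rank_features(fm)
    screening.to_csv(out / "anova_screening.csv")
    artifacts["anova"] = screening

    if cfg.balance == "whole":
        target = cfg.target_per_class or int(
            np.median(list(fm["label"].value_counts()))
        )
        logger.info("stage: balancing to %d per class", target)
        fm = balancing.balance_classes(
            fm, balancing.BalanceSpec(target_per_class=target, seed=cfg.seed)
        )
        io_epochs.epoch_accounting(
            {"dataset": fm["label"].value_counts().to_dict()}
        ).to_csv(out / "epoch_accounting_balanced.csv")
    artifacts["features"] = fm

    logger.info("stage: repeated %d-fold CV x %d trials", cfg.k, cfg.trials)
    X, y = features.split_features(fm)
    strict_target = None
    if cfg.balance == "strict":
        strict_target = cfg.target_per_class or int(
            np.median(list(fm["label"].value_counts()))
        )
    result = evaluation.repeated_cv(
        X.to_numpy(), list(y), n_learners=cfg.n_learners,
        max_splits=cfg.max_splits, k=cfg.k, trials=cfg.trials, seed=cfg.seed,
        train_balance_target=strict_target,
    )
    artifacts["cv"] = result

    pd.DataFrame(
        {"trial": np.arange(1, cfg.trials + 1),
         "accuracy": result.per_trial_accuracy,
         "kappa": result.per_trial_kappa}
    ).to_csv(out / "per_trial_metrics.csv", index=False)
    result.confusion.to_frame().to_csv(out / "confusion_counts.csv")
    result.confusion.to_frame(percent=True).round(1).to_csv(
        out / "confusion_row_percent.csv")
    result.per_class.to_csv(out / "per_class_metrics.csv")
    summary = pd.DataFrame(
        [{"mean_accuracy": result.mean_accuracy,
          "std_accuracy": result.std_accuracy,
          "kappa": result.kappa_mean,
          "kappa_error": result.kappa_error,
          "n_epochs": len(fm)}]
    )
    summary.to_csv(out / "summary.csv", index=False)
    logger.info("done in %.1fs: %s", time.time() - t0, result.summary())
    return artifacts
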