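"""Class balancing by random resampling.

Overnight recordings are dominated by S2 while S1 is rare (4.36% of
the study database), which biases a classifier toward the majority
stages.  Balancing equalizes the per-stage counts: minority classes
are over-sampled by drawing *exact duplicates* uniformly with
replacement, majority classes under-sampled uniformly without
replacement.  No synthetic examples are created.

The per-group targets used in the study are exposed as
``STUDY_TARGETS``; arbitrary targets are allowed.  Balancing is
applied to the whole dataset before cross-validation, matching the
epoch totals the study reports; note that duplicated minority epochs
can then appear in both training and test folds, which inflates CV
scores relative to balancing within training folds only (a ``strict``
mode is available for the latter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_epochs import EpochSet
from .stages import STAGES

#: Per-group balanced per-class epoch counts used in the study.
STUDY_TARGETS: dict[str, int] = {
    "healthy": 1000,
    "insomnia": 1400,
    "bruxism": 71,
    "narcolepsy": 935,
    "NFLE": 4480,
    "PLM": 1262,
    "RBD": 3779,
    "SDB": 480,
    "all_disordered": 12500,
    "all_combined": 14000,
}


@dataclass(frozen=True)
class BalanceSpec:
    target_per_class: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_per_class < 1:
            raise ValueError("target_per_class must be >= 1")


def _balanced_indices(labels: list[str], spec: BalanceSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed & 0x7FFFFFFF)
    labels_arr = np.asarray(labels)
    chosen: list[np.ndarray] = []
    for stage in STAGES:
        idx = np.flatnonzero(labels_arr == stage)
        if idx.size == 0:
            raise ValueError(
                f"class {stage!r} absent from input; cannot over-sample from nothing"
            )
        if idx.size >= spec.target_per_class:
            take = rng.choice(idx, size=spec.target_per_class, replace=False)
        else:
            extra = rng.choice(idx, size=spec.target_per_class - idx.size, replace=True)
            take = np.concatenate([idx, extra])
        chosen.append(np.sort(take))
    return np.concatenate(chosen)


def balance_classes(data: "pd.DataFrame | EpochSet", spec: BalanceSpec):
    """Return a copy of ``data`` with exactly ``target_per_class`` rows
    per stage, selected by seeded resampling.

    Accepts a feature matrix (with a ``label`` column) or an
    ``EpochSet``; the return type matches the input.
    """
    if isinstance(data, EpochSet):
        idx = _balanced_indices(data.labels(), spec)
        return EpochSet(records=[data.records[i] for i in idx],
                        channels=data.channels, fs=data.fs)
    if "label" not in data.columns:
        raise ValueError("feature matrix must carry a 'label' column")
    idx = _balanced_indices(list(data["label"]), spec)
    return data.iloc[idx].reset_index(drop=True)
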