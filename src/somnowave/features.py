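"""Sub-band norm features.

Each epoch channel is decomposed into six sub-bands and summarized by
the l1, l2 and l-infinity norms of each sub-band's coefficients: 3
norms x 6 sub-bands = 18 features per channel, 36 when the two study
channels are concatenated.  No scaling or feature selection is applied
-- the downstream tree ensemble is scale-invariant and the feature set
is deliberately small.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .filterbank import WaveletFilterBank
from .io_epochs import EpochRecord, EpochSet
from .transform import SUBBAND_NAMES, wavedec

logger = logging.getLogger(__name__)

NORM_NAMES = ("l1", "l2", "linf")
META_COLUMNS = ("label", "group", "subject")


def lm_norm(u: np.ndarray, m: int) -> float:
    """(sum |u[n]|^m)^(1/m) for positive integer m."""
    if m < 1:
        raise ValueError("m must be a positive integer")
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        logger.debug("lm_norm of empty vector -> 0 by convention")
        return 0.0
    return float(np.sum(np.abs(u) ** m) ** (1.0 / m))


def linf_norm(u: np.ndarray) -> float:
    """Peak absolute value."""
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        logger.debug("linf_norm of empty vector -> 0 by convention")
        return 0.0
    return float(np.max(np.abs(u)))


def feature_names(channels: Sequence[str]) -> list[str]:
    return [
        f"{ch}_{sb}_{nm}"
        for ch in channels
        for nm in NORM_NAMES
        for sb in SUBBAND_NAMES
    ]


def epoch_features(
    epoch: EpochRecord,
    bank: WaveletFilterBank,
    channels: Sequence[str],
    levels: int = 5,
) -> dict[str, float]:
    """Named norm features of one epoch over the requested channels."""
    out: dict[str, float] = {}
    for ch in channels:
        if ch not in epoch.samples:
            raise KeyError(
                f"channel {ch!r} not in epoch (has {sorted(epoch.samples)})"
            )
        sb = wavedec(epoch.samples[ch], bank, levels, fs=epoch.fs)
        for nm in NORM_NAMES:
            for name, band in zip(SUBBAND_NAMES, sb.bands):
                if nm == "l1":
                    val = lm_norm(band, 1)
                elif nm == "l2":
                    val = lm_norm(band, 2)
                else:
                    val = linf_norm(band)
                out[f"{ch}_{name}_{nm}"] = val
    return out


def build_feature_matrix(
    epochs: EpochSet,
    bank: WaveletFilterBank,
    channels: Sequence[str] | None = None,
    levels: int = 5,
) -> pd.DataFrame:
    """One row of named features per epoch, plus label/group/subject.

    Row order follows the epoch order of the input set.
    """
    channels = tuple(channels) if channels is not None else epochs.channels
    cols = feature_names(channels)
    rows = np.empty((len(epochs), len(cols)))
    meta = {"label": [], "group": [], "subject": []}
    for i, rec in enumerate(epochs):
        feats = epoch_features(rec, bank, channels, levels)
        rows[i] = [feats[c] for c in cols]
        meta["label"].append(rec.label)
        meta["group"].append(rec.group)
        meta["subject"].append(rec.subject_id)
    df = pd.DataFrame(rows, columns=cols)
    for k, v in meta.items():
        df[k] = v
    return df


def split_features(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Separate the numeric feature block from the label column."""
    feats = df.drop(columns=[c for c in META_COLUMNS if c in df.columns])
    return feats, df["label"]
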