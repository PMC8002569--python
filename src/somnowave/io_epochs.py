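"""Reading signals and annotations, and epoch bookkeeping.

EDF (European Data Format) signals are read through MNE.  Writing uses
a minimal in-package 16-bit EDF writer (one data record per second,
standard 256-byte headers) so synthetic cohorts can be round-tripped
through the same reader path a real recording would take.

Hypnograms are plain-text delimited exports with a header row and, at
minimum, a sleep-stage column plus either a clock-time column
(hh:mm:ss, onsets taken relative to the first scored row with midnight
wrap) or a numeric onset-in-seconds column.  Scoring is assumed to be
in 30-s epochs per the R&K rules.
"""

from __future__ import annotations

import io
import logging

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stages import STAGES, normalize_stage, require_stage

logger = logging.getLogger(__name__)

EPOCH_SECONDS = 30.0


@dataclass
class EpochRecord:
    """One labelled 30-s EEG segment."""

    samples: dict[str, np.ndarray]  # channel name -> samples (uV)
    label: str
    subject_id: str
    group: str
    fs: float
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.label = require_stage(self.label)


@dataclass
class EpochSet:
    """An ordered collection of epochs sharing channels and rate."""

    records: list[EpochRecord]
    channels: tuple[str, ...]
    fs: float

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def stage_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STAGES}
        for r in self.records:
            counts[r.label] += 1
        return counts


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, channels: Mapping[str, np.ndarray], fs: float,
              patient_id: str = "X", recording_id: str = "synthetic") -> None:
    """Write channels to a 16-bit EDF file with 1-second data records.

    ``fs`` must be a positive integer rate; the signal is truncated to
    a whole number of seconds.  Physical scaling per channel is chosen
    from the data range, so the quantization step is
    ``(pmax - pmin) / (2^16 - 1)``.
    """
    fs_i = int(round(fs))
    if fs_i <= 0 or abs(fs - fs_i) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    names = list(channels)
    data = [np.asarray(channels[c], dtype=float) for c in names]
    n_sec = min(len(d) // fs_i for d in data)
    if n_sec == 0:
        raise ValueError("signals shorter than one 1-second data record")

    digital_min, digital_max = -32768, 32767
    phys = []
    scaled = []
    for d in data:
        d = d[: n_sec * fs_i]
        pmin, pmax = float(np.min(d)), float(np.max(d))
        if pmax <= pmin:  # constant channel
            pmin, pmax = pmin - 1.0, pmax + 1.0
        gain = (digital_max - digital_min) / (pmax - pmin)
        dig = np.round((d - pmin) * gain + digital_min).astype("<i2")
        phys.append((pmin, pmax))
        scaled.append(dig)

    ns = len(names)
    header = io.BytesIO()
    header.write(_pad("0", 8))
    header.write(_pad(patient_id, 80))
    header.write(_pad(recording_id, 80))
    header.write(_pad("01.01.01", 8))
    header.write(_pad("00.00.00", 8))
    header.write(_pad(str(256 * (1 + ns)), 8))
    header.write(_pad("", 44))
    header.write(_pad(str(n_sec), 8))
    header.write(_pad("1", 8))  # record duration, seconds
    header.write(_pad(str(ns), 4))
    for name in names:
        header.write(_pad(name, 16))
    for _ in names:
        header.write(_pad("EEG", 80))  # transducer
    for _ in names:
        header.write(_pad("uV", 8))
    for pmin, _ in phys:
        header.write(_pad(f"{pmin:.8g}"[:8], 8))
    for _, pmax in phys:
        header.write(_pad(f"{pmax:.8g}"[:8], 8))
    header.write(b"".join(_pad(str(digital_min), 8) for _ in names))
    header.write(b"".join(_pad(str(digital_max), 8) for _ in names))
    for _ in names:
        header.write(_pad("", 80))  # prefilter
    for _ in names:
        header.write(_pad(str(fs_i), 8))
    for _ in names:
        header.write(_pad("", 32))  # reserved

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for rec in range(n_sec):
            for dig in scaled:
                fh.write(dig[rec * fs_i: (rec + 1) * fs_i].tobytes())


def _norm_channel(name: str) -> str:
    return "".join(name.split()).upper()


def read_edf_channel(path, channel_name: str) -> tuple[np.ndarray, float]:
    """Read one channel from an EDF file, in physical units (uV).

    Channel matching is case-insensitive and whitespace-normalized.
    Raises ``KeyError`` naming the available channels when absent.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    wanted = _norm_channel(channel_name)
    match = None
    for ch in raw.ch_names:
        if _norm_channel(ch) == wanted:
            match = ch
            break
    if match is None:
        raise KeyError(
            f"channel {channel_name!r} not found; available: {raw.ch_names}"
        )
    fs = float(raw.info["sfreq"])
    data = raw.get_data(picks=[match])[0]
    # MNE scales EEG channels to volts; report microvolts as recorded.
    kind = mne.channel_type(raw.info, raw.ch_names.index(match))
    if kind in ("eeg", "eog", "emg", "ecg", "bio"):
        data = data * 1e6
    return np.asarray(data, dtype=float), fs


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------

_STAGE_COLS = ("sleep stage", "stage")
_TIME_COLS = ("time [hh:mm:ss]", "time", "position", "onset[s]", "onset")


def _parse_clock(text: str) -> float:
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise ValueError(f"not an hh:mm:ss time: {text!r}")
    h, m, s = (float(p) for p in parts)
    return 3600 * h + 60 * m + s


def parse_hypnogram(
    stream,
    stage_column: str | None = None,
    time_column: str | None = None,
    delimiter: str | None = None,
) -> list[tuple[float, str]]:
    """Parse a delimited hypnogram into ordered ``(onset_s, stage)`` pairs.

    One entry per scored 30-s epoch.  ``R``/``REM`` map to REM; labels
    outside the six-class set (e.g. movement time) are dropped and the
    drop count logged.  Clock times are referenced to the first scored
    row, wrapping over midnight.  A malformed line raises ``ValueError``
    with its line number.
    """
    if isinstance(stream, (str, bytes)):
        stream = io.StringIO(stream if isinstance(stream, str) else stream.decode())
    lines = [ln.rstrip("\n") for ln in stream]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return []
    delim = delimiter
    if delim is None:
        delim = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(delim)]
    lower = [h.lower() for h in header]

    def find(explicit: str | None, candidates: Sequence[str], what: str) -> int:
        if explicit is not None:
            if explicit not in header:
                raise ValueError(f"{what} column {explicit!r} not in header {header}")
            return header.index(explicit)
        for cand in candidates:
            if cand in lower:
                return lower.index(cand)
        raise ValueError(f"no {what} column found in header {header}")

    si = find(stage_column, _STAGE_COLS, "stage")
    ti = find(time_column, _TIME_COLS, "time")

    out: list[tuple[float, str]] = []
    dropped = 0
    t0: float | None = None
    prev_rel = -np.inf
    for lineno, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) <= max(si, ti):
            raise ValueError(f"hypnogram line {lineno}: too few fields: {line!r}")
        raw_stage, raw_time = fields[si], fields[ti]
        try:
            if ":" in raw_time:
                clock = _parse_clock(raw_time)
                if t0 is None:
                    t0 = clock
                rel = clock - t0
                while rel < prev_rel:  # midnight wrap
                    rel += 86400.0
            else:
                rel = float(raw_time)
        except ValueError as exc:
            raise ValueError(f"hypnogram line {lineno}: {exc}") from None
        prev_rel = rel
        stage = normalize_stage(raw_stage)
        if stage is None:
            dropped += 1
            continue
        out.append((float(rel), stage))
    if dropped:
        logger.info("parse_hypnogram: dropped %d unscored/other epochs", dropped)
    out.sort(key=lambda p: p[0])
    return out


def write_hypnogram(entries: Iterable[tuple[float, str]]) -> str:
    """Serialize ``(onset_s, stage)`` pairs in the supported dialect."""
    lines = ["Sleep Stage\tOnset[s]\tDuration[s]"]
    for onset, stage in entries:
        lines.append(f"{require_stage(stage)}\t{onset:g}\t30")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Segmentation and accounting
# ---------------------------------------------------------------------------

def segment_epochs(
    samples: Mapping[str, np.ndarray],
    fs: float,
    hypnogram: Sequence[tuple[float, str]],
    subject_id: str = "",
    group: str = "",
) -> EpochSet:
    """Cut labelled 30-s epochs out of continuous per-channel signals.

    Epochs start at the hypnogram onsets; an epoch not fully covered by
    signal is dropped (logged).  All channels must share the length.
    """
    channels = tuple(samples)
    arrays = {c: np.asarray(samples[c], dtype=float) for c in channels}
    lengths = {len(a) for a in arrays.values()}
    if len(lengths) > 1:
        raise ValueError(f"channels differ in length: { {c: len(a) for c, a in arrays.items()} }")
    n = lengths.pop() if lengths else 0
    epoch_len = int(round(fs * EPOCH_SECONDS))

    records = []
    dropped = 0
    for idx, (onset, label) in enumerate(hypnogram):
        start = int(round(onset * fs))
        stop = start + epoch_len
        if start < 0 or stop > n:
            dropped += 1
            continue
        records.append(
            EpochRecord(
                samples={c: arrays[c][start:stop] for c in channels},
                label=label,
                subject_id=subject_id,
                group=group,
                fs=fs,
                epoch_index=idx,
            )
        )
    if dropped:
        logger.warning("segment_epochs: dropped %d epochs not covered by signal", dropped)
    return EpochSet(records=records, channels=channels, fs=fs)


def epoch_accounting(sets: Mapping[str, "EpochSet | Mapping[str, int]"]) -> pd.DataFrame:
    """Per-group per-stage epoch counts with totals and percentages.

    Accepts EpochSets or plain stage->count mappings per group.  The
    returned frame has one row per stage plus a ``Total`` row; the
    ``Percent`` column is 100 x stage total / grand total, rounded to
    two decimals.
    """
    if not sets:
        raise ValueError("epoch_accounting requires at least one group")
    cols = {}
    for name, obj in sets.items():
        counts = obj.stage_counts() if isinstance(obj, EpochSet) else dict(obj)
        cols[name] = [int(counts.get(s, 0)) for s in STAGES]
    df = pd.DataFrame(cols, index=list(STAGES))
    df["Total"] = df.sum(axis=1)
    grand = int(df["Total"].sum())
    df["Percent"] = (100.0 * df["Total"] / grand).round(2) if grand else 0.0
    total_row = df.sum(axis=0)
    total_row["Percent"] = round(float(df["Percent"].sum()), 2)
    df.loc["Total"] = total_row
    return df
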