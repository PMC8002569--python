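"""Stage-conditioned synthetic EEG.

Real polysomnography is bulky and access-controlled, so the package
ships a generator that emulates the *spectral* physiology of the six
R&K stages at the study's 512 Hz sampling rate: each stage is a mixture
of band-limited Gaussian noise components (delta/theta/alpha/sigma/
beta/gamma) with stage-specific relative band powers and an overall
RMS amplitude target in microvolts.  Deep sleep (S4) is delta-dominant
and large; wake and REM are low-amplitude mixtures rich in alpha/beta
and theta/beta respectively.  This reproduces the qualitative feature
pattern seen on real data (coarsest sub-band norms maximal in S4)
without attempting transients such as spindles, K-complexes or
artifacts.

Cohorts mirror the per-group class imbalance of the study database
(e.g. the healthy group's 280 S1 epochs against 2172 S2 epochs).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .io_epochs import EpochRecord, EpochSet
from .stages import STAGES, STAGE_INDEX, require_stage

#: EEG band edges in Hz, in ascending order.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 32.0),
    "gamma": (32.0, 64.0),
}

_BAND_NAMES = tuple(BANDS)


@dataclass(frozen=True)
class StageProfile:
    """Relative band powers and amplitude target for one stage.

    ``band_weights`` are dimensionless relative powers per band in the
    order delta, theta, alpha, sigma, beta, gamma; ``amplitude_scale``
    is the target signal RMS in microvolts.
    """

    stage: str
    band_weights: tuple[float, ...]
    amplitude_scale: float

    def __post_init__(self) -> None:
        require_stage(self.stage)
        w = np.asarray(self.band_weights, dtype=float)
        if w.shape != (len(BANDS),):
            raise ValueError(f"expected {len(BANDS)} band weights, got {w.shape}")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("band_weights must be non-negative with at least one > 0")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")


# Default profiles: weights over (delta, theta, alpha, sigma, beta, gamma).
# Wake = alpha/beta dominant and low amplitude; S1 theta; S2 theta+sigma
# (spindle band); S3 delta 60%/theta 30%; S4 delta 85% and largest
# amplitude; REM mixed theta/beta, low amplitude.
DEFAULT_PROFILES: dict[str, StageProfile] = {
    "W": StageProfile("W", (0.05, 0.10, 0.45, 0.10, 0.25, 0.05), 30.0),
    "S1": StageProfile("S1", (0.15, 0.50, 0.15, 0.05, 0.10, 0.05), 40.0),
    "S2": StageProfile("S2", (0.25, 0.35, 0.10, 0.20, 0.08, 0.02), 50.0),
    "S3": StageProfile("S3", (0.60, 0.30, 0.04, 0.03, 0.02, 0.01), 65.0),
    "S4": StageProfile("S4", (0.85, 0.10, 0.02, 0.01, 0.01, 0.01), 80.0),
    "REM": StageProfile("REM", (0.10, 0.45, 0.10, 0.05, 0.25, 0.05), 35.0),
}

#: Channels emulated by default, matching the study montage.
DEFAULT_CHANNELS: tuple[str, ...] = ("F4-C4", "C4-A1")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort: per-group, per-stage epoch counts."""

    groups: tuple[tuple[str, Mapping[str, int]], ...]
    fs: float = 512.0
    epoch_s: float = 30.0
    seed: int = 0
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        for name, counts in self.groups:
            for stage, n in counts.items():
                require_stage(stage)
                if n < 0:
                    raise ValueError(f"negative count for ({name}, {stage})")

    def labels(self) -> list[tuple[str, str]]:
        """Flat (group, stage) label list in deterministic order."""
        out = []
        for name, counts in self.groups:
            for stage in STAGES:
                out.extend([(name, stage)] * int(counts.get(stage, 0)))
        return out


def healthy_cohort_spec(seed: int = 0, fs: float = 512.0, epoch_s: float = 30.0,
                        channels: Sequence[str] = DEFAULT_CHANNELS) -> CohortSpec:
    """The healthy-group class imbalance of the study (6063 epochs)."""
    counts = {"W": 445, "S1": 280, "S2": 2172, "S3": 573, "S4": 1184, "REM": 1409}
    return CohortSpec((("healthy", counts),), fs=fs, epoch_s=epoch_s, seed=seed,
                      channels=tuple(channels))


def _band_sos(lo: float, hi: float, fs: float):
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    if hi <= lo:
        return None
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _epoch_rng(seed: int, stage: str, extra: Sequence[int] = ()) -> np.random.Generator:
    # Seed stream derived from (seed, stage, extra) so cohorts are
    # order-independent and epochs individually reproducible.
    return np.random.default_rng([seed & 0x7FFFFFFF, STAGE_INDEX[stage], *extra])


def generate_epoch(
    stage: str,
    fs: float = 512.0,
    epoch_s: float = 30.0,
    seed: int = 0,
    profiles: Mapping[str, StageProfile] | None = None,
    _extra_key: Sequence[int] = (),
) -> np.ndarray:
    """Generate one synthetic EEG epoch for ``stage``.

    Returns ``round(fs * epoch_s)`` samples in microvolts: a sum of
    band-passed white-noise components weighted by the stage profile,
    rescaled to the profile's RMS amplitude.  Deterministic in
    ``(stage, fs, epoch_s, seed)``.
    """
    stage = require_stage(stage)
    if fs < 128:
        raise ValueError("fs must be >= 128 Hz to resolve the EEG bands")
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    profile = (profiles or DEFAULT_PROFILES)[stage]
    n = int(round(fs * epoch_s))
    rng = _epoch_rng(seed, stage, _extra_key)

    weights = np.asarray(profile.band_weights, dtype=float)
    weights = weights / weights.sum()
    # Pad so the zero-phase band-pass transient does not bias epoch edges.
    pad = min(n, int(2 * fs))
    x = np.zeros(n)
    for w, name in zip(weights, _BAND_NAMES):
        noise = rng.standard_normal(n + 2 * pad)
        if w <= 0:
            continue
        sos = _band_sos(*BANDS[name], fs)
        if sos is None:
            continue
        comp = signal.sosfiltfilt(sos, noise)[pad:pad + n]
        rms = np.sqrt(np.mean(comp**2))
        if rms > 0:
            x += np.sqrt(w) * comp / rms
    total_rms = np.sqrt(np.mean(x**2))
    if total_rms > 0:
        x *= profile.amplitude_scale / total_rms
    return x


def generate_cohort(
    spec: CohortSpec,
    profiles: Mapping[str, StageProfile] | None = None,
) -> EpochSet:
    """Generate a labelled cohort with exactly the requested counts.

    Each epoch draws an independent reproducible stream keyed by
    (master seed, group, stage, index, channel), so the cohort is
    identical regardless of generation order.  Channels of one epoch
    are independent realizations of the same stage profile.
    """
    records: list[EpochRecord] = []
    for name, counts in spec.groups:
        gkey = zlib.crc32(name.encode()) & 0x7FFFFFFF
        for stage in STAGES:
            for i in range(int(counts.get(stage, 0))):
                chans = {
                    ch: generate_epoch(
                        stage, spec.fs, spec.epoch_s, spec.seed,
                        profiles=profiles,
                        _extra_key=(gkey, i, ci),
                    )
                    for ci, ch in enumerate(spec.channels)
                }
                records.append(
                    EpochRecord(
                        samples=chans,
                        label=stage,
                        subject_id=f"{name}-synth",
                        group=name,
                        fs=spec.fs,
                        epoch_index=i,
                    )
                )
    return EpochSet(records=records, channels=tuple(spec.channels), fs=spec.fs)


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean periodogram power of ``x`` inside ``band`` (Hz); diagnostic."""
    f, pxx = signal.periodogram(x, fs=fs)
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    return float(np.trapezoid(pxx[mask], f[mask]))
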