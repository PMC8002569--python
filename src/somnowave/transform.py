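"""Multilevel wavelet decomposition with periodic boundary handling.

A 30-s epoch at 512 Hz has 15,360 = 30 * 512 samples, divisible by
2^5, so five levels of periodized analysis halve the length exactly at
every step and the six sub-bands have deterministic lengths
(480, 480, 960, 1920, 3840, 7680).  Periodic extension also makes
perfect reconstruction exact rather than approximate at the edges;
epochs are long relative to the filters, so the boundary choice is
immaterial to the features.

Filtering is zero-phase circular convolution (the filters are
symmetric, so aligning on the filter center removes the group delay);
the approximation branch keeps even-indexed samples and the detail
branch odd-indexed ones, which is the phase pairing under which the
modulated highpass filters cancel aliasing exactly.

Sub-band ordering: Sb-1 is the level-5 approximation (coarsest,
0-8 Hz at 512 Hz), Sb-2 the level-5 detail, ..., Sb-6 the level-1
detail (128-256 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filterbank import WaveletFilterBank

SUBBAND_NAMES = ("Sb1", "Sb2", "Sb3", "Sb4", "Sb5", "Sb6")


@dataclass
class SubbandSet:
    """The J+1 coefficient arrays from a J-level decomposition."""

    bands: list[np.ndarray]  # [a_J, d_J, d_{J-1}, ..., d_1]
    levels: int
    fs: float | None = None

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def level_map(self) -> list[tuple[int, str]]:
        out = [(self.levels, "approx")]
        out += [(self.levels - i, "detail") for i in range(self.levels)]
        return out


def _circ_filter_zero_phase(x: np.ndarray, taps: np.ndarray, center: int) -> np.ndarray:
    """Circular convolution with the filter aligned on its center tap."""
    n = len(x)
    y = np.convolve(x, taps)
    out = np.zeros(n)
    idx = (np.arange(len(y)) - center) % n
    np.add.at(out, idx, y)
    return out


def analyze_one_level(x: np.ndarray, bank: WaveletFilterBank) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: periodized filtering and dyadic downsampling."""
    x = np.asarray(x, dtype=float)
    max_len = max(len(bank.h0), len(bank.h1))
    if len(x) < max_len:
        raise ValueError(f"input length {len(x)} shorter than filter length {max_len}")
    if len(x) % 2:
        raise ValueError("periodized analysis requires even input length")
    lo = _circ_filter_zero_phase(x, bank.h0.coeffs, bank.h0.center)
    hi = _circ_filter_zero_phase(x, np.asarray(bank.h1), (len(bank.h1) - 1) // 2)
    return lo[0::2], hi[1::2]


def synthesize_one_level(approx: np.ndarray, detail: np.ndarray,
                         bank: WaveletFilterBank) -> np.ndarray:
    """Inverse of :func:`analyze_one_level`."""
    if len(approx) != len(detail):
        raise ValueError("approximation and detail lengths differ")
    n = 2 * len(approx)
    up0 = np.zeros(n)
    up0[0::2] = approx
    up1 = np.zeros(n)
    up1[1::2] = detail
    y0 = _circ_filter_zero_phase(up0, bank.f0.coeffs, bank.f0.center)
    y1 = _circ_filter_zero_phase(up1, np.asarray(bank.f1), (len(bank.f1) - 1) // 2)
    return y0 + y1


def _one_level_roundtrip_error(bank: WaveletFilterBank, n: int = 64,
                               seed: int = 12345) -> float:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    a, d = analyze_one_level(x, bank)
    xh = synthesize_one_level(a, d, bank)
    return float(np.linalg.norm(x - xh) / np.linalg.norm(x))


def wavedec(x: np.ndarray, bank: WaveletFilterBank, levels: int = 5,
            fs: float | None = None) -> SubbandSet:
    """J-level decomposition into J+1 sub-bands, coarsest first."""
    x = np.asarray(x, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(x) % (2**levels):
        raise ValueError(
            f"length {len(x)} not divisible by 2^{levels}; periodized cascade undefined"
        )
    if len(x) // (2**levels) < 1:
        raise ValueError(f"signal too short for {levels} levels")
    details = []
    approx = x
    for _ in range(levels):
        approx, d = analyze_one_level(approx, bank)
        details.append(d)
    bands = [approx] + details[::-1]
    return SubbandSet(bands=bands, levels=levels, fs=fs)


def waverec(sb: SubbandSet, bank: WaveletFilterBank) -> np.ndarray:
    """Inverse cascade; exact up to floating-point roundoff."""
    approx = sb.bands[0]
    for d in sb.bands[1:]:
        if len(d) != len(approx):
            raise ValueError(
                f"band-length mismatch: approx {len(approx)} vs detail {len(d)}"
            )
        approx = synthesize_one_level(approx, d, bank)
    return approx
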