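"""Design of linear-phase optimal biorthogonal wavelet filter banks.

The two-channel bank is built around a *halfband* analysis lowpass
filter: odd length L, center tap 1/2, every second off-center tap
structurally zero.  Its zero-phase amplitude

    A(w) = 1/2 + 2 * sum_k a_k cos((2k-1) w)

automatically satisfies the halfband identity A(w) + A(pi - w) = 1, so
passband and stopband errors coincide and a single stopband energy
term suffices.  The free odd-offset taps ``a_k`` are found by
minimizing a convex combination of

* stopband energy  E_s = int_{pi-w_p}^{pi} A(w)^2 dw   (closed-form
  cosine-product integrals), and
* a time-frequency localization penalty (second moments of the taps in
  time and of A in frequency),

subject to linear regularity constraints (even-order derivatives of A
vanishing at pi; odd orders vanish by symmetry).  The objective is a
strictly convex quadratic, so the equality-constrained minimum is the
unique solution of the KKT linear system -- the eigenfilter family of
designs with a direct linear-algebra solve.

The synthesis lowpass filter is a general symmetric odd-length filter
found from linear constraints: perfect reconstruction (the product
filter p = h0 * f0 must be halfband with p[center] = 1), the requested
number of vanishing moments, and -- when degrees of freedom remain --
the same convex objective.  Highpass filters follow by modulation and
the completed bank is verified by an analysis/synthesis roundtrip on a
random probe before it is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_GRID = 8192  # quadrature grid for frequency-domain moments


@dataclass(frozen=True)
class LinearPhaseFilter:
    """A symmetric (linear-phase) FIR filter of odd length."""

    coeffs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        object.__setattr__(self, "coeffs", c)
        if c.ndim != 1 or len(c) % 2 == 0 or len(c) < 1:
            raise ValueError("linear-phase filter must be a 1-D odd-length vector")
        if not np.allclose(c, c[::-1], atol=1e-12):
            raise ValueError("filter is not symmetric")

    def __len__(self) -> int:
        return len(self.coeffs)

    @property
    def center(self) -> int:
        return (len(self.coeffs) - 1) // 2

    def amplitude(self, omega: np.ndarray) -> np.ndarray:
        """Zero-phase amplitude A(w) = g[c] + 2 sum_k g[c+k] cos(k w)."""
        omega = np.asarray(omega, dtype=float)
        c = self.center
        out = np.full_like(omega, self.coeffs[c])
        for k in range(1, c + 1):
            out = out + 2.0 * self.coeffs[c + k] * np.cos(k * omega)
        return out


@dataclass(frozen=True)
class HalfbandFilter(LinearPhaseFilter):
    """Halfband lowpass: center tap 1/2, even off-center taps exactly 0."""

    def __post_init__(self) -> None:
        super().__post_init__()
        c = self.center
        if self.coeffs[c] != 0.5:
            raise ValueError("halfband filter requires center tap exactly 1/2")
        for k in range(2, c + 1, 2):
            if self.coeffs[c + k] != 0.0:
                raise ValueError("halfband filter requires exact zeros at even offsets")

    @property
    def free_taps(self) -> np.ndarray:
        """The odd-offset taps a_k = h[c + (2k-1)], k = 1..K."""
        c = self.center
        return self.coeffs[c + 1:: 2].copy()


def halfband_from_free_taps(a: Sequence[float]) -> HalfbandFilter:
    """Assemble the full symmetric halfband tap vector from a_1..a_K."""
    a = np.asarray(a, dtype=float)
    K = len(a)
    c = 2 * K - 1
    h = np.zeros(2 * c + 1)
    h[c] = 0.5
    for k in range(1, K + 1):
        h[c + 2 * k - 1] = a[k - 1]
        h[c - (2 * k - 1)] = a[k - 1]
    return HalfbandFilter(h)


# ---------------------------------------------------------------------------
# quadratic forms
# ---------------------------------------------------------------------------

def _cos_product_integral(m: int, n: int, lo: float, hi: float) -> float:
    """Closed-form int_lo^hi cos(m w) cos(n w) dw."""
    def s(q: int) -> float:
        if q == 0:
            return hi - lo
        return (np.sin(q * hi) - np.sin(q * lo)) / q
    return 0.5 * (s(m - n) + s(m + n))


def _cos_integral(m: int, lo: float, hi: float) -> float:
    if m == 0:
        return hi - lo
    return (np.sin(m * hi) - np.sin(m * lo)) / m


def _stopband_quadratic(offsets: np.ndarray, center_val: float, omega_p: float
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """E_s as (G, g, const) for A(w) = center_val + 2 sum b_k cos(m_k w).

    ``offsets`` are the cosine harmonics m_k of the variable taps.
    """
    lo, hi = np.pi - omega_p, np.pi
    K = len(offsets)
    G = np.empty((K, K))
    for i, m in enumerate(offsets):
        for j, n in enumerate(offsets):
            G[i, j] = 4.0 * _cos_product_integral(int(m), int(n), lo, hi)
    g = np.array([4.0 * center_val * _cos_integral(int(m), lo, hi) for m in offsets])
    const = center_val**2 * (hi - lo)
    return G, g, const


def _freq_moment_quadratic(offsets: np.ndarray, center_val: float
                           ) -> tuple[np.ndarray, np.ndarray, float]:
    """int_0^pi w^2 A(w)^2 dw as a quadratic form, by quadrature."""
    w = np.linspace(0.0, np.pi, _GRID)
    wt = np.full(_GRID, np.pi / (_GRID - 1))
    wt[0] *= 0.5
    wt[-1] *= 0.5  # trapezoid
    wt = wt * w**2
    C = 2.0 * np.cos(np.outer(w, offsets))  # grid x K
    G = C.T @ (wt[:, None] * C)
    g = 2.0 * center_val * (wt @ C)
    const = center_val**2 * float(wt.sum())
    return G, g, const


def _solve_constrained_quadratic(G: np.ndarray, g: np.ndarray,
                                 C: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Minimize x^T G x + g^T x subject to C x = d.

    Solved in the constraint null space; the reduced Hessian must be
    positive definite (it is, for any positive band-error or
    localization weight), which makes the minimizer unique.
    """
    if C.size:
        x_p, *_ = np.linalg.lstsq(C, d, rcond=None)
        if not np.allclose(C @ x_p, d, atol=1e-9):
            raise ValueError("constraint system is infeasible")
        # null-space basis via SVD
        _, s, Vt = np.linalg.svd(C)
        rank = int(np.sum(s > 1e-12 * max(s[0], 1.0))) if s.size else 0
        N = Vt[rank:].T
    else:
        x_p = np.zeros(G.shape[0])
        N = np.eye(G.shape[0])
    if N.shape[1] == 0:
        return x_p
    H = N.T @ G @ N
    rhs = -N.T @ (2.0 * G @ x_p + g) / 2.0
    try:
        z = np.linalg.solve(H, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate objective in the reduced space: {exc}") from exc
    return x_p + N @ z


# ---------------------------------------------------------------------------
# analysis halfband design
# ---------------------------------------------------------------------------

def design_halfband_analysis(
    L: int = 15,
    omega_p: float = 0.4 * np.pi,
    alpha: float = 0.95,
    gamma: float = 0.05,
    R: int = 2,
    lam: float = 1.0,
) -> HalfbandFilter:
    """Design the halfband analysis lowpass filter of length ``L``.

    Parameters
    ----------
    L : odd filter length.
    omega_p : passband edge in radians, 0 < omega_p < pi/2.  By the
        halfband identity the stopband starts at pi - omega_p.
    alpha : weight of the band-error term in [0, 1].
    gamma : weight of the time-frequency localization term (>= 0).
    R : regularity order; imposes vanishing of A and its even
        derivatives at pi up to order 2R-1 (R linear constraints).
    lam : relative weight of the frequency moment inside the
        localization term.
    """
    if L < 3 or L % 2 == 0:
        raise ValueError("L must be odd and >= 3")
    if not (0.0 < omega_p < np.pi / 2):
        raise ValueError("omega_p must lie in (0, pi/2)")
    if not (0.0 <= alpha <= 1.0) or gamma < 0:
        raise ValueError("need 0 <= alpha <= 1 and gamma >= 0")
    if alpha == 0 and gamma == 0:
        raise ValueError("objective is empty: alpha and gamma are both zero")
    c = (L - 1) // 2
    K = (c + 1) // 2  # number of free odd-offset taps
    if R < 0 or R > K:
        raise ValueError(f"regularity order R={R} infeasible for K={K} free taps")

    offsets = np.array([2 * k - 1 for k in range(1, K + 1)])

    # Regularity: A(pi) = 0 and even derivatives up to order 2(R-1).
    # Row j: sum_k a_k (2k-1)^(2j) = (1/4 if j == 0 else 0).
    C = np.array([[float(m) ** (2 * j) for m in offsets] for j in range(R)])
    d = np.array([0.25 if j == 0 else 0.0 for j in range(R)])

    Gs, gs, _ = _stopband_quadratic(offsets, 0.5, omega_p)
    # time moment: h[c +/- m_k] = a_k at distance m_k from center
    Gt = np.diag(2.0 * offsets.astype(float) ** 2)
    Gw, gw, _ = _freq_moment_quadratic(offsets, 0.5)

    G = alpha * Gs + gamma * (Gt + lam * Gw)
    g = alpha * gs + gamma * lam * gw
    a = _solve_constrained_quadratic(G, g, C, d)
    return halfband_from_free_taps(a)


# ---------------------------------------------------------------------------
# synthesis lowpass design
# ---------------------------------------------------------------------------

def _symmetry_map(M: int) -> np.ndarray:
    """Map half-parameters b = (f[c], f[c+1], ..., f[M-1]) to full taps."""
    c = (M - 1) // 2
    S = np.zeros((M, c + 1))
    S[c, 0] = 1.0
    for k in range(1, c + 1):
        S[c + k, k] = 1.0
        S[c - k, k] = 1.0
    return S


def design_synthesis_lowpass(
    h0: HalfbandFilter,
    M: int = 25,
    V: int = 2,
    alpha: float = 0.95,
    gamma: float = 0.05,
    omega_p: float = 0.4 * np.pi,
    lam: float = 1.0,
) -> LinearPhaseFilter:
    """Design the synthesis lowpass filter paired with ``h0``.

    The filter is symmetric of odd length ``M`` and satisfies exactly:

    * perfect reconstruction -- the product p = h0 * f0 is halfband
      about its center d = (L + M - 2)/2 with p[d] = 1;
    * ``V`` vanishing moments -- sum_n (-1)^n n^j f0[n] = 0 for
      j < V (odd j are implied by symmetry and lower even orders).

    Remaining degrees of freedom minimize the same stopband-energy /
    localization objective as the analysis design.  An inconsistent
    constraint system raises ``ValueError`` with a rank report.
    """
    if M < 3 or M % 2 == 0:
        raise ValueError("M must be odd and >= 3")
    if V < 1:
        raise ValueError("V must be >= 1")
    L = len(h0)
    cM = (M - 1) // 2
    nb = cM + 1
    S = _symmetry_map(M)
    d_center = (L + M - 2) // 2

    # convolution matrix: p = T @ f0,  T[j, n] = h0[j - n]
    P = L + M - 1
    T = np.zeros((P, M))
    h = h0.coeffs
    for j in range(P):
        for n in range(max(0, j - L + 1), min(M, j + 1)):
            T[j, n] = h[j - n]
    TS = T @ S  # p as a function of half-parameters b

    rows = [TS[d_center]]
    rhs = [1.0]
    for k in range(1, d_center // 2 + 1):
        rows.append(TS[d_center + 2 * k])
        rhs.append(0.0)
    n_pr = len(rows)
    for j_mom in range(V):
        n_idx = np.arange(M, dtype=float)
        mom = ((-1.0) ** n_idx) * n_idx**j_mom
        rows.append(mom @ S)
        rhs.append(0.0)
    C = np.vstack(rows)
    d = np.asarray(rhs)

    b_p, *_ = np.linalg.lstsq(C, d, rcond=None)
    if not np.allclose(C @ b_p, d, atol=1e-8):
        rank = np.linalg.matrix_rank(C)
        rank_aug = np.linalg.matrix_rank(np.column_stack([C, d]))
        raise ValueError(
            "synthesis filter is over-constrained: "
            f"{n_pr} PR + {V} moment conditions, rank {rank} vs augmented "
            f"rank {rank_aug}, {nb} free symmetric taps (length M={M}); "
            "increase M or reduce V"
        )

    offsets = np.arange(1, cM + 1)
    # objective on variable taps b = (center, side taps); amplitude
    # A_f(w) = b_0 + 2 sum b_k cos(k w): include the center as harmonic 0.
    all_off = np.arange(0, cM + 1)
    Gs = np.empty((nb, nb))
    lo, hi = np.pi - omega_p, np.pi
    for i, m in enumerate(all_off):
        for j, n in enumerate(all_off):
            fac = (1.0 if m == 0 else 2.0) * (1.0 if n == 0 else 2.0)
            Gs[i, j] = fac * _cos_product_integral(int(m), int(n), lo, hi)
    Gt = np.diag(np.concatenate([[0.0], 2.0 * offsets.astype(float) ** 2]))
    w = np.linspace(0.0, np.pi, _GRID)
    wt = np.full(_GRID, np.pi / (_GRID - 1))
    wt[0] *= 0.5
    wt[-1] *= 0.5
    wt = wt * w**2
    Cgrid = np.cos(np.outer(w, all_off))
    Cgrid[:, 1:] *= 2.0
    Gw = Cgrid.T @ (wt[:, None] * Cgrid)
    G = alpha * Gs + gamma * (Gt + lam * Gw)
    b = _solve_constrained_quadratic(G, np.zeros(nb), C, d)
    return LinearPhaseFilter(S @ b)


# ---------------------------------------------------------------------------
# bank completion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveletFilterBank:
    """The four filters of a two-channel biorthogonal bank.

    ``h0`` (analysis lowpass, halfband), ``f0`` (synthesis lowpass),
    and the modulated highpass pair ``h1``/``f1``.  A bank instance is
    only ever produced after a one-level reconstruction self-test.
    """

    h0: HalfbandFilter
    f0: LinearPhaseFilter
    h1: np.ndarray
    f1: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "format": "somnowave-filterbank",
            "version": 1,
            "h0": self.h0.coeffs.tolist(),
            "f0": self.f0.coeffs.tolist(),
            "h1": np.asarray(self.h1).tolist(),
            "f1": np.asarray(self.f1).tolist(),
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "WaveletFilterBank":
        payload = json.loads(text)
        if payload.get("format") != "somnowave-filterbank":
            raise ValueError("not a somnowave filter-bank file")
        return cls(
            h0=HalfbandFilter(np.asarray(payload["h0"], dtype=float)),
            f0=LinearPhaseFilter(np.asarray(payload["f0"], dtype=float)),
            h1=np.asarray(payload["h1"], dtype=float),
            f1=np.asarray(payload["f1"], dtype=float),
            metadata=payload.get("metadata", {}),
        )


def make_filter_bank(h0: HalfbandFilter, f0: LinearPhaseFilter,
                     metadata: dict | None = None) -> WaveletFilterBank:
    """Complete the bank by modulation and verify reconstruction.

    h1[n] = (-1)^n f0[n]; f1[n] = +/-(-1)^n h0[n], the sign chosen so
    the one-level analysis/synthesis cascade is the identity -- checked
    on a random probe rather than assumed.
    """
    from .transform import _one_level_roundtrip_error

    n0 = np.arange(len(f0))
    h1 = ((-1.0) ** n0) * f0.coeffs
    n1 = np.arange(len(h0))
    best = None
    for sign in (+1.0, -1.0):
        f1 = sign * ((-1.0) ** n1) * h0.coeffs
        bank = WaveletFilterBank(h0=h0, f0=f0, h1=h1, f1=f1,
                                 metadata=dict(metadata or {}))
        err = _one_level_roundtrip_error(bank)
        if best is None or err < best[0]:
            best = (err, bank)
    err, bank = best
    if err > 1e-8:
        raise ValueError(
            f"filter bank failed the reconstruction self-test (relative error {err:.3e})"
        )
    return bank


def design_filter_bank(
    L: int = 15,
    M: int = 25,
    omega_p: float = 0.4 * np.pi,
    alpha: float = 0.95,
    gamma: float = 0.05,
    R: int = 2,
    V: int = 2,
) -> WaveletFilterBank:
    """One-call design of the default bank (analysis + synthesis)."""
    h0 = design_halfband_analysis(L, omega_p, alpha, gamma, R)
    f0 = design_synthesis_lowpass(h0, M, V, alpha, gamma, omega_p)
    meta = {"L": L, "M": M, "omega_p": omega_p, "alpha": alpha,
            "gamma": gamma, "R": R, "V": V}
    return make_filter_bank(h0, f0, metadata=meta)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def verify_halfband(h) -> float:
    """Maximum structural deviation from the halfband form.

    Zero for a true halfband filter: every even-offset tap h[c +/- 2k]
    (k >= 1) must vanish and the center tap must equal 1/2 (reported
    as |2 h[c] - 1|, the deviation of the DC-normalized center).
    """
    coeffs = h.coeffs if hasattr(h, "coeffs") else np.asarray(h, dtype=float)
    c = (len(coeffs) - 1) // 2
    vals = [abs(2.0 * coeffs[c] - 1.0)]
    vals += [abs(coeffs[c + 2 * k]) for k in range(1, c // 2 + 1)]
    vals += [abs(coeffs[c - 2 * k]) for k in range(1, c // 2 + 1)]
    return max(vals)


def vanishing_moments(filt, tol: float = 1e-8, max_order: int = 32) -> int:
    """Largest V with |sum_n (-1)^n n^j g[n]| < tol for all j < V."""
    coeffs = filt.coeffs if hasattr(filt, "coeffs") else np.asarray(filt, dtype=float)
    n = np.arange(len(coeffs), dtype=float)
    signs = (-1.0) ** n
    for j in range(max_order):
        if abs(float(np.sum(signs * n**j * coeffs))) >= tol:
            return j
    return max_order


def tf_localization(filt, grid: int = 8192) -> tuple[float, float, float]:
    """Time and frequency variances and their product.

    sigma_t^2 in samples^2 about the filter center; sigma_w^2 in rad^2
    from the one-sided energy spectrum, by trapezoid quadrature.
    """
    coeffs = filt.coeffs if hasattr(filt, "coeffs") else np.asarray(filt, dtype=float)
    if not np.any(coeffs):
        raise ValueError("tf_localization of the zero filter is undefined")
    c = (len(coeffs) - 1) / 2.0
    n = np.arange(len(coeffs), dtype=float)
    e = coeffs**2
    sig_t2 = float(np.sum((n - c) ** 2 * e) / np.sum(e))
    w = np.linspace(0.0, np.pi, grid)
    H = np.abs(np.exp(-1j * np.outer(w, n)) @ coeffs) ** 2
    sig_w2 = float(np.trapezoid(w**2 * H, w) / np.trapezoid(H, w))
    return sig_t2, sig_w2, sig_t2 * sig_w2
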