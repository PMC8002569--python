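import numpy as np
import pytest

import somnowave as sw
from somnowave.filterbank import (
    HalfbandFilter,
    _cos_product_integral,
    halfband_from_free_taps,
)

MAXFLAT7 = np.array([-1, 0, 9, 16, 9, 0, -1]) / 32.0


def stopband_energy(filt, omega_p=0.4 * np.pi, grid=20_000):
    """Independent quadrature oracle for the stopband energy."""
    w = np.linspace(np.pi - omega_p, np.pi, grid)
    return np.trapezoid(filt.amplitude(w) ** 2, w)


def maxflat_free_taps(K):
    """Closed-form maximal-regularity free taps by direct linear solve."""
    m = np.array([2 * k - 1 for k in range(1, K + 1)], dtype=float)
    A = np.vstack([m ** (2 * j) for j in range(K)])
    d = np.zeros(K)
    d[0] = 0.25
    return np.linalg.solve(A, d)


class TestHalfbandDesign:
    def test_maxflat_length7_closed_form(self):
        h = sw.design_halfband_analysis(L=7, alpha=1.0, gamma=0.0, R=2)
        np.testing.assert_allclose(h.coeffs, MAXFLAT7, atol=1e-12)
        # amplitude and first three derivatives vanish at pi
        eps = 1e-4
        w = np.array([np.pi - 2 * eps, np.pi - eps, np.pi])
        assert abs(h.amplitude(np.array([np.pi]))[0]) < 1e-12
        assert np.all(np.abs(h.amplitude(w)) < 1e-10)

    @pytest.mark.parametrize("L,R", [(7, 2), (11, 3), (15, 2), (19, 3)])
    def test_structural_zeros_exact(self, L, R):
        h = sw.design_halfband_analysis(L=L, R=R)
        assert sw.verify_halfband(h) == 0.0
        assert h.coeffs[h.center] == 0.5

    @pytest.mark.parametrize("L", [7, 11, 15])
    def test_halfband_identity(self, L):
        h = sw.design_halfband_analysis(L=L)
        w = np.linspace(0, np.pi, 4097)
        np.testing.assert_allclose(
            h.amplitude(w) + h.amplitude(np.pi - w), 1.0, atol=1e-12
        )

    @pytest.mark.parametrize("L", [7, 11])
    def test_maximal_regularity_matches_maxflat(self, L):
        K = ((L - 1) // 2 + 1) // 2
        h = sw.design_halfband_analysis(L=L, alpha=1.0, gamma=0.0, R=K)
        np.testing.assert_allclose(h.free_taps, maxflat_free_taps(K), atol=1e-10)

    def test_optimal_beats_maxflat_stopband(self):
        designed = sw.design_halfband_analysis(L=11, omega_p=0.4 * np.pi,
                                               alpha=1.0, gamma=0.0, R=1)
        maxflat = halfband_from_free_taps(maxflat_free_taps(3))
        assert stopband_energy(designed) <= stopband_energy(maxflat) + 1e-12

    def test_optimality_against_grid_search(self):
        """Brute-force oracle: no feasible tap choice on a 0.01 grid beats
        the analytic minimizer of the stopband energy."""
        designed = sw.design_halfband_analysis(L=11, omega_p=0.4 * np.pi,
                                               alpha=1.0, gamma=0.0, R=1)
        best = np.inf
        for a2 in np.arange(-0.15, 0.15, 0.01):
            for a3 in np.arange(-0.15, 0.15, 0.01):
                a1 = 0.25 - a2 - a3  # DC regularity constraint
                cand = halfband_from_free_taps([a1, a2, a3])
                best = min(best, stopband_energy(cand))
        assert stopband_energy(designed) <= best + 1e-9

    def test_stopband_energy_monotone_in_length(self):
        es = [stopband_energy(sw.design_halfband_analysis(L=L, alpha=1.0,
                                                          gamma=0.0, R=2))
              for L in (7, 11, 15, 19)]
        assert all(b <= a + 1e-12 for a, b in zip(es, es[1:]))

    def test_infeasible_regularity_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            sw.design_halfband_analysis(L=7, R=5)

    def test_empty_objective_rejected(self):
        with pytest.raises(ValueError, match="objective"):
            sw.design_halfband_analysis(L=7, alpha=0.0, gamma=0.0)


class TestSynthesisDesign:
    def test_product_filter_is_halfband(self, maxflat_bank):
        p = np.convolve(maxflat_bank.h0.coeffs, maxflat_bank.f0.coeffs)
        d = (len(p) - 1) // 2
        assert p[d] == pytest.approx(1.0, abs=1e-12)
        for k in range(1, d // 2 + 1):
            assert abs(p[d + 2 * k]) < 1e-12

    def test_vanishing_moment_and_symmetry(self, maxflat_bank):
        f0 = maxflat_bank.f0.coeffs
        n = np.arange(len(f0))
        assert abs(np.sum((-1.0) ** n * f0)) < 1e-10
        np.testing.assert_allclose(f0, f0[::-1], atol=1e-14)

    def test_over_constrained_rejected(self):
        h0 = sw.design_halfband_analysis(L=15)
        with pytest.raises(ValueError, match="over-constrained"):
            sw.design_synthesis_lowpass(h0, M=9, V=2)

    def test_default_pair_satisfies_pr(self, default_bank):
        p = np.convolve(default_bank.h0.coeffs, default_bank.f0.coeffs)
        d = (len(p) - 1) // 2
        assert p[d] == pytest.approx(1.0, abs=1e-10)
        for k in range(1, d // 2 + 1):
            assert abs(p[d + 2 * k]) < 1e-10


class TestBankCompletion:
    def test_one_level_roundtrip(self, maxflat_bank, rng):
        x = rng.standard_normal(64)
        a, d = sw.analyze_one_level(x, maxflat_bank)
        xh = sw.transform.synthesize_one_level(a, d, maxflat_bank)
        assert np.linalg.norm(x - xh) / np.linalg.norm(x) < 1e-10

    def test_highpass_signs_alternate(self, maxflat_bank):
        h1 = np.asarray(maxflat_bank.h1)
        f0 = maxflat_bank.f0.coeffs
        np.testing.assert_allclose(h1, ((-1.0) ** np.arange(len(f0))) * f0)

    def test_swapped_roles_still_reconstruct(self, maxflat_bank, rng):
        """Biorthogonal duality: analysis with (f0, f1-side) and synthesis
        with (h0, h1-side) also reconstructs."""
        from types import SimpleNamespace

        from somnowave.transform import analyze_one_level, synthesize_one_level

        b = maxflat_bank
        x = rng.standard_normal(128)
        errors = []
        for sign in (1.0, -1.0):
            h1 = sign * ((-1.0) ** np.arange(len(b.h0))) * b.h0.coeffs
            f1 = ((-1.0) ** np.arange(len(b.f0))) * b.f0.coeffs
            dual = SimpleNamespace(h0=b.f0, h1=h1, f0=b.h0, f1=f1)
            a, d = analyze_one_level(x, dual)
            xh = synthesize_one_level(a, d, dual)
            errors.append(np.linalg.norm(x - xh) / np.linalg.norm(x))
        assert min(errors) < 1e-10

    def test_serialization_roundtrip(self, default_bank):
        text = default_bank.to_json()
        back = sw.WaveletFilterBank.from_json(text)
        np.testing.assert_array_equal(back.h0.coeffs, default_bank.h0.coeffs)
        np.testing.assert_array_equal(back.f0.coeffs, default_bank.f0.coeffs)
        assert back.metadata == default_bank.metadata


class TestDiagnostics:
    def test_verify_halfband_examples(self):
        assert sw.verify_halfband(MAXFLAT7) == 0.0
        assert sw.verify_halfband(np.array([1, 1, 1]) / 3) == pytest.approx(1 / 3)

    def test_vanishing_moments_examples(self):
        assert sw.vanishing_moments(MAXFLAT7) == 4
        assert sw.vanishing_moments(np.array([1, 2, 1]) / 4) == 2
        assert sw.vanishing_moments(np.array([0.0, 1.0, 0.0])) == 0

    def test_tf_localization(self):
        t2, w2, prod = sw.tf_localization(np.array([0.0, 1.0, 0.0]))
        assert t2 == pytest.approx(0.0, abs=1e-15)
        t2, _, prod = sw.tf_localization(np.array([0.5, 0.5]))
        assert t2 == pytest.approx(0.25)
        assert prod >= 0

    def test_zero_filter_rejected(self):
        with pytest.raises(ValueError):
            sw.tf_localization(np.zeros(5))

    def test_cos_product_integral_against_quadrature(self, rng):
        lo, hi = 0.6 * np.pi, np.pi
        w = np.linspace(lo, hi, 200_001)
        for m, n in [(1, 1), (1, 3), (3, 5), (5, 5)]:
            expected = np.trapezoid(np.cos(m * w) * np.cos(n * w), w)
            assert _cos_product_integral(m, n, lo, hi) == pytest.approx(expected, abs=1e-9)


def test_halfband_type_enforces_structure():
    with pytest.raises(ValueError, match="center tap"):
        HalfbandFilter(np.array([0.25, 0.4, 0.25]))
    with pytest.raises(ValueError, match="even offsets"):
        HalfbandFilter(np.array([0.0, 0.1, 0.2, 0.5, 0.2, 0.1, 0.0]))
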