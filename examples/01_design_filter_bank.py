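"""Design an optimal biorthogonal halfband wavelet filter bank.

Builds the default bank (length-15 halfband analysis lowpass, length-25
synthesis lowpass with 2 vanishing moments), then prints the structural
checks that make it a valid wavelet bank: exact halfband zeros, the
halfband amplitude identity, perfect-reconstruction error, and the
time-frequency localization of the analysis filter.
"""

import numpy as np

import somnowave as sw

bank = sw.design_filter_bank(L=15, M=25, R=2, V=2)

print("analysis lowpass h0 (halfband):")
print(np.array2string(bank.h0.coeffs, precision=5, suppress_small=True))
print(f"structural halfband deviation : {sw.verify_halfband(bank.h0):.1e}")

w = np.linspace(0, np.pi, 4097)
identity_dev = np.max(np.abs(bank.h0.amplitude(w) + bank.h0.amplitude(np.pi - w) - 1))
print(f"max |A(w) + A(pi-w) - 1|      : {identity_dev:.2e}")

rng = np.random.default_rng(0)
x = rng.standard_normal(15_360)  # one 30-s epoch at 512 Hz
xr = sw.waverec(sw.wavedec(x, bank, 5), bank)
print(f"5-level reconstruction error  : {np.linalg.norm(x-xr)/np.linalg.norm(x):.2e}")

print(f"vanishing moments of f0       : {sw.vanishing_moments(bank.f0)}")
t2, w2, prod = sw.tf_localization(bank.h0)
print(f"h0 localization sigma_t^2={t2:.3f} samples^2, sigma_w^2={w2:.3f} rad^2, "
      f"product={prod:.3f}")

# A zero structural deviation and ~1e-15 reconstruction error mean the
# bank is exactly halfband and perfectly invertible; the localization
# product quantifies the bandwidth-duration trade-off of the design.
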