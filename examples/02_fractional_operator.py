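"""The complex fractional-order diffusion operator as a spectral multiplier.

Shows the real symbol s(k) = -|k|^alpha cos(beta ln|k|) of the
complex-conjugate fractional Laplacian pair, verifies the classical limit
and an eigenmode identity, and prints the stability bound on the imaginary
order beta for the reference tissue grid.
"""

import numpy as np

from fracatrial.fractional import (FractionalOrder, SpectralGrid, apply_H,
                                   max_stable_beta, spectral_symbol)

grid = SpectralGrid(N=128, dx=0.03215, ndim=2)   # 4.1 cm sheet spacing
k = np.array([0.5, 1.0, 10.0, 50.0])

for order in [FractionalOrder(2.0, 0.0), FractionalOrder(2.0, 0.28),
              FractionalOrder(1.4, 0.28)]:
    print(f"gamma = {order}:  s(k) =",
          np.array2string(spectral_symbol(k, order), precision=3))

print("\nAt k = 1 rad/cm the log-periodic factor vanishes, so s = -1 for")
print("every order; at beta = 0, alpha = 2 the symbol is the classical -k^2.")

# eigenmode check: a periodic sine mode picks up exactly s(k0)
g1 = SpectralGrid(N=128, dx=2.0 / 128)
x = np.arange(128) * g1.dx
k0 = 2 * np.pi * 3 / g1.L
order = FractionalOrder(1.6, 0.2)
out = apply_H(np.sin(k0 * x), g1, order, boundary="periodic")
lam = spectral_symbol(np.array([k0]), order)[0]
print(f"\nsine mode k0 = {k0:.2f} rad/cm: max |H f - s(k0) f| = "
      f"{np.abs(out - lam * np.sin(k0 * x)).max():.2e}")

bmax = max_stable_beta(grid)
print(f"\nstability bound on the sheet grid (rad/cm modes): beta_max = {bmax:.3f}")
print("the published simulations use beta <= 0.28, inside this bound;")
print("beta beyond the bound would make some spectral mode grow.")
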