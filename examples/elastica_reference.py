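"""Zero-temperature Euler elastica: the fluctuation-free baseline.

Force-extension of a hinged elastic rod from the elliptic-integral
solution, cross-checked by brute-force minimization of a 201-segment
discrete rod.
"""

from wlcbuckle import ChainSpec, elastica_extension, euler_force_dimensionless
from wlcbuckle.elastica import discrete_elastica_fixed_f

N = 0.5
chain = ChainSpec.from_dimensionless(N)
fE = euler_force_dimensionless(N)
print(f"N = {N}, Euler force fE = {fE:.4f} kBT/(2lp)\n")
print(f"{'f/fE':>6} {'R/L (elliptic)':>15} {'R/L (discrete)':>15}")
for fr in (0.5, 1.0, 1.2, 1.5, 2.0, 3.0):
    ext = elastica_extension(chain, fr * fE)
    d = discrete_elastica_fixed_f(N, fr * fE)
    print(f"{fr:6.2f} {ext:15.6f} {d['extension']:15.6f}")

# Below fE the rod stays straight (R/L = 1 exactly); above it the
# buckled branch drops continuously (second-order transition). The two
# columns agree to ~1e-4: the elliptic parametrization and an
# independent numerical minimization describe the same shape.
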