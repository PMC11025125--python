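"""Multipole decomposition of a synthetic oriented water slab.

Generates 2e5 SPC/E-template waters whose dipole orientations follow a
sinh-shaped polarization target, bins the dipolar, quadrupolar and
octupolar density profiles, and compares their signed sum with the
exact bound-charge polarization.
"""

import numpy as np

from hydrep import GeneratorSpec, bin_profiles, generate_ordered_slab

spec = GeneratorSpec(n_water=200_000, d=2.0, lam=0.27, h_over_a=-0.228,
                     a=706.0, seed=7)
config = generate_ordered_slab(spec)
profiles = bin_profiles(config, bin_width=0.05)

mmax = np.max(np.abs(profiles.m_bound))
print(f"molecules                  : {config.n_molecules}")
print(f"max |polarization|         : {mmax:.3f} e/nm^2")
for order, label in ((1, "dipole only"), (2, "+ quadrupole"), (3, "+ octupole")):
    err = np.max(np.abs(profiles.composition(order) - profiles.m_bound))
    print(f"truncation at {label:13s}: max deviation {err / mmax:6.1%} of peak")
print(f"rms residual (full sum)    : {profiles.oracle_residual():6.1%} of peak")
print()
print("Each added multipole moment tightens the match to the bound-charge")
print("oracle; the octupole is already a small correction, so the dipole +")
print("quadrupole densities carry nearly all of the water polarization.")
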