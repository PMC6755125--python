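"""Primary SAXS analysis of a globular particle.

Builds a synthetic globular domain (uniform-sphere bead model), computes
its theoretical scattering by the Debye equation, and runs the standard
primary analyses: Guinier fit, dimensionless Kratky plot, P(r) inversion
and the volume-of-correlation molecular weight estimate.
"""

import numpy as np

from saxsemble.saxscalc import (SaxsProfile, debye_profile, guinier_fit,
                                kratky_dimensionless, pr_transform, vc_mw)
from saxsemble.structmodel import radius_of_gyration
from saxsemble.synthetic import default_q_grid, make_toy_complex

topology, sources = make_toy_complex(n_domains=1, domain_radii=(20.0,), seed=7)
domain = sources["D1"]

q = default_q_grid(200)
profile = debye_profile(domain, q, method="exact")
profile = SaxsProfile(profile.q, profile.I, sigma=0.01 * profile.I)

g = guinier_fit(profile)
print(f"coordinate-space Rg : {radius_of_gyration(domain):6.2f} A")
print(f"Guinier Rg          : {g.Rg:6.2f} A   (low-q fit, q*Rg <= 1.3)")

pr = pr_transform(profile, dmax=2 * 20.0 * 1.1)
print(f"P(r) Rg             : {pr.rg():6.2f} A   Dmax = {pr.dmax:.0f} A")

vc, mw = vc_mw(profile, g)
print(f"Vc = {vc:.0f} A^2 -> MW = {mw:.1f} kDa "
      f"(sequence mass {domain.n_atoms * 0.110:.1f} kDa)")

peak = kratky_dimensionless(profile, g.Rg, g.I0).peak()
print(f"dimensionless Kratky peak at (qRg, height) = "
      f"({peak[0]:.2f}, {peak[1]:.2f})")
print("a globular particle peaks near (1.73, 1.10); flexible chains "
      "rise monotonically instead")
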