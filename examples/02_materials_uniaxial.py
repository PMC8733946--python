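"""Evaluate the constitutive models against their closed-form responses.

Prints the uniaxial Cauchy stress of each hyperelastic material at 10%
compression: soft tissue and skin follow the one-term Ogden law (written
with the mu/alpha prefactor), the orthosis and sole foams the Storakers
law.  Negative values are compressive; magnitudes set the stress scale the
plantar tissue experiences in the midstance solution.
"""

import numpy as np

from forefem import materials as M

library = M.MaterialLibrary.defaults()
for region in ("soft_tissue", "skin", "orthosis", "sole"):
    mat = library[region]
    sigma = M.analytic_uniaxial(mat, 0.9)
    print(f"{region:12s}: sigma(lambda=0.9) = {sigma:9.2f} kPa")

# stress and tangent at a general deformation state
F = np.eye(3) + np.array([[0.0, 0.05, 0.0], [0, -0.08, 0], [0, 0, 0.02]])
S, CC = M.stress_and_tangent(library["soft_tissue"], F)
print("\nsoft tissue at a mixed shear/compression state:")
print("  2nd Piola-Kirchhoff stress (kPa):")
print(np.array_str(S, precision=2, suppress_small=True))
print(f"  tangent norm: {np.linalg.norm(CC):.1f} kPa")
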