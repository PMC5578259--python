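"""From a QCM-D trace to film mass and monolayer packing.

Simulates a rigid-film adsorption trace with a known areal mass, reduces
it with the Sauerbrey relation, converts to an area per protein, and
compares that footprint with the protein's cross-section.
"""

import numpy as np

from filmcharge import area_per_protein, gyration_analysis, packing_comparison, reduce_trace
from filmcharge.synthetic import make_ellipsoid_cloud, make_qcm_trace

# beta-lactoglobulin-like film: 2.1 mg/m2, 18.4 kDa, nearly spherical protein
trace = make_qcm_trace(mf_target=2.1, seed=1)
est = reduce_trace(trace, C=18.0)
ap = area_per_protein(est.areal_mass, Mw=18.4)

axes = tuple(np.sqrt(5 * np.array([1.6, 1.5, 1.4])))
protein = gyration_analysis(make_ellipsoid_cloud(axes, 20_000, seed=2))
packing = packing_comparison(protein, ap, orientation="flat")

print(f"areal mass      = {est.areal_mass:.2f} mg/m2 (rigid: {est.rigid})")
print(f"area/protein    = {ap:.1f} nm2")
print(f"cross-section   = {packing.cross_section:.1f} nm2")
print(f"ratio ac/ap     = {packing.ratio:.2f} -> {packing.verdict}")
# ratio ~ 1 means the proteins tile the surface almost without interstices.
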