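"""Protein net charge versus pH and the isoelectric point.

Titrates a composition-matched synthetic sequence with the intrinsic-pKa
Henderson-Hasselbalch model and prints the charge at a few pH values and
the pH at which it vanishes (pI).
"""

from filmcharge import charge_curve, sites_from_sequence
from filmcharge.synthetic import synthetic_sequence

seq = synthetic_sequence("beta_lactoglobulin_like", seed=1)
curve = charge_curve(sites_from_sequence(seq))

for ph in (3.0, 5.0, 7.0, 9.0):
    print(f"Q(pH {ph:.0f}) = {curve.charge_at(ph):+6.1f} e")
print(f"pI       = {curve.pI:.2f}")
# Positive below the pI, negative above; the pI is the zero crossing.
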