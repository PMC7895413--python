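"""Short-term synaptic dynamics: depression, facilitation, failures.

Drives the three synapse classes with a 40 Hz regular presynaptic train and
prints the amplitude factor of each successive PSP.  Strongly depressing
synapses lose about half of their amplitude by the eighth spike; the
facilitating RS→SOM class instead grows several-fold even after accounting
for its activity-dependent transmission-failure rate (which starts at 50%
and improves with use).
"""

import numpy as np

from nanostim.params import (FACILITATING, STRONG_DEPRESSION, WEAK_DEPRESSION)
from nanostim.plasticity import depression_factors, facilitation_factors

t = np.arange(8) * 25.0  # 40 Hz regular train

strong = depression_factors(t, STRONG_DEPRESSION)
weak = depression_factors(t, WEAK_DEPRESSION)
facil, p_fail = facilitation_factors(t, FACILITATING, mean_failures=True)

print("PSP amplitude factors along a 40 Hz train (relative to a rested synapse)")
print(f"{'spike':>5} {'strong dep.':>12} {'weak dep.':>10} "
      f"{'RS->SOM (incl. failures)':>25} {'failure rate':>13}")
for j in range(8):
    print(f"{j + 1:>5} {strong[j]:>12.3f} {weak[j]:>10.3f} "
          f"{facil[j]:>25.3f} {p_fail[j]:>13.2f}")

print(f"\n8th/1st strong-depression ratio: {strong[7] / strong[0]:.2f} "
      "(about one half)")
print(f"8th/1st facilitating ratio:      {facil[7] / facil[0]:.1f} "
      "(net amplification despite depression and failures)")
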