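"""Screen tendon anchor routings by excursion over the fold sweep.

Sweeps the elbow drive from extension to flexion, computes the straight-line
anchor-to-anchor length of each candidate biceps/triceps routing, and flags
those whose fully-folded excursion lies in the 10-20 mm band a micro linear
actuator can serve.
"""

import numpy as np

from wingkin import check_actuation_limits, default_geometry, tendon_excursion
from wingkin.mechanism import default_routings

geometry = default_geometry()
angles = np.arange(0.0, 38.83 + 1e-9, 1.0)  # extension -> flexion drive sweep

tables = {r.name: tendon_excursion(geometry, r, angles)
          for r in default_routings(geometry)}
selection = check_actuation_limits(tables, band_mm=(10.0, 20.0))
print(selection.to_string(index=False))

# Biceps-analog excursions are positive and triceps-analog negative (an
# antagonist pair); the largest displacement always occurs fully folded.
# Routings flagged within_band suit a 10-20 mm stroke actuator — the
# middle options (II-ii, B-b) land inside the band.
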