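"""Build a synthetic study region and a virtual species with a known niche.

Prints the realized prevalence (mean suitability over land) and how
concentrated the core habitat is — the ground truth every later stage is
judged against.
"""

import numpy as np

from _common import build_study_system
from shaderange import true_suitability

grid, env, species = build_study_system()

suit = true_suitability(species, env)
land = env.land_mask
print(f"grid: {grid.n_rows}x{grid.n_cols} cells, {land.sum()} on land")
print(f"mean suitability over land: {np.nanmean(suit[land]):.3f} "
      f"(prevalence target {species.prevalence_target})")
print(f"peak suitability: {np.nanmax(suit):.3f}; "
      f"cells above half the peak: {(suit[land] > np.nanmax(suit) / 2).sum()}")
# the numbers say how common the species is and how concentrated its core
# habitat is; downstream models must rediscover this surface from samples
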