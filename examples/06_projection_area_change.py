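"""Project a fitted ensemble under a warming/drying scenario and account
the change in suitable area, with and without the land-cover constraint.

Two GCM variants of the same SSP x period are averaged cellwise before
binarizing at the threshold fitted on current conditions.
"""

from _common import build_study_system
from shaderange import (
    ScenarioShift,
    aggregate_gcms,
    apply_scenario,
    area_change,
    binarize,
    fit_ensemble,
    generate_landcover,
    predict_map,
    sample_occurrences,
    sample_pseudoabsences,
)
from shaderange.pipeline import extract_training_set

grid, env, species = build_study_system()
occ = sample_occurrences(species, env, n_clean=200, seed=5)
pa = sample_pseudoabsences(occ["lon"].to_numpy(), occ["lat"].to_numpy(), env,
                           n=500, buffer_km=500.0, seed=5)
ts = extract_training_set(species.species_id, occ["lon"].to_numpy(),
                          occ["lat"].to_numpy(), pa, env, env.layer_names,
                          k=4, seed=5)
model = fit_ensemble(ts, seed=5, hyperparams={"GBM": {"n_estimators": 400},
                                              "RF": {"n_estimators": 300}})

current = predict_map(model, env, scenario="current")
gcm_maps = []
for g, d_t in ((1, 1.8), (2, 2.3)):  # GCM-specific warming, shared drying
    future_env = apply_scenario(env, ScenarioShift(
        f"SSP585_2041-2060_GCM{g}",
        offsets={"BIO1": d_t}, factors={"BIO12": 0.9}))
    gcm_maps.append(predict_map(model, future_env, scenario=f"GCM{g}"))
future = aggregate_gcms(gcm_maps, scenario="SSP585_2041-2060")

cur_bin = binarize(current, model.threshold)
fut_bin = binarize(future, model.threshold)
landcover = generate_landcover(grid, {
    "forest": 0.4, "shrubs": 0.2, "grassland": 0.15, "cropland": 0.15,
    "sparse_vegetation": 0.1}, seed=6)

s = area_change(cur_bin, fut_bin, landcover=landcover,
                study_area_mask=env.land_mask)
print(f"current suitable area: {s.current_km2:,.0f} km^2 "
      f"({s.pct_of_study_area_current:.1f}% of the study area)")
print(f"future suitable area:  {s.future_km2:,.0f} km^2 "
      f"({s.pct_change:+.1f}% vs current)")
print(f"under the agroforestry land-cover mask: {s.masked_current_km2:,.0f} -> "
      f"{s.masked_future_km2:,.0f} km^2 ({s.masked_pct_change:+.1f}%)")
# warming + drying pushes cells away from the species' optimum, so the
# suitable area typically contracts; the mask restricts to classes where
# agroforestry can expand without deforestation
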