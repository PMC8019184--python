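"""Compare sampling designs: single areas vs spread-out site grids.

Runs small versions of the two basic marking regimes and prints the mean
bias of the sampled Mantel score against two references: the zone truth
(everyone inside the spatial extent of sampling) and the global truth
(the whole population).  Area sampling is unbiased for its own zone but
underestimates the population score; spaced-out site grids overestimate
even the zone score.
"""

from migconn import run_area_experiment, run_spread_experiment, summarize_replicates

common = dict(master_seed=0, n_replicates=25, connectivity={"low": 7.0})

print("=== single-area designs (increasing area size) ===")
area = summarize_replicates(run_area_experiment(**common))
print(area[["level", "mean_r", "mean_bias_zone", "mean_bias_global"]]
      .to_string(index=False, float_format="%+.3f"))

print("\n=== nine-site 3x3 grids (increasing spread) ===")
spread = summarize_replicates(run_spread_experiment(**common))
print(spread[["level", "mean_r", "mean_bias_zone", "mean_bias_global"]]
      .to_string(index=False, float_format="%+.3f"))

print(
    "\nbias_zone ~ 0 for areas (random sampling matches its zone), but"
    "\nbias_global < 0: a spatial subset underestimates the whole population."
    "\nFor spread grids bias_zone grows positive with spacing: the gaps"
    "\nbetween sites oversample large breeding pairwise distances."
)
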