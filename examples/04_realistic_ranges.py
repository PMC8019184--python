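"""Build a realistic clustered population over a bundled range polygon.

Loads the 'compact' synthetic range pair, simulates a spatially
autocorrelated density surface (Gaussian random field), scatters
individuals in proportion to it, links the seasons by longitudinal-rank
matching at three bandwidths, and shows how the chosen bandwidth sets the
population's true connectivity.
"""

from migconn import (
    GaussianFieldParams,
    RankMatchParams,
    build_realistic_population,
    global_truth_score,
    load_fixture,
)

breeding, nonbreeding = load_fixture("compact")
print(f"breeding range area: {breeding.geometry.area/1e6:.1f} million square map units; "
      f"bbox {tuple(round(v) for v in breeding.geometry.bounds)}")

N = 5000  # scaled down from the study-scale 50,000
for bandwidth in (100, 1300, 2500):  # keeps the full-scale bandwidth:n ratios
    pop = build_realistic_population(
        breeding, nonbreeding,
        GaussianFieldParams(seed=3),
        N,
        RankMatchParams(bandwidth, seed=4),
    )
    r = global_truth_score(pop)
    print(f"bandwidth {bandwidth:>5} ranks -> whole-population r = {r:.3f}")

print(
    "\nA narrow rank window forces west-to-west / east-to-east season"
    "\npairings (high connectivity); a window as wide as the population"
    "\ngives a random shuffle and the correlation collapses."
)
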