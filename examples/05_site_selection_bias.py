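"""How the number and spacing of discrete study sites drives bias.

Reproduces the k-of-20 site experiment on the 'wide' range fixture at a
reduced scale: the 20 highest-density grid cells form a site pool, each
replicate study picks k sites at random and tracks 200 individuals from
them.  With few sites, estimates swing wildly - underestimating when the
chosen sites happen to lie close together and overestimating when they are
far apart.
"""

import numpy as np

from migconn import run_realistic_experiment

rec = run_realistic_experiment(
    "wide",
    master_seed=0,
    n=8000,
    bandwidths={"medium": 2000},
    ks=(3, 5, 10, 20),
    n_replicates=20,
)

r_global = rec.r_global.iloc[0]
print(f"whole-population r = {r_global:.3f}\n")
print("k sites   mean r   SD of r   corr(bias, site spacing)")
for k, sub in rec.groupby("k_sites"):
    rho = np.corrcoef(sub.bias_global, sub.site_centroid_mean_dist)[0, 1]
    print(f"{k:>7}   {sub.r_sample.mean():+.3f}   {sub.r_sample.std(ddof=1):.3f}     {rho:+.2f}")

print(
    "\nMore sites shrink the replicate spread; with k <= 5 the sign of the"
    "\nerror is largely set by how far apart the selected sites are."
)
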