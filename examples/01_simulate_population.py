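"""Simulate migratory populations and score their true connectivity.

Builds one population per connectivity strength on the default geometry
(5600 x 5600 breeding square, 11,200-unit southward migration) and prints
the whole-population Mantel correlation: the Pearson correlation between
breeding and non-breeding pairwise distances over every individual.
"""

from migconn import CONNECTIVITY_MEANLOG, global_truth_score
from migconn.experiments import make_population

N = 3000  # scaled down from the default 10,000 so this runs in seconds

for name, meanlog in CONNECTIVITY_MEANLOG.items():
    pop = make_population(N, meanlog, seed=1)
    r = global_truth_score(pop)
    print(f"{name:>6} connectivity (displacement meanlog {meanlog}): r = {r:.3f}")

print(
    "\nSmaller random displacements keep neighbours together across seasons,"
    "\nso the Mantel correlation falls as the displacement scale grows."
)
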