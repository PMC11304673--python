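"""Discover CMC patterns: k-means + average silhouette + labeling rules.

The number of clusters is chosen by maximising the mean silhouette over
k = 2..8; discovered clusters are profiled (incidence, onset timing,
ordered trajectories) and named by precedence rules on the first
disease and its onset window.
"""

from cmcpatterns import (
    fit_clusters,
    generate_cohort,
    label_clusters,
    profile_clusters,
    select_k,
    stratum_config,
)
from cmcpatterns.trajectory import frame_to_trajectories

_, trajectories, truth = generate_cohort(stratum_config("elsa", "male", n=3000, seed=5))

k_star, table = select_k(trajectories, range(2, 9), seed=0)
print(table.round(3).to_string(index=False))
print(f"silhouette-optimal k = {k_star}")

model = fit_clusters(trajectories, k_star, seed=0)
trajs = frame_to_trajectories(trajectories)
profiles = profile_clusters(model, trajs)
labels = label_clusters(profiles, trajs, assignments=model.assignments)

for p in profiles:
    top = p.pattern_counts.iloc[0]
    print(
        f"cluster {p.cluster} -> {labels[p.cluster]:<9} n={p.n:<5} "
        f"HYP {p.incidence_pct['HYP']:.0f}% / DM {p.incidence_pct['DM']:.0f}% / "
        f"HD {p.incidence_pct['HD']:.0f}%  most frequent: {top['pattern']} "
        f"({top['pct']:.0f}%)"
    )
# each line: which diseases the cluster's members develop, and the
# dominant ordered trajectory that earned the cluster its name
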