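"""Resolve microglial signaling states by two-round Leiden clustering and
follow their abundance over the time course.

Cells are drawn from four planted signaling archetypes whose prevalences
shift over 48 h of LPS: a baseline-low state, an early MAPK burst
(pERK/pp38/pRSK/pCREB-high, 73% of cells at 15 min), a mid pSTAT1 state,
and a late CD40/CD86 reactive state.  Round 1 clusters on identity
markers and drops non-microglia; round 2 clusters on the remaining
markers and is annotated by z-score hi/lo calls.
"""

import warnings

warnings.filterwarnings("ignore")

from cytoglia import (
    abundance_trajectories,
    rmse_baseline_return,
    simulate_signaling_states,
    two_round_clustering,
)

table, truth = simulate_signaling_states("LPS", "microglia_only",
                                         n_per_sample=200, seed=42)
model = two_round_clustering(table, target_band=(3, 6), seed=0)

print(f"round-1 identity clusters: {model.round1_labels.max()} "
      f"(excluded as non-microglia: {model.excluded_clusters or 'none'})")
labels = model.round2_labels
print(f"round-2 signaling clusters: {int(labels[model.retained_index].max())}")

print("\nhi/lo annotations (selected markers):")
cols = ["pERK", "pp38", "pSTAT1", "CD40", "CD86"]
print(model.annotations[cols].to_string())

traj = abundance_trajectories(labels, table.annotations)
print("\ncluster ordering by abundance-weighted mean time (1 = earliest):")
print(traj.ordering.to_string())
print("\ncluster fractions at selected times:")
print(traj.fractions["LPS"][[0.0, 0.25, 2.0, 48.0]].round(3).to_string())

rmse = rmse_baseline_return(traj, "LPS")
print(f"\nbaseline-return RMSE (48 h vs 0 h): {rmse:.3f}")

# The cluster annotated pERK-hi/pp38-hi dominates at 15 min, the
# pSTAT1-hi cluster at 2 h, and the CD40/CD86-hi cluster at 24-48 h,
# reproducing the MAPK -> pSTAT1 -> CD40/CD86 trajectory; the RMSE
# measures how far the 48 h cluster composition remains from baseline.
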