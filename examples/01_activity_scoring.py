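"""Score regulon activity per cell and check the planted state structure.

Builds a small synthetic dataset with three terminal hepatocyte-like states
(fate0/fate1/fate2) and 18 regulons, 4 of which per state are planted as
state-specific, then scores every regulon with the rank-based recovery-curve
AUC and prints how cleanly a planted regulon separates its home state.
"""

from regfate import SyntheticDesign, generate_single_cell_dataset, score_gene_sets

design = SyntheticDesign(n_cells=600, n_genes=500, n_regulons=18,
                         n_state_specific_per_state=4,
                         regulon_size_range=(8, 15), activity_noise_sd=0.0, seed=1)
expression, cells, regulons, truth = generate_single_cell_dataset(design)
activity = score_gene_sets(expression, regulons, top_fraction=0.05, seed=1)

print(f"activity matrix: {activity.shape[0]} cells x {activity.shape[1]} regulons, "
      f"values in [{activity.min().min():.3f}, {activity.max().max():.3f}]")
for state, tfs in truth.state_specific_regulons.items():
    tf = tfs[0]
    home = activity.loc[(cells["state"] == state).values, tf]
    away = activity.loc[(cells["state"] != state).values, tf]
    print(f"{tf} (planted for {state}): mean AUC {home.mean():.3f} at home "
          f"vs {away.mean():.3f} elsewhere")
# A planted regulon's AUC is high only where its targets are co-upregulated:
# the home/elsewhere gap is the signal every downstream stage builds on.
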