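"""Group inference: Welch real-vs-pseudo test with permutation cluster FWE.

The voxelwise Welch t compares real-pair against pseudo-pair Fisher-z
maps (unequal variances, Satterthwaite df); clusters above the p < 0.001
height threshold are corrected by the permutation distribution of the
maximum cluster size.
"""

import numpy as np

import dyadsync as ds

shape = (12, 12, 12)
truth = ds.default_ground_truth(shape, n_mask_voxels=27,
                                coupling_task=0.6, coupling_residual=0.0)
cohort = ds.simulate_cohort(n_pairs=6, truth=truth, seed=4,
                            n_volumes=96, n_trials_per_run=16)

table, tmap, real_z, pseudo_z = ds.real_vs_pseudo_cluster_test(
    cohort.series_by_pair("beta_series"), shape, n_perm=200, seed=5)

print("clusters above the height threshold (sorted by size):")
print(table.clusters.to_string(index=False))
sig = table.significant()
print(f"\n{len(sig)} cluster(s) significant at FWE p <= 0.05")
if len(sig):
    peak = tuple(int(sig.iloc[0][k]) for k in ("peak_i", "peak_j", "peak_k"))
    print(f"peak voxel {peak} inside the coupled ground-truth mask: "
          f"{bool(truth.task_sync_mask[peak])}")
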