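"""Functional gradients: voxel-wise FC, group PCA, and ROI localization.

Builds each subject's voxel-to-voxel Pearson FC matrix, vectorizes the
upper triangle, stacks profiles into the connections x subjects group
matrix, estimates the top-10 gradients, and localizes the strongest 5% of
one gradient's connection loadings to ROIs.
"""

import numpy as np

import cerebgrad as cg

config = cg.CohortConfig(n_subjects=40, n_voxels=80, n_volumes=120, seed=3)
records, bolds, motions, volumes, truth = cg.generate_cohort(config)

vectors = [cg.vectorize_upper(cg.fc_matrix(b), subject_id=b.subject_id) for b in bolds]
group = cg.assemble_group_matrix(vectors)
print(f"Group matrix: {group.n_connections} connections x {group.n_subjects} subjects")

model = cg.fit_group_pca(group, k=10)
print(f"Top-10 gradients explain {100 * cg.variance_explained(model, 10):.1f}% "
      f"of FC-profile variance; per-component %:",
      np.round(100 * model.variance_fraction[:10], 1).tolist())

# which gradient tracks the planted latent source?
planted = truth.subject_strengths[:, config.coupled_source_index]
cors = [abs(np.corrcoef(model.coefficients[k], planted)[0, 1]) for k in range(10)]
best = int(np.argmax(cors))
print(f"Gradient {best + 1} coefficients correlate |r|={max(cors):.2f} with the "
      "planted source strengths (ground-truth recovery).")

report = cg.top_loading_clusters(model, component=best, labels=truth.roi_assignment)
print(f"\nTop 5% strongest connections of gradient {best + 1} "
      f"({report.n_selected} connections) localize to:")
print(report.roi_ranking.head(4).to_string(index=False))
print("Incidence counts how often each ROI's voxels participate in the "
      "selected connections; the planted source's home regions should rank first.")
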