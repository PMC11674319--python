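"""Estimate connectome gradients from a group functional connectome.

Subject correlation matrices are Fisher z-transformed and averaged, the
group matrix is sparsified to its top 10% entries per row, converted to
a normalized-angle affinity, and embedded with a diffusion map. G1-G3
are the smooth axes along which connectivity profiles vary; the
eigenvalues say how much affinity structure each axis carries.
"""

import numpy as np

import conngrad as cg

scheme = cg.make_parcellation(100, 7, 4, seed=0)
truth = cg.make_ground_truth(scheme, n_affected=0, seed=0)
study, _ = cg.simulate_fc_cohort(scheme, 15, 15, truth)

group_fc = cg.group_average_fc([cg.fisher_z(r.fc) for r in study])
gradients = cg.embed_functional(group_fc)

print(f"gradient matrix: {gradients.components.shape} (parcels x k)")
print("eigenvalues:        ", np.round(gradients.eigenvalues, 4))
print("variance explained: ", np.round(gradients.variance_explained, 4))
print(f"G1-G3 jointly carry {100 * gradients.variance_explained.sum():.1f}% "
      "of the positive non-trivial spectrum")

# G1 should track the dominant latent axis the generator planted
r = np.corrcoef(gradients.components[:, 0], truth.latent_coords[:, 0])[0, 1]
print(f"|corr(G1, first latent axis)| = {abs(r):.3f} "
      "(the embedding recovers the planted principal axis)")
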