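# conngrad

Connectome gradient templates: construction, alignment, and between-group
inference — with a fully synthetic multi-site cohort generator so the whole
pipeline is testable end to end.

## The problem

Gradient analyses summarize a brain's parcellated connectome by a few smooth
eigen-axes ("gradients" G1, G2, G3) of a connectivity-derived affinity
operator. To compare individuals — say, a clinical group against controls —
every subject's gradients must first be rotated onto a common **group-level
template**, and there is no consensus on which template to use: one built
from the study cohort itself (cases + controls, controls only, cases only),
one from an independent normative dataset, or a study template re-anchored
onto the normative one. The choice changes the measured group effects, so it
matters for anyone hunting connectome biomarkers.

`conngrad` implements that whole comparison as a reusable library for
methodologists and applied researchers working with parcellated functional
(FC) or structural (SC) connectivity:

* **Connectome construction** — Pearson FC from parcel time series, Fisher
  r-to-z, group averaging; log-transformed streamline-count SC with
  distance-dependent consensus group thresholding.
* **Gradient estimation** — top 10%-per-row sparsification, normalized-angle
  (or cosine) affinity, diffusion map embedding
  (`W'_ij = W_ij / (d_i^α d_j^α)`, α = 0.5; components scaled by
  λ/(1−λ)); structural connectomes embedded per hemisphere and merged over
  homologous parcels.
* **Templates and alignment** — the six construction strategies above;
  orthogonal Procrustes rotation `R = argmin_R ‖S·R − T‖_F` (no centering,
  no scaling) for template-to-template and subject-to-template alignment.
* **Inference** — per parcel, the multivariate linear model
  `Y = intercept + group + age + sex + site` on the three aligned gradients,
  tested with Hotelling's T²
  (`F = T²(ν−q+1)/(νq) ~ F(q, ν−q+1)`), Benjamini–Hochberg FDR across
  parcels, spin permutation tests for map similarity, community/hierarchy
  stratification, and cross-validated classification/prediction to gauge
  template utility.
* **Synthetic cohorts** — a latent-manifold factor model with known ground
  truth: smooth gradient structure, a planted group effect in known parcels,
  multi-site offsets, and an independent higher-quality reference cohort.

## Worked example

```python
import numpy as np, pandas as pd
import conngrad as cg

scheme = cg.make_parcellation(100, 7, 4, seed=3)
truth = cg.make_ground_truth(scheme, n_affected=10, effect_size=1.0, seed=3)
study, _ = cg.simulate_fc_cohort(scheme, 30, 30, truth)

template = cg.build_template(study, cg.TemplateSpec(1), scheme=scheme)
grads = [cg.embed_functional(cg.fisher_z(r.fc)) for r in study]
aligned = np.stack([g.components for g in cg.align_cohort(grads, template)])

cov = pd.DataFrame({"group": [r.group for r in study],
                    "age": [r.age for r in study],
                    "sex": [r.sex for r in study],
                    "site": [r.site for r in study]})
effects = cg.fit_mglm(aligned, cov)
print(cg.summarize_template(effects))
```

Running this (it is `examples/04_group_inference.py`) prints

```
mean T2 = 6.38 +/- 9.00, 11 significant parcels at q < 0.05
planted parcels recovered: 9/10; false positives: 2
```

— the multivariate test recovers 9 of the 10 parcels that carry the planted
gradient perturbation, with 2 false detections at q < 0.05. The other
scripts in `examples/` walk through each capability (simulation, embedding,
the six templates, spin tests, the structural path, template utility), each
printing the numbers it computes and what they mean.

A thin CLI mirrors the pipeline stages for shell use:

```bash
conngrad simulate --out cohort --seed 0
conngrad run --out experiment --seed 0      # full experiment, all strategies
```

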