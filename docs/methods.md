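# Methods

This note documents the models, conventions and design decisions behind
`conngrad`, in the spirit of a statistical software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Connectome construction

**Functional.** Subject FC is the Pearson correlation of parcellated time
series (constant series are a hard error naming the parcel). Correlations
are Fisher r-to-z transformed per subject; the group matrix is the
elementwise mean of subject z-matrices. Two conventions keep the transform
total: the diagonal (r = 1, arctanh divergent) is set to 0 — downstream
kernels ignore self-similarity — and off-diagonal |r| = 1, which short
synthetic series can produce, is clipped to ±(1 − 1e−7) with a logged
warning rather than raising.

**Structural.** Subject SC is a non-negative streamline-count matrix,
transformed by log(1 + x): log1p keeps absent edges at exactly zero and
preserves edge ranking, and raw counts contain zeros so a plain log would
need an arbitrary offset. The group SC uses distance-dependent consensus
thresholding: candidate edges (present in ≥ 1 subject) are binned by
inter-centroid great-circle distance into `n_bins = 10` equal-count
(quantile) bins, intra- and inter-hemispheric edges binned separately;
within each bin the K most frequently present edges are kept, with
K = round(mean per-subject count of present edges in the bin), ties broken
by higher mean nonzero weight then lower parcel-index pair (fully
deterministic, hence bit-reproducible); retained edges carry the mean of
the nonzero subject weights. Consensus runs on raw counts and the log
transform is applied afterwards. Per-bin density conservation
(|retained| = K exactly) is asserted in tests. At very small problem sizes
(≲ 80 parcels with ≲ 10 subjects) the consensus can leave a parcel without
intra-hemispheric edges; the embedding then raises a degenerate-input
error naming the parcel — at the intended scale (≥ 100 parcels, ≥ 10
subjects) this does not occur in our simulations.

## 2. Gradient estimation

The functional pathway is: retain the top `ceil(density · (p − 1))`
off-diagonal entries per row (default density 0.10; ranking by value,
negatives included; ties to the lower column index; output may be
asymmetric — symmetry returns via the kernel, which compares row
profiles), then the normalized-angle affinity
`a_ij = 1 − arccos(cos_sim(row_i, row_j))/π ∈ [0, 1]`, then a diffusion
map. A cosine kernel is available for sensitivity analyses; its negative
values are floored at 0 because the diffusion operator requires
non-negative affinities (the same rationale that motivates the normalized
angle in the first place).

The diffusion map density-normalizes `W'_ij = W_ij/(d_i^α d_j^α)` with
α = 0.5 (anisotropic normalization — the common default in connectome
gradient toolboxes; config-exposed), row-normalizes to a Markov operator,
and eigendecomposes through the symmetric conjugate
`S = D'^{-1/2} W' D'^{-1/2}` (dense `eigh`; problem sizes are a few
hundred parcels). The trivial constant eigenvector (λ = 1) is dropped and
component i is eigenvector i+1 scaled by λ/(1−λ) — the "automatic
diffusion time" convention, integrating over all diffusion scales.
Eigenvector signs are arbitrary, so a deterministic convention (largest
|element| positive; idempotent) makes templates reproducible.
`variance_explained_i = λ_i / Σ(positive non-trivial λ)`; note this
denominator convention matters — summing over a fixed small number of
components instead would roughly double the reported percentages, and
published "variance explained" figures do not always state their
denominator. Disconnected affinity graphs are a hard error naming the
component sizes.

**Structural embedding** is hemisphere-separate (streamline counts are
dominated by intra-hemispheric edges and lateralized): each
intra-hemispheric block is embedded with no extra thresholding (the
matrix is already sparse), then the right-hemisphere gradients are
rotated onto the left by orthogonal Procrustes over homologous parcel
pairs and the blocks are concatenated. Without a homologue map the code
falls back to eigenvalue-order matching with a logged warning.
A consequence of anchoring right onto left: hemisphere flipping commutes
with embedding only up to a common k×k orthogonal transform (flipping
swaps which hemisphere anchors the merge); tests assert exact commutation
after one Procrustes alignment. For hemisphere-symmetric matrices the
transform is the identity up to signs.

## 3. Templates and alignment

Six template strategies: (1) study cases + controls, (2) study controls,
(3) study cases, (4) the independent reference cohort, (5) strategy 1
rotated onto strategy 4, (6) strategy 2 rotated onto strategy 4.
Sex-specific variants are parameterizations of 4/5 with a filtered
reference cohort, not separate code paths. Procrustes is solved in closed
form from the SVD of `SᵀT` over the full orthogonal group — reflections
allowed, no centering, no scaling — because gradient magnitudes are
compared across groups downstream and must be preserved. Alignment uses
exactly k = 3 components (config-exposed). Subjects are aligned to the
rotated template itself for strategies 5/6.

**An invariance worth knowing.** Hotelling's T² is invariant under any
common invertible transform of the response. Since the strategy-5
template is the strategy-1 template times an orthogonal matrix R, and the
Procrustes solution for each subject then differs by exactly that R, the
aligned cohorts differ by a common rotation — so per-parcel T² under
strategy 5 equals strategy 1 to machine precision. The same holds for 6
vs 2. Differences between template strategies can therefore only arise
from templates that differ in *shape* (1 vs 2 vs 3 vs 4), not from the
reference-alignment rotation; in the synthetic experiments the
strategy-5-vs-1 comparison is an equality, and the test suite checks the
"not weaker" direction that this implies.

## 4. Inference

Per parcel, the 3-gradient response is fit by multivariate least squares
on `intercept + group (0/1) + age + sex (0/1) + site` (one-hot, first
level dropped; the dropped level provably does not affect p-values, and a
test asserts it). With residual crossproduct `E`, ν = n − rank(X),
`Σ̂ = EᵀE/ν` and group contrast c:

    T² = (cᵀB)ᵀ Σ̂⁻¹ (cᵀB) / (cᵀ(XᵀX)⁻¹c),
    F  = T² (ν − q + 1)/(νq) ~ F(q, ν − q + 1),  q = 3.

For q = 1 with no covariates this reduces exactly to the squared pooled
two-sample t (the guard test). FDR is Benjamini–Hochberg at q < 0.05
(the threshold and a relaxed 0.1 variant are config-exposed); the
implementation delegates to `statsmodels.multipletests` and is checked
against a from-definition step-up oracle. Motion (framewise-displacement
analogue) is supported as an optional design column, default off.

**Spin test.** Map similarity is tested against a spatial null: per
permutation a uniform random rotation (QR of a Gaussian matrix, det
corrected to +1) is applied to left-hemisphere centroids and its mirror
conjugate `M R M` (M = diag(−1,1,1)) to the right; parcels are reassigned
within hemisphere. The default reassignment solves the optimal one-to-one
matching (Hungarian algorithm on the rotated-to-original cosine
alignments), so every null map is an exact permutation and value
multisets are preserved per hemisphere. The classical nearest-neighbour
reassignment (which can duplicate values but tracks the rotation more
faithfully) is config-exposed; in our calibration runs the permutation
variant is mildly anticonservative for very smooth maps (rejection rate
≈ 0.09 at nominal 0.05 for maps with 0.3 rad correlation length) while
nearest-neighbour is closer to nominal — the trade-off between exact
exchangeability of values and fidelity of the spatial null is inherent to
parcel-level spin tests. p-values are two-sided with the add-one
estimator `p = (1 + #{|r_null| ≥ |r_obs|})/(n_perm + 1)`.

## 5. The synthetic cohort generator

The generator defines the study conditions for every end-to-end test, so
its assumptions matter.

**Latent manifold.** Each parcel sits at a 3-D latent position: low-order
smooth functions of its spherical centroid — (z, y, x² − y²) —
standardized and scaled by (1.0, 0.5, 0.3). The anisotropy makes the
first gradient dominant (as in real connectomes) and, equally
importantly, keeps the embedding's eigenvectors identifiable: with
isotropic scales the three non-trivial eigenvalues are nearly degenerate
and subject-level gradients mix arbitrarily. All three functions are
mirror-symmetric, so homologous parcels share latent coordinates.

**Loadings.** A parcel's factor loadings are a Gaussian radial-basis
function of its latent position (25 k-means centers over the latent
cloud, bandwidth 0.8 latent units), row-normalized to constant overall
connectivity strength and scaled by gain 1.5 against unit scanner noise.
Local profiles mean that moving one parcel changes *its* connectivity
fingerprint without re-wiring everyone else — which is what lets a
planted effect stay localized in gradient space. The implied correlation
matrix `corr(AAᵀ + σ²I)` is a valid correlation matrix by construction,
with no positive-semidefinite projection step.

**Planted effect.** Case subjects have the affected parcels' latent
position shifted along the first axis by `effect_size` × SD(axis 1),
oriented toward the manifold interior — the "gradient contraction"
pattern reported in clinical cohorts. The interior orientation is not
cosmetic: a shift off the manifold's support saturates the radial-basis
profile and makes the perturbation invisible to any method. The effect
therefore propagates through FC → thresholding → affinity → embedding →
alignment → inference, making end-to-end recovery a genuine test rather
than a painted-on gradient difference.

**Noise structure.** Subjects jitter around the group latent positions
(SD 0.6 of the principal-axis SD — calibrated so individual aligned
gradients correlate with the group template at ≈ 0.8, the mid-range of
reported individual-gradient reliability); time series are
`A_s f + ε` with 200 timepoints (a typical resting-state run) and unit
noise; sites add small offsets in loading space (SD 0.1, rank-one per
site — variability across sites is documented in multi-site studies but
no quantitative generative model is established, so this default is a
placeholder and config-exposed). Covariates (age, sex, site, motion) are
drawn independently of group, so the GLM's adjustments are exercised
without confounding.

**Structural generator.** Edges exist with probability exp(−d/λ) in
great-circle distance (λ = 0.65, giving ≈ 15% density at 100–200
parcels, comparable to tractography matrices); log-normal weights
decrease with distance and increase with latent-profile similarity; case
subjects multiply weights on edges incident to affected parcels by
exp(effect_size · δ), δ = 0.1.

**Reference cohort.** Control-only, sharing the latent manifold and
loading map, with series length ×4 and noise ÷4 (quality factor 4) and no
study-site offsets — a stand-in for a large normative dataset with a
superior acquisition. Note one scale subtlety: lower noise de-attenuates
correlations, so the reference's *raw* FC dispersion across subjects is
larger even though its *relative* (scale-normalized) dispersion is
smaller; comparisons of cohort variability should be scale-free.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: hemodynamics and temporal autocorrelation,
head-motion artifacts and their group confounding, scanner-specific
spatial noise, true cortical geometry (a sphere stands in for the
surface), non-Gaussian heavy-tailed FC variability, and any realistic
effect topography beyond a contiguous patch. Results about calibration
and recovery are statements about this generative family.

## 6. Numerical choices and degenerate inputs

* Dense `eigh` everywhere (parcel counts ≤ a few hundred); the symmetric
  conjugate guards symmetry to rounding.
* Ties in row thresholding and consensus ranking break deterministically
  (lower index), so every pipeline output is bit-reproducible from
  (config, seed); the experiment manifest records per-file SHA-256.
* Rank-deficient designs error listing aliased columns; singular residual
  covariance (constant response) errors as degenerate input;
  rank-deficient Procrustes cross-products solve with a logged
  non-uniqueness warning.
* Randomness: a single seed expands into fixed-tag child streams
  (ground truth 11, FC 13, SC 17, reference 19), so each stage is
  independently reproducible.
* TSV I/O uses %.17g and round-trip float parsing; write-then-read is
  bit-exact (tested).

## 7. Test-suite problem sizes

End-to-end checks run at 100 parcels, 30 + 30 subjects, 3 sites — the
generator's default study scale — with 20 replicate seeds for recovery
(each replicate re-draws parcellation, ground truth and cohort), 50 for
null calibration, 200 runs × 200 permutations for spin-test uniformity.
These sizes put per-edge FC noise, gradient reliability, and test power
in realistic ranges while the full suite completes in about a minute.

## 8. Known limitations

* The third gradient is only partially recoverable at the default 10% row
  density (canonical correlation with the generating axis ≈ 0.85–0.94);
  without thresholding it exceeds 0.95. Thresholding trades third-axis
  fidelity for robustness.
* The permutation-enforcing spin variant is mildly anticonservative for
  very smooth maps (see §4).
* Strategy 5/6 effect maps are exactly those of strategies 1/2 (§3); the
  package reports both, and any observed difference in other settings
  indicates a template-shape difference, not the rotation.
* No vertex-level analysis, no generalized (iterative) Procrustes, no
  mixed-effects models, no imaging-container I/O — inputs begin at
  parcellated matrices in delimited text.
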