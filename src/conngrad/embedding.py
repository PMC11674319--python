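"""Connectome gradient estimation via diffusion map embedding.

The pipeline is: sparsify the connectivity matrix (top-density entries
per row), convert row profiles into an affinity matrix (normalized-angle
or cosine kernel), then eigendecompose the density-normalized Markov
operator of the affinity graph. The resulting eigenvectors ("gradients"
G1, G2, G3, ...) place parcels with similar connection profiles close
together along smooth axes of connectivity variation.

Structural connectomes are embedded one hemisphere at a time (streamline
counts are dominated by intra-hemispheric edges and strongly lateralized)
and the right-hemisphere gradients are rotated onto the left over
homologous parcels before concatenation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components

from .connectome import ConnectivityMatrix
from .parcellation import ParcellationScheme

logger = logging.getLogger(__name__)


@dataclass
class GradientParams:
    """Embedding hyper-parameters.

    kernel : affinity kernel, ``normalized_angle`` (default) or ``cosine``.
    density : fraction of off-diagonal entries kept per row before the
        kernel (functional pathway only); 0.10 keeps the top 10%.
    k : number of gradients retained (three by default).
    alpha : diffusion-map density-normalization exponent; 0.5 gives
        anisotropic (Fokker-Planck) normalization, the common default for
        connectome gradients.
    """

    kernel: str = "normalized_angle"
    density: float = 0.10
    k: int = 3
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.kernel not in ("normalized_angle", "cosine"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not 0 < self.density <= 1:
            raise ValueError(f"density must be in (0, 1], got {self.density}")


@dataclass
class AffinityMatrix:
    values: np.ndarray
    kernel: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GradientSet:
    """Low-dimensional embedding of a connectome.

    components : (p, k) matrix whose columns are G1..Gk (eigenvectors of
        the diffusion operator scaled by lambda/(1-lambda)).
    eigenvalues : k non-trivial eigenvalues, non-increasing.
    variance_explained : eigenvalue_i over the sum of all positive
        non-trivial eigenvalues of the operator.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)

    @property
    def n_parcels(self) -> int:
        return self.components.shape[0]

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def copy_with(self, components: np.ndarray) -> "GradientSet":
        return GradientSet(
            components=np.asarray(components, dtype=float),
            eigenvalues=self.eigenvalues.copy(),
            variance_explained=self.variance_explained.copy(),
            meta=dict(self.meta),
        )


def row_threshold(m: np.ndarray, density: float = 0.10) -> np.ndarray:
    """Keep the top ``density`` fraction of off-diagonal entries per row.

    Per row, the ceil(density * (p - 1)) largest off-diagonal values are
    retained (ranking by value, negatives included); everything else and
    the diagonal are set to zero. Ties break toward the lower column
    index. The output is generally asymmetric; symmetry is restored
    downstream by the affinity kernel, which compares row profiles.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got {m.shape}")
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    p = m.shape[0]
    n_keep = int(np.ceil(density * (p - 1)))
    out = np.zeros_like(m)
    cols = np.arange(p)
    for i in range(p):
        row = m[i].copy()
        off = cols != i
        # stable sort on (-value, column) implements the tie-break
        order = np.lexsort((cols[off], -row[off]))
        keep = cols[off][order[:n_keep]]
        out[i, keep] = row[keep]
    return out


def _cosine_similarity_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(
            f"all-zero row(s) for parcel(s) {zero.tolist()}: affinity undefined"
        )
    sim = (m @ m.T) / np.outer(norms, norms)
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def normalized_angle_affinity(m: np.ndarray) -> AffinityMatrix:
    """Normalized-angle affinity between row profiles.

    a_ij = 1 - arccos(cos_sim(row_i, row_j)) / pi, mapping cosine
    similarity into [0, 1]: 1 for equal angles, 0 for opposite ones. This
    avoids the negative similarities a raw cosine kernel can produce.
    """
    sim = _cosine_similarity_rows(np.asarray(m, dtype=float))
    aff = 1.0 - np.arccos(sim) / np.pi
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(aff, kernel="normalized_angle")


def cosine_affinity(m: np.ndarray) -> AffinityMatrix:
    """Cosine-similarity affinity with negative values floored at zero.

    Diffusion maps need non-negative affinities, so the negative part of
    the cosine similarity is clipped.
    """
    sim = _cosine_similarity_rows(np.asarray(m, dtype=float))
    aff = np.maximum(sim, 0.0)
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(aff, kernel="cosine")


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|value| element positive.

    Eigenvector signs are arbitrary; fixing them makes templates
    bit-reproducible. Idempotent by construction.
    """
    out = components.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def diffusion_map(a: AffinityMatrix, k: int = 3, alpha: float = 0.5) -> GradientSet:
    """Diffusion map embedding of an affinity matrix.

    The affinity W is density-normalized, W'_ij = W_ij / (d_i^alpha
    d_j^alpha) with d the degree vector, then row-normalized into a Markov
    operator P. The eigenvectors of P are computed through the symmetric
    conjugate S = D'^(-1/2) W' D'^(-1/2) (same spectrum; eigenvectors
    related by the diagonal scaling), the trivial constant eigenvector
    (eigenvalue 1) is dropped, and component i is eigenvector i+1 scaled
    by lambda/(1 - lambda) — the "automatic diffusion time" convention,
    which integrates over all diffusion scales.
    """
    w = np.asarray(a.values, dtype=float)
    p = w.shape[0]
    if k >= p:
        raise ValueError(f"k must be < number of parcels ({p}), got {k}")
    if np.any(w < 0):
        raise ValueError("affinity must be non-negative")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    n_comp, labels = connected_components(w > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph is disconnected: {n_comp} components of sizes "
            f"{sizes.tolist()}"
        )

    d = w.sum(axis=1)
    w_alpha = w / np.outer(d**alpha, d**alpha)
    d_alpha = w_alpha.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d_alpha)
    s = w_alpha * np.outer(inv_sqrt, inv_sqrt)
    s = (s + s.T) / 2.0  # guard symmetry against rounding

    evals, evecs = eigh(s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    # eigenvectors of the Markov operator P = D'^-1 W'; normalize so the
    # trivial one is constant (psi_0 = 1)
    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]

    lam = evals[1 : k + 1]
    comps = psi[:, 1 : k + 1] * (lam / (1.0 - lam))
    comps = _fix_signs(comps)

    nontrivial = evals[1:]
    pos_sum = nontrivial[nontrivial > 0].sum()
    var_exp = np.where(lam > 0, lam / pos_sum, 0.0)
    return GradientSet(
        components=comps,
        eigenvalues=lam,
        variance_explained=var_exp,
        meta={"alpha": alpha, "kernel": a.kernel, "all_eigenvalues": evals},
    )


_KERNELS = {"normalized_angle": normalized_angle_affinity, "cosine": cosine_affinity}


def embed_functional(
    fc: ConnectivityMatrix, params: GradientParams | None = None
) -> GradientSet:
    """Gradients of a functional connectome (group or individual level).

    Row-threshold the Fisher-z matrix at the configured density, apply
    the affinity kernel, and run the diffusion map. Group and subject
    matrices go through the identical code path.
    """
    params = params or GradientParams()
    fc._require("functional", "fisher_z")
    sparse = row_threshold(fc.values, density=params.density)
    aff = _KERNELS[params.kernel](sparse)
    return diffusion_map(aff, k=params.k, alpha=params.alpha)


def embed_structural(
    sc: ConnectivityMatrix,
    scheme: ParcellationScheme,
    params: GradientParams | None = None,
) -> GradientSet:
    """Hemisphere-separate gradients of a structural connectome.

    Each intra-hemispheric block of the log-transformed SC is embedded
    independently — no thresholding, since the structural connectome is
    already sparse — which sidesteps the lateralization problem of a
    joint embedding. The right-hemisphere gradients are then rotated onto
    the left-hemisphere ones over homologous parcels (orthogonal
    Procrustes), and the two blocks are concatenated into a whole-brain
    gradient set. Without a homologue map the hemispheres are matched by
    eigenvalue order only, with a logged warning.
    """
    params = params or GradientParams()
    sc._require("structural", "log")
    if sc.values.shape[0] != scheme.n_parcels:
        raise ValueError(
            f"matrix has {sc.values.shape[0]} parcels, scheme has {scheme.n_parcels}"
        )
    idx = {h: scheme.hemisphere_indices(h) for h in ("L", "R")}
    grads: dict[str, GradientSet] = {}
    for h in ("L", "R"):
        block = sc.values[np.ix_(idx[h], idx[h])]
        aff = _KERNELS[params.kernel](block)
        try:
            grads[h] = diffusion_map(aff, k=params.k, alpha=params.alpha)
        except ValueError as exc:
            raise ValueError(f"hemisphere {h}: {exc}") from exc

    left, right = grads["L"], grads["R"]
    if scheme.has_complete_homologue_map:
        # order right-hemisphere rows as the homologues of the left rows,
        # then solve the orthogonal Procrustes problem onto the left block
        from .templates import procrustes_rotate

        homol_of_left = scheme.homologue[idx["L"]]
        pos_in_right = np.searchsorted(idx["R"], homol_of_left)
        right_matched = right.components[pos_in_right]
        _, rot = procrustes_rotate(right_matched, left.components)
        right_aligned = right.components @ rot.matrix
    else:
        logger.warning(
            "no homologue map: matching hemispheres by eigenvalue order only"
        )
        right_aligned = right.components

    comps = np.zeros((scheme.n_parcels, params.k))
    comps[idx["L"]] = left.components
    comps[idx["R"]] = right_aligned
    eigenvalues = (left.eigenvalues + right.eigenvalues) / 2.0
    var_exp = (left.variance_explained + right.variance_explained) / 2.0
    return GradientSet(
        components=comps,
        eigenvalues=eigenvalues,
        variance_explained=var_exp,
        meta={
            "hemisphere_eigenvalues": {
                "L": left.eigenvalues,
                "R": right.eigenvalues,
            },
            "kernel": params.kernel,
        },
    )
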