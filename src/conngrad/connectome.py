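"""Individual- and group-level connectome construction.

Functional connectivity (FC) is the Pearson correlation of parcellated
time series, Fisher r-to-z transformed per subject and averaged across
subjects at the group level. Structural connectivity (SC) is a
streamline-count matrix, log-transformed at the subject level; the group
SC is built with distance-dependent consensus thresholding, which keeps
per distance bin the edges most consistently present across subjects so
that the group matrix preserves the subject-typical edge-length
distribution (a plain group average over-represents short edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .parcellation import ParcellationScheme

logger = logging.getLogger(__name__)

_FC_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """A square symmetric parcel-by-parcel connectivity matrix.

    ``modality`` is ``"functional"`` or ``"structural"``;
    ``transform_state`` tracks which transforms have been applied
    (``raw_r`` / ``fisher_z`` for FC, ``raw_count`` / ``log`` for SC) so
    that a transform cannot be applied twice or to the wrong modality.
    """

    values: np.ndarray
    modality: str
    transform_state: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.values
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {m.shape}")
        if self.modality not in ("functional", "structural"):
            raise ValueError(f"unknown modality {self.modality!r}")
        valid = {
            "functional": {"raw_r", "fisher_z"},
            "structural": {"raw_count", "log"},
        }
        if self.transform_state not in valid[self.modality]:
            raise ValueError(
                f"state {self.transform_state!r} invalid for {self.modality} matrix"
            )

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    def _require(self, modality: str, state: str) -> None:
        if self.modality != modality or self.transform_state != state:
            raise ValueError(
                f"expected {modality}/{state} matrix, got "
                f"{self.modality}/{self.transform_state}"
            )


def build_fc(time_series: np.ndarray) -> ConnectivityMatrix:
    """Pearson-correlation FC from a parcels-by-timepoints series."""
    ts = np.asarray(time_series, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"time series must be 2-D (parcels x time), got {ts.ndim}-D")
    if ts.shape[1] < 3:
        raise ValueError(f"need at least 3 timepoints, got {ts.shape[1]}")
    sd = ts.std(axis=1)
    constant = np.where(sd == 0)[0]
    if constant.size:
        raise ValueError(
            f"constant time series for parcel(s) {constant.tolist()}: "
            "correlation undefined"
        )
    r = np.corrcoef(ts)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, modality="functional", transform_state="raw_r")


def fisher_z(fc: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher r-to-z transform of a raw-correlation FC matrix.

    The diagonal (r = 1, arctanh divergent) is set to 0; off-diagonal
    entries with |r| = 1 — possible with short series — are clipped to
    ±(1 - 1e-7) with a logged warning rather than raising.
    """
    fc._require("functional", "raw_r")
    r = fc.values.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    n_extreme = int(np.sum(np.abs(r[off]) >= 1.0))
    if n_extreme:
        logger.warning(
            "clipping %d off-diagonal |r|=1 entries before arctanh", n_extreme
        )
    z = np.arctanh(np.clip(r, -_FC_CLIP, _FC_CLIP))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, modality="functional", transform_state="fisher_z")


def group_average_fc(z_matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean of subject-level Fisher-z FC matrices."""
    mats = list(z_matrices)
    if not mats:
        raise ValueError("need at least one matrix")
    shape = mats[0].values.shape
    for i, m in enumerate(mats):
        m._require("functional", "fisher_z")
        if m.values.shape != shape:
            raise ValueError(
                f"matrix {i} has shape {m.values.shape}, expected {shape}"
            )
    mean = np.mean([m.values for m in mats], axis=0)
    return ConnectivityMatrix(mean, modality="functional", transform_state="fisher_z")


def log_transform_sc(sc: ConnectivityMatrix) -> ConnectivityMatrix:
    """log(1 + x) transform of a streamline-count matrix.

    log1p rather than log keeps absent edges at exactly zero and is
    monotone, so edge ranking is unchanged.
    """
    sc._require("structural", "raw_count")
    if np.any(sc.values < 0):
        raise ValueError("streamline counts must be non-negative")
    return ConnectivityMatrix(
        np.log1p(sc.values), modality="structural", transform_state="log"
    )


def _consensus_one_class(
    weights: np.ndarray,  # (s, e) subject weights for candidate edges
    dist: np.ndarray,  # (e,) edge distances
    n_bins: int,
) -> np.ndarray:
    """Consensus edge selection within one edge class (intra or inter).

    Returns the (e,) group weights: mean of nonzero subject weights for
    retained edges, zero elsewhere.
    """
    n_subj, n_edges = weights.shape
    out = np.zeros(n_edges)
    if n_edges == 0:
        return out
    present = weights > 0
    # equal-count (quantile) bin edges over the candidate-edge distances
    qs = np.quantile(dist, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(qs[1:-1], dist, side="right"), 0, n_bins - 1)
    freq = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_w = np.where(freq > 0, weights.sum(axis=0) / np.maximum(freq, 1), 0.0)
    for b in range(n_bins):
        in_bin = np.where(bin_idx == b)[0]
        cand = in_bin[freq[in_bin] > 0]
        if cand.size == 0:
            logger.info("distance bin %d has no candidate edges; skipped", b)
            continue
        # K = rounded mean number of present edges per subject in this bin
        k = int(np.round(present[:, in_bin].sum() / n_subj))
        if k <= 0:
            continue
        k = min(k, cand.size)
        # rank: most frequent first, then higher mean weight, then lower
        # edge index (edges are enumerated in (i, j) lexicographic order)
        order = np.lexsort((cand, -mean_w[cand], -freq[cand]))
        keep = cand[order[:k]]
        out[keep] = mean_w[keep]
    return out


def distance_consensus_group_sc(
    sc_list: Sequence[ConnectivityMatrix],
    scheme: ParcellationScheme,
    n_bins: int = 10,
) -> ConnectivityMatrix:
    """Distance-dependent consensus group structural connectome.

    Candidate edges (nonzero in at least one subject) are binned by
    inter-centroid great-circle distance into ``n_bins`` equal-count bins,
    with intra- and inter-hemispheric edges binned separately. Within each
    bin the K most frequently present edges are retained, K being the
    rounded mean per-subject count of present edges in the bin; ties break
    by higher mean nonzero weight, then lower parcel-index pair. Retained
    edges carry the mean of the nonzero subject weights.
    """
    mats = list(sc_list)
    if len(mats) < 2:
        raise ValueError("consensus needs at least 2 subjects")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    p = scheme.n_parcels
    for i, m in enumerate(mats):
        m._require("structural", "raw_count")
        if m.values.shape != (p, p):
            raise ValueError(f"matrix {i} shape {m.values.shape} != ({p}, {p})")

    iu, ju = np.triu_indices(p, k=1)
    weights = np.stack([m.values[iu, ju] for m in mats])  # (s, e)
    dist = scheme.pairwise_distances()[iu, ju]
    intra = scheme.hemisphere[iu] == scheme.hemisphere[ju]
    candidate = (weights > 0).any(axis=0)

    group = np.zeros(len(iu))
    for mask in (intra & candidate, ~intra & candidate):
        idx = np.where(mask)[0]
        group[idx] = _consensus_one_class(weights[:, idx], dist[idx], n_bins)

    out = np.zeros((p, p))
    out[iu, ju] = group
    out += out.T
    return ConnectivityMatrix(out, modality="structural", transform_state="raw_count")


def flip_hemispheres(
    m: ConnectivityMatrix, scheme: ParcellationScheme
) -> ConnectivityMatrix:
    """Swap each parcel with its contralateral homologue (rows and columns).

    Used to pool subjects whose lateralized pathology sits in opposite
    hemispheres onto a common side before group analysis.
    """
    if not scheme.has_complete_homologue_map:
        missing = np.where(scheme.homologue < 0)[0]
        raise ValueError(
            f"homologue map incomplete; unmapped parcels: {missing.tolist()}"
        )
    perm = scheme.homologue
    return replace(m, values=m.values[np.ix_(perm, perm)])


def flip_gradient_rows(components: np.ndarray, scheme: ParcellationScheme) -> np.ndarray:
    """Apply the homologue permutation to the rows of a parcel-wise map."""
    if not scheme.has_complete_homologue_map:
        raise ValueError("homologue map incomplete")
    return np.asarray(components)[scheme.homologue]
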