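"""Spherical parcellation schemes.

A parcellation assigns each cortical parcel a hemisphere, a unit-sphere
centroid, a functional-community label, a cortical-hierarchy label, and a
contralateral homologue. The sphere geometry is what the spatial null
(spin) test rotates, so centroids must have unit norm and the two
hemispheres must be mirror images of each other across the sagittal plane
(x = 0 by convention; left hemisphere has x < 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

# Canonical label sets used when the requested granularity matches them:
# the seven intrinsic functional communities and the four cortical
# hierarchical levels commonly used to stratify cortical maps.
YEO7_COMMUNITIES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)
MESULAM4_HIERARCHY = ("idiotypic", "unimodal", "heteromodal", "paralimbic")


@dataclass
class ParcellationScheme:
    """Parcel geometry and labels.

    Attributes
    ----------
    parcel_id : (p,) int array, 0-based contiguous ids.
    hemisphere : (p,) array of 'L'/'R'.
    centroids : (p, 3) unit vectors; left parcels have x < 0.
    community : (p,) object array of community labels.
    hierarchy : (p,) object array of hierarchy labels.
    homologue : (p,) int array; ``homologue[i]`` is the contralateral
        homologous parcel of ``i``, or -1 when undefined.
    """

    parcel_id: np.ndarray
    hemisphere: np.ndarray
    centroids: np.ndarray
    community: np.ndarray
    hierarchy: np.ndarray
    homologue: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.parcel_id = np.asarray(self.parcel_id, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        if self.homologue is None:
            self.homologue = np.full(self.n_parcels, -1, dtype=int)
        self.homologue = np.asarray(self.homologue, dtype=int)
        self.validate()

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_id)

    def validate(self) -> None:
        p = self.n_parcels
        if self.centroids.shape != (p, 3):
            raise ValueError(f"centroids must be ({p}, 3), got {self.centroids.shape}")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            bad = np.where(np.abs(norms - 1.0) > 1e-9)[0]
            raise ValueError(f"centroids not unit-norm for parcels {bad.tolist()}")
        hemis = set(self.hemisphere.tolist())
        if not hemis <= {"L", "R"}:
            raise ValueError(f"hemisphere labels must be 'L'/'R', got {sorted(hemis)}")
        defined = np.where(self.homologue >= 0)[0]
        for i in defined:
            j = self.homologue[i]
            if j >= p or self.homologue[j] != i:
                raise ValueError(f"homologue map is not an involution at parcel {i}")
            if self.hemisphere[i] == self.hemisphere[j]:
                raise ValueError(f"homologue pair ({i}, {j}) does not cross hemispheres")

    def hemisphere_indices(self, hemi: str) -> np.ndarray:
        return np.where(self.hemisphere == hemi)[0]

    @property
    def has_complete_homologue_map(self) -> bool:
        return bool(np.all(self.homologue >= 0))

    def pairwise_distances(self) -> np.ndarray:
        """Great-circle (geodesic) distances between parcel centroids."""
        cos = np.clip(self.centroids @ self.centroids.T, -1.0, 1.0)
        return np.arccos(cos)


def _fibonacci_hemisphere(n: int, rotation: float) -> np.ndarray:
    """Quasi-uniform points on the x > 0 half of the unit sphere.

    A Fibonacci lattice is generated on the half-sphere, then rotated about
    the x-axis by ``rotation`` radians. Rotation about x preserves the x
    coordinate, so all points stay strictly inside the hemisphere.
    """
    golden = (1 + np.sqrt(5)) / 2
    i = np.arange(n)
    # x in (0, 1): offset keeps points off the sagittal plane and the pole
    x = (i + 0.5) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - x**2)
    y = r * np.cos(theta)
    z = r * np.sin(theta)
    c, s = np.cos(rotation), np.sin(rotation)
    y, z = c * y - s * z, s * y + c * z
    pts = np.column_stack([x, y, z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_parcellation(
    n_parcels: int,
    n_communities: int = 7,
    n_hierarchy: int = 4,
    seed: int = 0,
) -> ParcellationScheme:
    """Build a hemisphere-symmetric spherical parcellation.

    Half of the parcels are placed quasi-uniformly on the right unit
    hemisphere (x > 0) via a seeded Fibonacci lattice; the left hemisphere
    is the mirror image across the sagittal plane, which makes the
    homologue map exact by construction. Communities are contiguous
    spatial patches (nearest of ``n_communities`` spherical anchors, shared
    between mirrored hemispheres); hierarchy levels are equal-count bands
    of the z coordinate, which are likewise spatially contiguous.

    Parameters
    ----------
    n_parcels : even int >= 8, total parcel count across both hemispheres.
    n_communities, n_hierarchy : label granularities; with 7 and 4 the
        canonical community / hierarchy names are used.
    seed : rotates the lattice and the community anchors; the scheme is a
        deterministic function of all arguments.
    """
    if n_parcels < 8 or n_parcels % 2 != 0:
        raise ValueError(f"n_parcels must be an even integer >= 8, got {n_parcels}")
    if n_communities < 1 or n_communities > n_parcels // 2:
        raise ValueError(
            f"n_communities must be in [1, n_parcels/2], got {n_communities}"
        )
    if n_hierarchy < 1 or n_hierarchy > n_parcels // 2:
        raise ValueError(f"n_hierarchy must be in [1, n_parcels/2], got {n_hierarchy}")

    rng = np.random.default_rng(seed)
    half = n_parcels // 2
    right = _fibonacci_hemisphere(half, rotation=rng.uniform(0, 2 * np.pi))
    left = right * np.array([-1.0, 1.0, 1.0])

    centroids = np.vstack([left, right])
    hemisphere = np.array(["L"] * half + ["R"] * half, dtype=object)
    parcel_id = np.arange(n_parcels)
    homologue = np.concatenate([np.arange(half) + half, np.arange(half)])

    # Communities: k-means on mirrored coordinates (|x|, y, z) so that a
    # parcel and its homologue always land in the same community patch.
    mirrored = np.abs(centroids) * np.array([1.0, 0, 0]) + centroids * np.array(
        [0, 1.0, 1.0]
    )
    km = KMeans(n_clusters=n_communities, n_init=4, random_state=seed)
    comm_idx = km.fit_predict(mirrored)
    if n_communities == len(YEO7_COMMUNITIES):
        names = YEO7_COMMUNITIES
    else:
        names = tuple(f"community_{i + 1}" for i in range(n_communities))
    community = np.array([names[c] for c in comm_idx], dtype=object)

    # Hierarchy: equal-count z-bands, mirror-symmetric by construction.
    edges = np.quantile(centroids[:, 2], np.linspace(0, 1, n_hierarchy + 1)[1:-1])
    hier_idx = np.searchsorted(edges, centroids[:, 2], side="right")
    if n_hierarchy == len(MESULAM4_HIERARCHY):
        hnames = MESULAM4_HIERARCHY
    else:
        hnames = tuple(f"level_{i + 1}" for i in range(n_hierarchy))
    hierarchy = np.array([hnames[h] for h in hier_idx], dtype=object)

    return ParcellationScheme(
        parcel_id=parcel_id,
        hemisphere=hemisphere,
        centroids=centroids,
        community=community,
        hierarchy=hierarchy,
        homologue=homologue,
    )
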