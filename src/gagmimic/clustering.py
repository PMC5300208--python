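"""RMSD-radius conformer clustering.

Groups ensemble frames so that every member lies within a fixed RMSD radius
(default 2 Å) of its cluster's medoid frame.  The number of clusters is not
chosen by the user: k-means is run at k = 1, 2, … (10 seeded restarts each)
until the radius constraint is satisfied, making the radius — not k — the
contract.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .ensemble import ConformerEnsemble
from .errors import GagmimicError, RadiusUnsatisfiableError
from .shape import pairwise_rmsd, superpose_ensemble_to_mean, superpose_rmsd


@dataclass
class ClusteringParams:
    """Parameters of radius-constrained clustering.

    radius:
        Maximum allowed RMSD (Å) of any frame to its cluster medoid.
    seed:
        Seed for the k-means restarts; same seed gives identical labels.
    max_k:
        Largest k tried before declaring the radius unsatisfiable.
    selection:
        Optional atom indices the RMSDs are computed over.
    """

    radius: float = 2.0
    seed: int = 0
    max_k: int = 20
    selection: list[int] | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise GagmimicError(f"radius must be positive, got {self.radius}")
        if self.max_k < 1:
            raise GagmimicError(f"max_k must be >= 1, got {self.max_k}")


@dataclass
class ClusterAssignment:
    """Frame labels (dense 0..k-1, canonical by first occurrence), medoid
    frame index per cluster, and cluster sizes."""

    labels: np.ndarray
    centroids: list[int]
    sizes: list[int]
    max_member_distance: float = field(default=0.0)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_conformers(
    ensemble: ConformerEnsemble, params: ClusteringParams | None = None
) -> ClusterAssignment:
    """Cluster frames at a fixed RMSD radius.

    Frames are superposed onto their converged mean, k-means is run on the
    flattened coordinates for k = 1, 2, …, and the smallest k whose medoids
    hold every member within ``params.radius`` RMSD (pairwise-superposed) is
    returned.  The medoid of a cluster is the member frame minimizing the
    summed RMSD to the other members.

    Raises
    ------
    RadiusUnsatisfiableError
        If no k <= max_k satisfies the radius; reports the best achieved
        maximum member-to-medoid distance.
    """
    params = params or ClusteringParams()
    coords = ensemble.coordinates
    if params.selection is not None:
        coords = coords[:, np.asarray(params.selection, dtype=int)]
    n_frames = coords.shape[0]
    if n_frames < 1:
        raise GagmimicError("cannot cluster an empty ensemble")
    if n_frames == 1:
        return ClusterAssignment(np.zeros(1, dtype=int), [0], [1], 0.0)

    X, _ = superpose_ensemble_to_mean(coords)
    flat = X.reshape(n_frames, -1)
    dmat = pairwise_rmsd(coords)

    best_overall = np.inf
    for k in range(1, params.max_k + 1):
        if k > n_frames:
            break
        if k == 1:
            labels = np.zeros(n_frames, dtype=int)
        else:
            km = KMeans(
                n_clusters=k, n_init=10, random_state=params.seed
            ).fit(flat)
            labels = _canonicalize(km.labels_)
        centroids: list[int] = []
        sizes: list[int] = []
        worst = 0.0
        for c in range(labels.max() + 1):
            members = np.flatnonzero(labels == c)
            sub = dmat[np.ix_(members, members)]
            medoid_local = int(np.argmin(sub.sum(axis=1)))
            centroids.append(int(members[medoid_local]))
            sizes.append(int(members.size))
            worst = max(worst, float(sub[medoid_local].max()))
        best_overall = min(best_overall, worst)
        if worst <= params.radius:
            return ClusterAssignment(labels, centroids, sizes, worst)

    raise RadiusUnsatisfiableError(
        f"no k <= {params.max_k} puts every frame within {params.radius} Å of "
        f"its medoid (best achieved max distance {best_overall:.3f} Å)",
        best_max_distance=best_overall,
    )


@dataclass
class RepresentativeReport:
    """Largest-cluster medoid plus per-cluster medoids; optionally the RMSD
    of the largest-cluster medoid to an externally chosen reference frame
    (e.g. a lowest-energy conformation)."""

    largest_cluster: int
    largest_centroid: int
    per_cluster_centroids: list[int]
    sizes: list[int]
    rmsd_to_reference: float | None = None
    reference_frame: int | None = None


def representative_structures(
    ensemble: ConformerEnsemble,
    assignment: ClusterAssignment,
    reference_frame: int | None = None,
) -> RepresentativeReport:
    """Report representative (medoid) structures of a cluster assignment.

    The largest cluster is chosen by size, ties broken by lower cluster
    index.  If ``reference_frame`` is given, its superposed RMSD to the
    largest-cluster medoid is included.
    """
    sizes = np.asarray(assignment.sizes)
    largest = int(np.argmax(sizes))  # argmax takes the first (lowest index) tie
    centroid = assignment.centroids[largest]
    rmsd_val = None
    if reference_frame is not None:
        if not 0 <= reference_frame < ensemble.n_frames:
            raise IndexError(
                f"reference frame {reference_frame} out of range for "
                f"{ensemble.n_frames} frames"
            )
        _, _, rmsd_val = superpose_rmsd(
            ensemble.coordinates[reference_frame],
            ensemble.coordinates[centroid],
        )
    return RepresentativeReport(
        largest_cluster=largest,
        largest_centroid=centroid,
        per_cluster_centroids=list(assignment.centroids),
        sizes=list(assignment.sizes),
        rmsd_to_reference=rmsd_val,
        reference_frame=reference_frame,
    )
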