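"""Shape descriptors for conformational ensembles.

Per-frame metrics — end-to-end distance (EED), minimum-volume enclosing
ellipsoid (MVEE) volume and axes, RMSD to the converged average structure —
and static descriptors (MVEE of a single conformation, principal-component
summaries).  EED and MVEE are the two free-state comparables of the mimicry
algorithm; the MVEE is computed with the Khachiyan dual-ascent iteration.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .ensemble import ConformerEnsemble
from .errors import (
    ConvergenceError,
    DegenerateGeometryError,
    GagmimicError,
    InsufficientFramesError,
    RankError,
)


class EndpointProvenance(str, Enum):
    USER_SPECIFIED = "user_specified"
    AUTO_MAX_EXTENT = "auto_max_extent"


@dataclass(frozen=True)
class EndpointPair:
    """The two atoms whose separation defines the end-to-end distance."""

    atom_a: int
    atom_b: int
    provenance: EndpointProvenance = EndpointProvenance.USER_SPECIFIED

    def __post_init__(self):
        if self.atom_a == self.atom_b:
            raise GagmimicError("endpoint atoms must differ")
        if self.atom_a < 0 or self.atom_b < 0:
            raise GagmimicError("endpoint indices must be non-negative")


@dataclass
class ShapeSeries:
    """One value per frame of a named shape metric."""

    metric_name: str
    values: np.ndarray
    units: str
    times: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise GagmimicError(f"{self.metric_name}: non-finite values")
        if np.any(self.values < 0):
            raise GagmimicError(f"{self.metric_name}: negative values")


class ShapeClass(str, Enum):
    SPHERICAL = "spherical"
    PROLATE = "prolate"
    OBLATE = "oblate"
    SCALENE = "scalene"


@dataclass
class Ellipsoid:
    """Ellipsoid ``{x : (x - center)^T A (x - center) <= 1}``.

    ``shape_matrix`` A is symmetric positive definite (Å⁻²); semi-axes are
    the reciprocal square roots of its eigenvalues, sorted descending.
    """

    center: np.ndarray
    shape_matrix: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.shape_matrix = np.asarray(self.shape_matrix, dtype=float).reshape(3, 3)
        if not np.allclose(self.shape_matrix, self.shape_matrix.T, atol=1e-8):
            raise GagmimicError("shape matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(self.shape_matrix) <= 0):
            raise GagmimicError("shape matrix must be positive definite")

    @property
    def semi_axes(self) -> np.ndarray:
        """Semi-axis lengths (Å), sorted descending."""
        eig = np.linalg.eigvalsh(self.shape_matrix)
        return np.sort(1.0 / np.sqrt(eig))[::-1]

    @property
    def axial_lengths(self) -> np.ndarray:
        """Full axial lengths (2x semi-axes, Å), sorted descending."""
        return 2.0 * self.semi_axes

    @property
    def volume(self) -> float:
        """Volume (Å³) = 4/3 π a b c."""
        a, b, c = self.semi_axes
        return float(4.0 / 3.0 * np.pi * a * b * c)

    def contains(self, points: np.ndarray, tolerance: float = 1e-6) -> np.ndarray:
        """Boolean mask: which points satisfy the quadratic form <= 1 + tol."""
        d = np.atleast_2d(points) - self.center
        q = np.einsum("ij,jk,ik->i", d, self.shape_matrix, d)
        return q <= 1.0 + tolerance


def mvee(
    points: np.ndarray,
    tolerance: float = 1e-6,
    max_iterations: int = 10000,
) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid of a 3-D point set.

    Khachiyan's dual-ascent iteration with Wolfe–Atwood away steps:
    maintain simplex weights ``u`` over the points, repeatedly shift mass
    onto the point with the largest Mahalanobis distance under the current
    weighted scatter (or off the most over-weighted interior point), until
    the ``(1 + eps)`` enclosure factor drops below ``tolerance``.  The away
    steps give linear convergence, so tight tolerances are reached in a few
    hundred iterations.

    Parameters
    ----------
    points:
        ``(n, 3)`` coordinates, ``n >= 4``, not all coplanar.
    tolerance:
        Convergence threshold on the relative enclosure excess
        ``max_i M_i / (d + 1) - 1``.
    max_iterations:
        Iteration cap; exceeding it raises a convergence error that reports
        the final excess.

    Returns
    -------
    Ellipsoid
        Every input point satisfies the quadratic form within
        ``1 + 10 * tolerance``; the volume is within ``(1 + tolerance)^3``
        of the true minimum.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise GagmimicError(f"points must be (n, 3), got {P.shape}")
    n = P.shape[0]
    if n < 4:
        raise DegenerateGeometryError(f"need at least 4 points, got {n}")
    centered = P - P.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(P).max())) < 3:
        raise DegenerateGeometryError(
            "points are coplanar or collinear; no full-dimensional "
            "enclosing ellipsoid exists"
        )

    d = 3
    Q = np.column_stack([P, np.ones(n)])  # (n, d+1) lifted points
    u = np.full(n, 1.0 / n)
    err = np.inf
    for _ in range(max_iterations):
        X = Q.T @ (Q * u[:, None])  # (d+1, d+1) weighted scatter
        M = np.einsum("ij,ij->i", Q @ np.linalg.inv(X), Q)
        j_plus = int(np.argmax(M))
        eps_plus = M[j_plus] / (d + 1) - 1.0
        support = np.flatnonzero(u > 0)
        j_minus = int(support[np.argmin(M[support])])
        eps_minus = 1.0 - M[j_minus] / (d + 1)
        err = max(eps_plus, eps_minus)
        if eps_plus <= tolerance and eps_minus <= tolerance:
            break
        if eps_plus >= eps_minus:
            j, m = j_plus, M[j_plus]
            step = (m - d - 1.0) / ((d + 1.0) * (m - 1.0))
        else:
            # away step: pull weight off the most over-weighted support
            # point; clamp so its weight stays non-negative
            j, m = j_minus, M[j_minus]
            step = (m - d - 1.0) / ((d + 1.0) * (m - 1.0))
            step = max(step, -u[j] / (1.0 - u[j]))
        u *= 1.0 - step
        u[j] += step
        u = np.maximum(u, 0.0)
    else:
        raise ConvergenceError(
            f"MVEE did not converge in {max_iterations} iterations "
            f"(final enclosure excess {err:.3e})",
            residual=err,
        )

    center = P.T @ u
    scatter = P.T @ (P * u[:, None]) - np.outer(center, center)
    A = np.linalg.inv(scatter) / d
    A = 0.5 * (A + A.T)
    return Ellipsoid(center=center, shape_matrix=A)


def ellipsoid_descriptors(
    ellipsoid: Ellipsoid, axis_equality_tolerance: float = 0.02
) -> tuple[np.ndarray, float, ShapeClass]:
    """Semi-axes (descending), volume, and qualitative shape class.

    Two axes count as equal when their relative difference is within
    ``axis_equality_tolerance``.  Classes: spherical (all equal), prolate
    (two smaller equal), oblate (two larger equal), scalene (all differ).
    """
    a, b, c = ellipsoid.semi_axes  # a >= b >= c

    def close(x, y):
        return abs(x - y) <= axis_equality_tolerance * max(x, y)

    if close(a, b) and close(b, c):
        cls = ShapeClass.SPHERICAL
    elif close(b, c):
        cls = ShapeClass.PROLATE
    elif close(a, b):
        cls = ShapeClass.OBLATE
    else:
        cls = ShapeClass.SCALENE
    return ellipsoid.semi_axes, ellipsoid.volume, cls


# --- superposition --------------------------------------------------------

def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation R and translation t mapping mobile onto
    reference in the least-squares sense: ref ≈ mobile @ R.T + t."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def superpose_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation matrix (det +1), the translation vector,
    and the RMSD over the selection after applying the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        mobile_sel, ref_sel = mobile[sel], reference[sel]
    else:
        mobile_sel, ref_sel = mobile, reference
    if mobile_sel.shape != ref_sel.shape:
        raise GagmimicError(
            f"selection shapes differ: {mobile_sel.shape} vs {ref_sel.shape}"
        )
    if mobile_sel.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 atoms to superpose")
    if (
        np.linalg.matrix_rank(ref_sel - ref_sel.mean(axis=0), tol=1e-8) < 2
        or np.linalg.matrix_rank(mobile_sel - mobile_sel.mean(axis=0), tol=1e-8) < 2
    ):
        raise DegenerateGeometryError("selection atoms are collinear")
    R, t = _kabsch(mobile_sel, ref_sel)
    moved = mobile_sel @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_sel) ** 2, axis=1))))
    return R, t, rmsd


def pairwise_rmsd(coordinates: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs over frames.

    Uses a batched Kabsch (one SVD per pair, vectorized with numpy) so that
    medoid searches over a few hundred frames stay fast.
    """
    X = np.asarray(coordinates, dtype=float)
    n_f, n_a, _ = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    sq = np.sum(Xc**2, axis=(1, 2))  # per-frame squared norm about centroid
    ii, jj = np.triu_indices(n_f, k=1)
    # cross-covariance H_p = Xc[i]^T Xc[j] for each pair p
    H = np.einsum("pak,pal->pkl", Xc[ii], Xc[jj])
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("pij,pjk->pik", Vt.transpose(0, 2, 1), U.transpose(0, 2, 1)))
    S_signed = S.copy()
    S_signed[:, -1] *= np.sign(det)
    # E = |A|^2 + |B|^2 - 2 * trace of signed singular values
    e = sq[ii] + sq[jj] - 2.0 * S_signed.sum(axis=1)
    e = np.maximum(e, 0.0)
    out = np.zeros((n_f, n_f))
    out[ii, jj] = out[jj, ii] = np.sqrt(e / n_a)
    return out


def superpose_ensemble_to_mean(
    coordinates: np.ndarray,
    rmsd_tol: float = 1e-6,
    max_iterations: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose all frames onto their running mean structure.

    Repeats (superpose every frame onto the current mean, recompute the
    mean) until the mean moves by less than ``rmsd_tol`` Å RMSD.  Returns
    the superposed coordinates and the converged mean structure.
    """
    X = np.array(coordinates, dtype=float)
    mean = X[0].copy()
    for _ in range(max_iterations):
        for f in range(X.shape[0]):
            R, t, _ = superpose_rmsd(X[f], mean)
            X[f] = X[f] @ R.T + t
        new_mean = X.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < rmsd_tol:
            break
    return X, mean


# --- per-frame series -----------------------------------------------------

def end_to_end_distance(
    ensemble: ConformerEnsemble, pair: EndpointPair
) -> ShapeSeries:
    """Per-frame Euclidean distance (Å) between the two endpoint atoms."""
    n = ensemble.n_atoms
    if pair.atom_a >= n or pair.atom_b >= n:
        raise IndexError(
            f"endpoint pair ({pair.atom_a}, {pair.atom_b}) out of range for "
            f"{n} atoms"
        )
    diff = ensemble.coordinates[:, pair.atom_a] - ensemble.coordinates[:, pair.atom_b]
    return ShapeSeries(
        metric_name="EED",
        values=np.linalg.norm(diff, axis=1),
        units="Å",
        times=ensemble.times,
    )


def auto_endpoints(ensemble: ConformerEnsemble) -> EndpointPair:
    """Default EED endpoints: the two heavy atoms with maximum separation in
    the first frame, fixed for all frames."""
    heavy = [a.atom_index for a in ensemble.topology.atoms if a.element.upper() != "H"]
    if len(heavy) < 2:
        raise GagmimicError("need at least two heavy atoms for auto endpoints")
    pts = ensemble.coordinates[0, heavy]
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    a, b = sorted((heavy[i], heavy[j]))
    return EndpointPair(a, b, EndpointProvenance.AUTO_MAX_EXTENT)


def mvee_series(
    ensemble: ConformerEnsemble,
    heavy_only: bool = True,
    tolerance: float = 1e-6,
    max_iterations: int = 10000,
) -> dict[str, ShapeSeries]:
    """Per-frame MVEE volume and sorted semi-axes.

    By default the ellipsoid encloses heavy atoms only — sulfate and ring
    geometry dominate molecular shape, and hydrogens merely pad the hull.
    Returns series keyed ``MVEE_volume``, ``axis_longest``, ``axis_mid``,
    ``axis_shortest``.
    """
    if heavy_only:
        idx = [a.atom_index for a in ensemble.topology.atoms if a.element.upper() != "H"]
    else:
        idx = list(range(ensemble.n_atoms))
    vols = np.empty(ensemble.n_frames)
    axes = np.empty((ensemble.n_frames, 3))
    for f in range(ensemble.n_frames):
        ell = mvee(ensemble.coordinates[f, idx], tolerance, max_iterations)
        vols[f] = ell.volume
        axes[f] = ell.semi_axes
    t = ensemble.times
    return {
        "MVEE_volume": ShapeSeries("MVEE_volume", vols, "Å³", t),
        "axis_longest": ShapeSeries("axis_longest", axes[:, 0], "Å", t),
        "axis_mid": ShapeSeries("axis_mid", axes[:, 1], "Å", t),
        "axis_shortest": ShapeSeries("axis_shortest", axes[:, 2], "Å", t),
    }


def rmsd_to_average(
    ensemble: ConformerEnsemble,
    selection: np.ndarray | list[int] | None = None,
) -> ShapeSeries:
    """Per-frame RMSD (Å) to the converged iterative mean structure."""
    if ensemble.n_frames < 2:
        raise InsufficientFramesError(
            "rmsd_to_average needs at least 2 frames"
        )
    coords = ensemble.coordinates
    if selection is not None:
        coords = coords[:, np.asarray(selection, dtype=int)]
    X, mean = superpose_ensemble_to_mean(coords)
    vals = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=1))
    return ShapeSeries("RMSD_to_average", vals, "Å", ensemble.times)


# --- PCA ------------------------------------------------------------------

@dataclass
class PCAResult:
    """Eigenvalues (Å², descending), per-frame projections, and the fraction
    of positional variance each component explains."""

    eigenvalues: np.ndarray
    projections: np.ndarray
    explained_fraction: np.ndarray
    total_variance: float


def pca_ensemble(
    ensemble: ConformerEnsemble,
    selection: np.ndarray | list[int] | None = None,
    n_components: int = 3,
) -> PCAResult:
    """Principal components of the superposed positional covariance.

    Frames are first superposed onto their converged mean (removing rigid
    diffusion), then the 3N x 3N covariance of the flattened coordinates is
    diagonalized and each frame projected onto the top eigenvectors.
    """
    coords = ensemble.coordinates
    if selection is not None:
        coords = coords[:, np.asarray(selection, dtype=int)]
    n_frames = coords.shape[0]
    if n_frames < 2:
        raise InsufficientFramesError("PCA needs at least 2 frames")
    X, mean = superpose_ensemble_to_mean(coords)
    flat = X.reshape(n_frames, -1) - mean.reshape(1, -1)
    rank = min(n_frames - 1, flat.shape[1])
    if n_components > rank:
        raise RankError(
            f"requested {n_components} components but data rank is {rank}"
        )
    # SVD of the centered data gives the covariance eigensystem directly
    U, S, Vt = np.linalg.svd(flat, full_matrices=False)
    eigvals = S**2 / (n_frames - 1)
    total = float(np.sum(flat**2) / (n_frames - 1))
    proj = flat @ Vt[:n_components].T
    return PCAResult(
        eigenvalues=eigvals[:n_components],
        projections=proj,
        explained_fraction=eigvals[:n_components] / total,
        total_variance=total,
    )
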