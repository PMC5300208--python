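"""Independent reference implementations used only by the test suite.

These deliberately take different algorithmic routes from the package:
the MVEE oracle solves the dual log-det program directly with SLSQP, and
the superposition oracle uses the quaternion eigendecomposition instead of
the Kabsch SVD.
"""
import numpy as np
from scipy.optimize import minimize


def mvee_oracle(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimum-volume enclosing ellipsoid by direct constrained optimization.

    Maximizes log det of the weighted lifted scatter over the probability
    simplex with SLSQP run to tight tolerance.  Returns (center,
    shape_matrix, volume).
    """
    P = np.asarray(points, dtype=float)
    n, d = P.shape[0], 3
    Q = np.column_stack([P, np.ones(n)])

    def neg_logdet(u):
        sign, logdet = np.linalg.slogdet(Q.T @ (Q * u[:, None]))
        return -logdet if sign > 0 else 1e10

    def grad(u):
        Xi = np.linalg.inv(Q.T @ (Q * u[:, None]))
        return -np.einsum("ij,jk,ik->i", Q, Xi, Q)

    res = minimize(
        neg_logdet,
        np.full(n, 1.0 / n),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[
            {
                "type": "eq",
                "fun": lambda u: u.sum() - 1.0,
                "jac": lambda u: np.ones(n),
            }
        ],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    u = res.x
    center = P.T @ u
    scatter = P.T @ (P * u[:, None]) - np.outer(center, center)
    A = np.linalg.inv(scatter) / d
    semi = 1.0 / np.sqrt(np.linalg.eigvalsh(A))
    volume = 4.0 / 3.0 * np.pi * np.prod(semi)
    return center, A, float(volume)


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via the quaternion eigen method.

    Builds the 4x4 key matrix from the cross-covariance; the largest
    eigenvalue gives the maximal attainable correlation, hence the minimal
    RMSD, without ever forming a rotation matrix.
    """
    A = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    B = np.asarray(reference, float) - np.mean(reference, axis=0)
    n = A.shape[0]
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    sq = (np.sum(A**2) + np.sum(B**2) - 2.0 * lam_max) / n
    return float(np.sqrt(max(sq, 0.0)))


def binomial_interval_99(p: float, n: int) -> tuple[float, float]:
    """99% normal-approximation interval for a binomial proportion."""
    from scipy.stats import norm

    z = norm.ppf(0.995)
    half = z * np.sqrt(max(p * (1 - p), 1e-12) / n)
    return p - half, p + half
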