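"""Independent brute-force checks for the superposition code.

The closed-form Kabsch solution is validated against an exhaustive Euler
grid search.  For a rotation R the squared fitted deviation of centered
sets P (mobile) and Q (reference) is

    N * rmsd^2(R) = |P|^2 + |Q|^2 - 2 tr(R M),    M = P^T Q,

so scanning rotations only requires the 3x3 cross-covariance, which makes
a dense grid affordable.  The search scans a full coarse Euler grid and
then a 1-degree local grid around the coarse optimum; the returned
resolution bound accounts for the rotation lying between fine-grid nodes:
a node within total angle theta of the optimum satisfies
rmsd_grid <= rmsd_opt + theta * rms_radius(P).

This module never calls the SVD implementation it is used to check.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["euler_grid_rmsd"]


@lru_cache(maxsize=4)
def _coarse_grid(step: float) -> tuple[np.ndarray, np.ndarray]:
    """Flattened rotation matrices (G, 9) and Euler angles (G, 3) of the scan."""
    alphas = np.arange(0.0, 360.0, step)
    betas = np.arange(0.0, 180.0 + step, step)
    gammas = np.arange(0.0, 360.0, step)
    grid = np.stack(
        np.meshgrid(alphas, betas, gammas, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    mats = Rotation.from_euler("ZYZ", grid, degrees=True).as_matrix()
    return mats.reshape(-1, 9), grid


def euler_grid_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    coarse_step: float = 6.0,
    fine_step: float = 1.0,
) -> tuple[float, float]:
    """Best RMSD over an exhaustive Euler-angle rotation grid.

    Returns ``(rmsd, bound)`` where ``bound`` is the grid-resolution
    slack: the true rigid-fit optimum lies within ``[rmsd - bound, rmsd]``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    n = P.shape[0]
    M = P.T @ Q
    const = float(np.sum(P**2) + np.sum(Q**2))

    mats, grid = _coarse_grid(coarse_step)
    best_idx = int(np.argmax(mats @ M.T.ravel()))
    center = grid[best_idx]

    offsets = np.arange(-coarse_step, coarse_step + fine_step / 2, fine_step)
    local = np.stack(
        np.meshgrid(offsets, offsets, offsets, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    fine = Rotation.from_euler("ZYZ", center + local, degrees=True)
    smax = float(np.max(fine.as_matrix().reshape(-1, 9) @ M.T.ravel()))

    rmsd = float(np.sqrt(max(const - 2.0 * smax, 0.0) / n))
    # nearest fine node: each Euler angle within fine_step/2, total rotation
    # angle therefore within 3 * fine_step / 2
    theta = np.radians(1.5 * fine_step)
    bound = float(theta * np.sqrt(np.mean(np.sum(P**2, axis=1))))
    return rmsd, bound
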