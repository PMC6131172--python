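"""Rigid-body superposition (Kabsch), RMSD matrices and ensemble averages.

All distances in this package are Kabsch-fitted RMSDs: the minimum
root-mean-square deviation over proper rigid motions (rotation +
translation, reflections excluded so molecular chirality is preserved).
The SVD solution is used, with the standard determinant correction that
flips the sign of the smallest singular vector when the optimal orthogonal
matrix would be improper.

A batched formulation (:func:`batch_kabsch`) fits many frames to one
reference in a single stacked SVD call; the per-frame trajectory analyses
and the clustering module are built on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, TopologyError

__all__ = [
    "RigidTransform",
    "RmsdMatrix",
    "AverageStructure",
    "kabsch_fit",
    "batch_kabsch",
    "pairwise_rmsd_matrix",
    "average_structure",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,), Å

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal within 1e-8")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation is improper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _as_coords(x: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name}: expected (N, 3) coordinates, got {arr.shape}")
    return arr


def _check_pair(mobile: np.ndarray, reference: np.ndarray) -> None:
    if mobile.shape[0] != reference.shape[0]:
        raise TopologyError(
            f"atom count mismatch: mobile {mobile.shape[0]} vs "
            f"reference {reference.shape[0]}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 atoms for a rigid fit, got {n}")
    for name, arr in (("mobile", mobile), ("reference", reference)):
        centered = arr - arr.mean(axis=0)
        # rank < 2 == all points collinear: rotation about that axis is free
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise DegenerateGeometryError(f"{name} configuration is collinear")


def kabsch_fit(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform and the minimized RMSD in Å.
    """
    mobile = _as_coords(mobile, "mobile")
    reference = _as_coords(reference, "reference")
    _check_pair(mobile, reference)
    R, t, rmsd = _kabsch_core(mobile[None], reference)
    return RigidTransform(R[0], t[0]), float(rmsd[0])


def batch_kabsch(
    mobiles: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit a stack of frames (M, N, 3) to one reference (N, 3).

    Returns rotations (M, 3, 3), translations (M, 3) and RMSDs (M,).
    Degeneracy is checked on the reference only; callers fitting
    pathological single frames should use :func:`kabsch_fit`.
    """
    mobiles = np.asarray(mobiles, dtype=float)
    reference = _as_coords(reference, "reference")
    if mobiles.ndim != 3 or mobiles.shape[1:] != reference.shape:
        raise TopologyError(
            f"mobiles {mobiles.shape} incompatible with reference "
            f"{reference.shape}"
        )
    if reference.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 atoms for a rigid fit")
    return _kabsch_core(mobiles, reference)


def _kabsch_core(
    mobiles: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = reference.shape[0]
    mob_cent = mobiles.mean(axis=1)  # (M, 3)
    ref_cent = reference.mean(axis=0)
    P = mobiles - mob_cent[:, None, :]
    Q = reference - ref_cent
    H = np.einsum("mni,nj->mij", P, Q)  # covariance per frame
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("mij,mjk->mik", U, Vt)))
    d = np.where(d == 0, 1.0, d)
    # flip the smallest singular vector when the optimum would be a reflection
    V = np.swapaxes(Vt, 1, 2)
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("mij,mjk,mkl->mil", V, D, np.swapaxes(U, 1, 2))
    fitted = np.einsum("mni,mji->mnj", P, R)
    rmsd = np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=2), axis=1))
    t = ref_cent - np.einsum("mij,mj->mi", R, mob_cent)
    return R, t, rmsd


def fit_all(mobiles: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Return each frame superposed onto the reference, shape (M, N, 3)."""
    R, t, _ = batch_kabsch(mobiles, reference)
    return np.einsum("mni,mji->mnj", np.asarray(mobiles, dtype=float), R) + t[:, None, :]


# ---------------------------------------------------------------------------
# pairwise matrices


@dataclass
class RmsdMatrix:
    """Symmetric matrix of pairwise fitted RMSDs with conformation labels."""

    labels: list[str]
    values: np.ndarray  # (n, n), Å

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("labels/values shape mismatch")
        if not np.allclose(v, v.T) or np.any(v < -1e-12) or np.any(np.diag(v) != 0):
            raise ValueError("RMSD matrix must be symmetric, non-negative, zero-diagonal")
        self.values = v

    @property
    def mean_offdiag(self) -> float:
        """Mean over the C(n,2) unordered pairs."""
        iu = np.triu_indices(len(self.labels), k=1)
        return float(self.values[iu].mean())

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "labels": self.labels,
            "values": [[round(float(v), 6) for v in row] for row in self.values],
            "mean_pairwise_rmsd": round(self.mean_offdiag, 6),
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return path


def pairwise_rmsd_matrix(
    frames: Sequence[np.ndarray], labels: Sequence[str] | None = None
) -> RmsdMatrix:
    """All-pairs fitted RMSD between conformations of equal atom count."""
    frames = [_as_coords(f, f"frame {i}") for i, f in enumerate(frames)]
    n = len(frames)
    if n < 2:
        raise ValueError("need >= 2 conformations for a pairwise matrix")
    labels = list(labels) if labels is not None else [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("one label per conformation required")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                _, rmsd = kabsch_fit(frames[i], frames[j])
            except (DegenerateGeometryError, TopologyError) as exc:
                raise type(exc)(
                    f"pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = rmsd
    return RmsdMatrix(labels, values)


# ---------------------------------------------------------------------------
# iterative ensemble average


@dataclass
class AverageStructure:
    """Iteratively refit coordinate-wise mean of an ensemble."""

    coords: np.ndarray  # (N, 3)
    n_iterations: int
    converged: bool


def average_structure(
    frames: Sequence[np.ndarray] | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> AverageStructure:
    """Mean conformation under iterative superposition.

    Starting from frame 0, every frame is fitted to the current mean and
    the coordinate-wise mean recomputed, until the mean moves by less than
    ``tol`` (plain RMSD between successive means, Å) or ``max_iter`` is
    reached.  Non-convergence is flagged, not raised.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[2] != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected (M, N, 3) frame stack, got {stack.shape}")
    mean = stack[0].copy()
    if stack.shape[0] == 1:
        return AverageStructure(mean, 0, True)
    for it in range(1, max_iter + 1):
        fitted = fit_all(stack, mean)
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            return AverageStructure(mean, it, True)
    return AverageStructure(mean, max_iter, False)
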