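"""Fixed-radius RMSD k-means clustering of fragment conformations.

The algorithm is the "kclust" style two-phase scheme used for MD
trajectories.  Seeding pass: frames are scanned in order; a frame joins
the nearest existing centroid if its Kabsch-fitted RMSD is within the
cutoff radius, otherwise it founds a new cluster seeded at itself.
Refinement passes: each centroid is recomputed as the coordinate-wise
mean of its members after fitting every member to the current centroid,
then every frame is reassigned to its nearest centroid (no radius test);
emptied clusters are dropped; iteration stops when assignments are stable
or ``max_iter`` is reached.  Given a frame order the procedure is fully
deterministic.

The cutoff radius defaults to 2.3 Å on lever-arm Cα coordinates — the
radius that resolves the conformational variability of that fragment in
microsecond GR DBD simulations.  Clusters are reported in decreasing size
order (ties broken by seeding order).

Cross-trajectory comparison pools evenly spaced subsamples of several
labelled sources, clusters the pool once, and summarizes each source's
occupancy per cluster; two sources "share" a cluster when both occupy it
at or above an occupancy floor (default 10% of each source's time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfensError, TopologyError
from .structure_io import FRAGMENT_PRESETS, FragmentSpec
from .superpose import batch_kabsch, fit_all

__all__ = [
    "ClusterConfig",
    "ClusterModel",
    "OccupancyTable",
    "subsample_evenly",
    "kclust",
    "combined_cluster",
    "overlap_report",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of the fixed-radius clustering analysis."""

    radius: float = 2.3  # Å, cutoff for founding new clusters while seeding
    fragment: FragmentSpec = FRAGMENT_PRESETS["lever_arm"]
    n_frames_single: int = 50_000
    n_frames_combined_per_source: int = 5_000
    max_iter: int = 100
    occupancy_floor: float = 0.10

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_frames_single < 1 or self.n_frames_combined_per_source < 1:
            raise ValueError("frame counts must be >= 1")
        if not (0 < self.occupancy_floor < 1):
            raise ValueError("occupancy_floor must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def to_dict(self) -> dict:
        return {
            "radius": self.radius,
            "fragment": {
                "name": self.fragment.name,
                "residue_range": list(self.fragment.residue_range),
                "chain_id": self.fragment.chain_id,
                "atom_names": sorted(self.fragment.atom_names),
            },
            "n_frames_single": self.n_frames_single,
            "n_frames_combined_per_source": self.n_frames_combined_per_source,
            "max_iter": self.max_iter,
            "occupancy_floor": self.occupancy_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterConfig":
        d = dict(d)
        frag = d.pop("fragment", None)
        if isinstance(frag, str):
            fragment = FRAGMENT_PRESETS[frag]
        elif isinstance(frag, dict):
            fragment = FragmentSpec(
                frag.get("name", "custom"),
                tuple(frag["residue_range"]),
                frag.get("chain_id"),
                frozenset(frag.get("atom_names", ["CA"])),
            )
        else:
            fragment = FRAGMENT_PRESETS["lever_arm"]
        return cls(fragment=fragment, **d)


@dataclass
class ClusterModel:
    """Result of one clustering run, ordered by decreasing cluster size."""

    centroids: list[np.ndarray]
    assignments: np.ndarray  # per-frame cluster index
    sizes: np.ndarray
    source_labels: list[str]
    converged: bool
    n_iterations: int
    n_seeded: int  # clusters founded during the seeding pass

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def __post_init__(self) -> None:
        if int(self.sizes.sum()) != len(self.assignments):
            raise ValueError("cluster sizes do not conserve the frame count")
        if np.any(self.sizes <= 0):
            raise ValueError("empty cluster reported")
        if np.any(np.diff(self.sizes) > 0):
            raise ValueError("clusters must be ordered by decreasing size")

    def assignments_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("frame\tsource\tcluster\n")
            for i, (lab, c) in enumerate(zip(self.source_labels, self.assignments)):
                fh.write(f"{i}\t{lab}\t{int(c)}\n")
        return path


def subsample_evenly(n_total: int, n: int) -> np.ndarray:
    """Indices floor(j * L / n), j = 0..n-1: deterministic, first frame kept."""
    if not (1 <= n <= n_total):
        raise ValueError(f"cannot take {n} evenly spaced frames from {n_total}")
    return (np.arange(n) * n_total) // n


def _frame_stack(frames) -> np.ndarray:
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[2] != 3:
        raise ValueError(f"expected (M, N, 3) coordinate stack, got {stack.shape}")
    return stack


def _rmsd_to_centroids(stack: np.ndarray, centroids: list[np.ndarray]) -> np.ndarray:
    """(K, M) fitted RMSD of every frame to every centroid."""
    return np.stack([batch_kabsch(stack, c)[2] for c in centroids])


def kclust(
    frames,
    config: ClusterConfig | None = None,
    *,
    radius: float | None = None,
    max_iter: int | None = None,
    source_labels: Sequence[str] | None = None,
) -> ClusterModel:
    """Cluster fragment conformations at a fixed RMSD cutoff radius.

    ``frames`` is an (M, N, 3) stack (or list) of fitted-comparable
    coordinate sets.  All distances are Kabsch-fitted RMSDs.
    """
    config = config or ClusterConfig()
    radius = config.radius if radius is None else radius
    max_iter = config.max_iter if max_iter is None else max_iter
    stack = _frame_stack(frames)
    m = stack.shape[0]
    if m < 1:
        raise ValueError("need at least one frame")
    labels = list(source_labels) if source_labels is not None else [""] * m
    if len(labels) != m:
        raise ValueError("one source label per frame required")

    # --- seeding pass: fixed-radius leader scan in frame order
    seeds: list[int] = [0]
    assign = np.zeros(m, dtype=int)
    for i in range(1, m):
        try:
            # fitted RMSD is symmetric, so fit the seed stack to frame i
            d = batch_kabsch(stack[seeds], stack[i])[2]
        except ConfensError as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
        j = int(np.argmin(d))
        if d[j] <= radius:
            assign[i] = j
        else:
            seeds.append(i)
            assign[i] = len(seeds) - 1
    n_seeded = len(seeds)
    centroids = [stack[s].copy() for s in seeds]

    # --- k-means refinement: mean-of-fitted-members centroids, free reassignment
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_centroids = []
        keep = []
        for c, cent in enumerate(centroids):
            members = stack[assign == c]
            if len(members) == 0:
                continue
            new_centroids.append(fit_all(members, cent).mean(axis=0))
            keep.append(c)
        centroids = new_centroids
        if len(keep) < len(set(assign)):  # pragma: no cover - defensive
            raise RuntimeError("lost a non-empty cluster during refinement")
        # reindex assignments onto the surviving (non-empty) clusters
        reindex = {old: new for new, old in enumerate(keep)}
        assign = np.array([reindex[a] for a in assign])
        d = _rmsd_to_centroids(stack, centroids)
        new_assign = np.argmin(d, axis=0)
        if np.array_equal(new_assign, assign):
            converged = True
            break
        assign = new_assign

    # --- order by decreasing size, ties by first-seeded (current index order)
    sizes = np.bincount(assign, minlength=len(centroids))
    order = sorted(range(len(centroids)), key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    assign = np.array([remap[a] for a in assign])
    centroids = [centroids[c] for c in order]
    sizes = sizes[order]
    return ClusterModel(
        centroids, assign, sizes, labels, converged, it, n_seeded
    )


# ---------------------------------------------------------------------------
# cross-trajectory clustering


@dataclass
class OccupancyTable:
    """Fraction of each source's frames per cluster (rows sum to 1)."""

    table: pd.DataFrame  # index = source labels, columns = cluster ids

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("occupancies must lie in [0, 1]")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each source's occupancies must sum to 1")

    @property
    def sources(self) -> list[str]:
        return list(self.table.index)

    def occupancy(self, source: str, cluster: int) -> float:
        return float(self.table.loc[source, cluster])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", float_format="%.6f", index_label="source")
        return path


def combined_cluster(
    trajectories: Sequence[tuple[str, np.ndarray]],
    config: ClusterConfig | None = None,
) -> tuple[ClusterModel, OccupancyTable]:
    """Pool evenly spaced subsamples of labelled sources and cluster once.

    Each source contributes ``n_frames_combined_per_source`` evenly spaced
    frames (or all of them, if it has fewer).  Occupancy(s, c) is the
    fraction of source s's pooled frames assigned to cluster c.
    """
    config = config or ClusterConfig()
    if len(trajectories) < 2:
        raise ValueError("combined clustering needs >= 2 sources")
    n_atoms = {label: np.asarray(t).shape[1] for label, t in trajectories}
    if len(set(n_atoms.values())) > 1:
        raise TopologyError(
            "sources have incompatible fragment topology: "
            + ", ".join(f"{k}={v} atoms" for k, v in n_atoms.items())
        )
    pooled, labels = [], []
    for label, traj in trajectories:
        stack = _frame_stack(traj)
        n = min(config.n_frames_combined_per_source, stack.shape[0])
        idx = subsample_evenly(stack.shape[0], n)
        pooled.append(stack[idx])
        labels.extend([label] * n)
    model = kclust(np.concatenate(pooled), config, source_labels=labels)
    src = np.array(model.source_labels)
    rows = {}
    for label, _ in trajectories:
        mask = src == label
        counts = np.bincount(
            model.assignments[mask], minlength=model.n_clusters
        ).astype(float)
        rows[label] = counts / counts.sum()
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.Index([label for label, _ in trajectories], name="source")
    table = table.loc[[label for label, _ in trajectories]]
    return model, OccupancyTable(table)


def overlap_report(table: OccupancyTable, floor: float = 0.10) -> dict:
    """Clusters shared between source pairs at an occupancy floor.

    Cluster c is shared by (s, s') iff occupancy(s, c) >= floor AND
    occupancy(s', c) >= floor (strict "at least" rule on both sides).
    """
    sources = table.sources
    clusters = list(table.table.columns)
    pairs = []
    for i, a in enumerate(sources):
        for b in sources[i + 1 :]:
            shared = [
                {
                    "cluster": int(c),
                    "occupancy_a": round(table.occupancy(a, c), 6),
                    "occupancy_b": round(table.occupancy(b, c), 6),
                }
                for c in clusters
                if table.occupancy(a, c) >= floor and table.occupancy(b, c) >= floor
            ]
            pairs.append(
                {
                    "source_a": a,
                    "source_b": b,
                    "n_shared": len(shared),
                    "shared_clusters": shared,
                }
            )
    return {"occupancy_floor": floor, "pairs": pairs}


def write_overlap_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=1) + "\n")
    return path
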