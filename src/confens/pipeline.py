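"""Orchestration of the full ensemble analysis: compare / analyze / combine.

These functions sit directly behind the command-line interface and the
analysis drivers.  Every output file carries a metadata line recording a
hash of the configuration that produced it, so outputs from different
configurations never mix silently; bodies contain no timestamps and
re-running a command with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .clustering import (
    ClusterConfig,
    ClusterModel,
    OccupancyTable,
    combined_cluster,
    kclust,
    overlap_report,
    subsample_evenly,
    write_overlap_json,
)
from .dihedrals import (
    HIS453_STATES,
    StateAssignment,
    VariabilityProfile,
    assign_states,
    dihedral_series,
    variability_profile,
)
from .errors import ConfensError, DataError, SelectionError
from .fluctuation import RmsdSeries, RmsfProfile, rmsd_timeseries, rmsf
from .structure_io import (
    FRAGMENT_PRESETS,
    FragmentSpec,
    Frame,
    read_pdb,
    select_ensemble,
)
from .superpose import RmsdMatrix, pairwise_rmsd_matrix

__all__ = [
    "config_hash",
    "cmd_compare",
    "cmd_analyze",
    "cmd_combine",
    "AnalysisBundle",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration dictionary."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _metadata(config: dict, **extra) -> dict:
    return {"config_hash": config_hash(config), "version": __version__, **extra}


def _split_conformations(
    frames: Sequence[Frame], label: str
) -> list[tuple[str, Frame]]:
    """One conformation per (model, chain): crystal chains count separately."""
    from dataclasses import replace

    out = []
    for f in frames:
        chains = sorted({a.chain_id for a in f.atoms if not a.het})
        for ch in chains:
            # chain id is normalized so single-chain conformations from
            # different chains compare as the same topology
            sub = Frame(
                [replace(a, chain_id="A") for a in f.atoms if a.chain_id == ch],
                f.model_index,
                f.source_label,
            )
            tag = label
            if len(frames) > 1:
                tag += f"/m{f.model_index}"
            if len(chains) > 1:
                tag += f"/{ch}"
            out.append((tag, sub))
    return out


def cmd_compare(
    paths: Sequence[str | Path],
    fragment: FragmentSpec | str = "core_dbd",
    allow_missing: bool = False,
) -> RmsdMatrix:
    """Pairwise fitted RMSD between every chain/model found in the inputs.

    Mirrors the crystallographic comparison of the eight free GR DBD
    monomers in one asymmetric unit (core Cα, residues 421-491) and of
    free vs DNA-bound structures with shared numbering.
    """
    if isinstance(fragment, str):
        fragment = FRAGMENT_PRESETS[fragment]
    conformations: list[tuple[str, Frame]] = []
    for p in paths:
        p = Path(p)
        frames = read_pdb(p)
        conformations.extend(_split_conformations(frames, p.stem))
    if len(conformations) < 2:
        raise DataError("compare needs at least two conformations in total")
    labels = [lab for lab, _ in conformations]
    spec = fragment.with_chain(None)
    try:
        sels = select_ensemble(
            [f for _, f in conformations], spec, allow_missing=allow_missing
        )
    except SelectionError as exc:
        raise SelectionError(f"while comparing {labels}: {exc}") from exc
    return pairwise_rmsd_matrix([s.coords for s in sels], labels)


@dataclass
class AnalysisBundle:
    """Per-trajectory analysis products."""

    rmsd_series: RmsdSeries
    rmsf_profile: RmsfProfile
    cluster_model: ClusterModel
    variability: VariabilityProfile | None  # None for Cα-only inputs
    state_assignment: StateAssignment | None
    config: dict

    def write(self, out_dir: str | Path) -> Path:
        """Write the TSV/JSON bundle; partial output is removed on failure."""
        out_dir = Path(out_dir)
        tmp = out_dir.with_name(out_dir.name + ".partial")
        if tmp.exists():
            shutil.rmtree(tmp)
        tmp.mkdir(parents=True)
        meta = _metadata(
            self.config,
            n_frames=len(self.rmsd_series.frame_index),
            n_clusters=self.cluster_model.n_clusters,
        )
        try:
            self.rmsd_series.to_tsv(tmp / "rmsd_series.tsv", meta)
            self.rmsf_profile.to_tsv(tmp / "rmsf_profile.tsv", meta)
            self.cluster_model.assignments_tsv(tmp / "cluster_assignments.tsv")
            if self.variability is not None:
                self.variability.to_tsv(tmp / "dihedral_variability.tsv")
            if self.state_assignment is not None:
                with open(tmp / "state_assignments.tsv", "w") as fh:
                    fh.write("frame\tstate\n")
                    for i, lab in enumerate(self.state_assignment.labels):
                        fh.write(f"{i}\t{lab}\n")
            (tmp / "metadata.json").write_text(json.dumps(meta, indent=1) + "\n")
        except Exception:
            shutil.rmtree(tmp, ignore_errors=True)
            raise
        if out_dir.exists():
            shutil.rmtree(out_dir)
        tmp.rename(out_dir)
        return out_dir


def cmd_analyze(
    frames: Sequence[Frame] | str | Path,
    cluster_config: ClusterConfig | None = None,
    fit_fragment: FragmentSpec | str = "core_dbd_md",
    his_residue: int | None = 453,
    allow_missing: bool = False,
) -> AnalysisBundle:
    """Full single-trajectory analysis bundle.

    Runs: even subsampling to the configured frame budget, RMSD time
    series (fit fragment, frame-0 reference), RMSF (fit on the stable
    fragment, measured everywhere it resolves), backbone-dihedral
    variability and His-state classification when backbone atoms are
    present, and fixed-radius clustering of the flexible fragment.
    """
    cluster_config = cluster_config or ClusterConfig()
    if isinstance(frames, (str, Path)):
        frames = read_pdb(frames)
    frames = list(frames)
    if isinstance(fit_fragment, str):
        fit_fragment = FRAGMENT_PRESETS[fit_fragment]
    n = min(cluster_config.n_frames_single, len(frames))
    idx = subsample_evenly(len(frames), n)
    frames = [frames[i] for i in idx]
    config = {
        "cluster": cluster_config.to_dict(),
        "fit_fragment": fit_fragment.name,
        "n_frames": n,
    }
    try:
        series = rmsd_timeseries(frames, fit_fragment, 0, allow_missing)
        profile = rmsf(frames, fit_fragment, allow_missing=allow_missing)
        frag_sels = select_ensemble(
            frames, cluster_config.fragment, allow_missing=allow_missing
        )
        model = kclust(
            np.stack([s.coords for s in frag_sels]),
            cluster_config,
            source_labels=[f.source_label for f in frames],
        )
    except ConfensError as exc:
        raise type(exc)(f"analysis stage failed: {exc}") from exc
    variability = None
    assignment = None
    has_backbone = any(a.atom_name == "C" for a in frames[0].atoms)
    if has_backbone:
        variability = variability_profile(frames)
        if his_residue is not None:
            psi = dihedral_series(frames, his_residue, "psi")
            assignment = assign_states(psi, HIS453_STATES)
    return AnalysisBundle(series, profile, model, variability, assignment, config)


def cmd_combine(
    trajectories: Sequence[tuple[str, Sequence[Frame] | str | Path]],
    cluster_config: ClusterConfig | None = None,
    allow_missing: bool = False,
    out_dir: str | Path | None = None,
) -> tuple[ClusterModel, OccupancyTable, dict]:
    """Combined cross-trajectory clustering with occupancy and overlap.

    Each labelled source contributes evenly spaced frames to a single
    pooled clustering; the occupancy table and the shared-cluster report
    show which conformations different sources have in common.
    """
    cluster_config = cluster_config or ClusterConfig()
    loaded: list[tuple[str, np.ndarray]] = []
    for label, frames in trajectories:
        if isinstance(frames, (str, Path)):
            frames = read_pdb(frames, source_label=label)
        sels = select_ensemble(
            list(frames), cluster_config.fragment, allow_missing=allow_missing
        )
        loaded.append((label, np.stack([s.coords for s in sels])))
    model, table = combined_cluster(loaded, cluster_config)
    report = overlap_report(table, cluster_config.occupancy_floor)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config = cluster_config.to_dict()
        meta = _metadata(config, n_clusters=model.n_clusters)
        table.to_tsv(out_dir / "occupancy.tsv")
        write_overlap_json({**report, "metadata": meta}, out_dir / "overlap.json")
        model.assignments_tsv(out_dir / "cluster_assignments.tsv")
    return model, table, report
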