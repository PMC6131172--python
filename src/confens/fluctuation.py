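"""Per-frame RMSD time series and per-residue RMSF profiles.

The RMSD series tracks global drift of a fragment relative to a reference
conformation (frame 0 by default).  The RMSF profile measures per-residue
flexibility about the iteratively refit ensemble average; by convention the
rigid fit is done on a stable fragment (the core domain) while fluctuations
are measured wherever requested, so that genuinely flexible regions are not
deflated by being part of the fit mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfensError
from .structure_io import FragmentSpec, Frame, select_ensemble
from .superpose import average_structure, batch_kabsch

__all__ = ["RmsdSeries", "RmsfProfile", "rmsd_timeseries", "rmsf"]


@dataclass
class RmsdSeries:
    frame_index: np.ndarray
    rmsd: np.ndarray  # Å
    fit_fragment: FragmentSpec
    reference_label: str

    def to_tsv(self, path: str | Path, metadata: dict | None = None) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            if metadata:
                fh.write("# " + json.dumps(metadata, sort_keys=True) + "\n")
            fh.write("frame\trmsd_angstrom\n")
            for i, r in zip(self.frame_index, self.rmsd):
                fh.write(f"{int(i)}\t{r:.4f}\n")
        return path


@dataclass
class RmsfProfile:
    residue_numbers: np.ndarray
    rmsf: np.ndarray  # Å
    n_frames: int

    def to_tsv(self, path: str | Path, metadata: dict | None = None) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            if metadata:
                fh.write("# " + json.dumps(metadata, sort_keys=True) + "\n")
            fh.write("residue\trmsf_angstrom\n")
            for r, v in zip(self.residue_numbers, self.rmsf):
                fh.write(f"{int(r)}\t{v:.4f}\n")
        return path


def rmsd_timeseries(
    frames: Sequence[Frame],
    spec: FragmentSpec,
    reference: np.ndarray | int = 0,
    allow_missing: bool = False,
) -> RmsdSeries:
    """Fitted RMSD of every frame's fragment selection to a reference.

    ``reference`` is either a frame index into ``frames`` (default 0) or an
    explicit (N, 3) coordinate set matching the selection.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    sels = select_ensemble(frames, spec, allow_missing=allow_missing)
    stack = np.stack([s.coords for s in sels])
    if isinstance(reference, (int, np.integer)):
        ref = stack[int(reference)]
        ref_label = f"frame {int(reference)}"
    else:
        ref = np.asarray(reference, dtype=float)
        ref_label = "external"
    try:
        _, _, rmsds = batch_kabsch(stack, ref)
    except ConfensError as exc:
        raise type(exc)(f"fitting {spec.name!r} series: {exc}") from exc
    return RmsdSeries(np.arange(len(frames)), rmsds, spec, ref_label)


def rmsf(
    frames: Sequence[Frame],
    fit_spec: FragmentSpec,
    measure_spec: FragmentSpec | None = None,
    allow_missing: bool = False,
) -> RmsfProfile:
    """Per-residue RMSF about the ensemble average.

    Frames are superposed on ``fit_spec`` atoms onto the iteratively refit
    average of that selection; fluctuations are then measured on
    ``measure_spec`` atoms (default: same as ``fit_spec``).  A residue's
    value is the RMS fluctuation over its selected atoms:
    RMSF_i = sqrt(<|x_i(t) - <x_i>|^2>_t).
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("RMSF needs >= 2 frames")
    measure_spec = measure_spec or fit_spec
    fit_sels = select_ensemble(frames, fit_spec, allow_missing=allow_missing)
    meas_sels = select_ensemble(frames, measure_spec, allow_missing=allow_missing)
    fit_stack = np.stack([s.coords for s in fit_sels])
    meas_stack = np.stack([s.coords for s in meas_sels])
    avg = average_structure(fit_stack)
    R, t, _ = batch_kabsch(fit_stack, avg.coords)
    aligned = np.einsum("mni,mji->mnj", meas_stack, R) + t[:, None, :]
    mean_pos = aligned.mean(axis=0)
    msf_atom = np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0)
    resnums = meas_sels[0].residue_numbers
    unique = np.unique(resnums)
    per_res = np.array(
        [np.sqrt(msf_atom[resnums == r].mean()) for r in unique]
    )
    return RmsfProfile(unique, per_res, len(frames))
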