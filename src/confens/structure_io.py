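"""Multi-model PDB reading/writing and atom-selection resolution.

A trajectory (or a multi-conformer crystal structure) is represented as a
list of :class:`Frame` objects, one per ``MODEL`` record; a file without
``MODEL`` records yields a single frame.  Atom selections are expressed as
:class:`FragmentSpec` objects (residue range plus atom-name filter) and
resolved into deterministically ordered coordinate sets by :func:`select`.

Named fragment presets for the glucocorticoid-receptor DNA-binding domain
(human numbering) ship in :data:`FRAGMENT_PRESETS`: the lever arm
(450-456), the core DBD (421-491, plus the 421-490 truncation used for
simulation systems), the dimerization loop (457-465) and the short
distorted helix of the second zinc finger (469-473).

Only ``ATOM`` records and zinc ``HETATM`` records are retained; zinc ions
carry ``het=True`` and are excluded from every selection (all fits in this
package are protein-atom based).  Insertion codes are not supported and
raise a parse error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyStructureError,
    PdbParseError,
    SelectionError,
    TopologyError,
)

__all__ = [
    "AtomRecord",
    "Frame",
    "FragmentSpec",
    "SelectionResult",
    "FRAGMENT_PRESETS",
    "read_pdb",
    "write_pdb",
    "select",
    "select_ensemble",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one conformation, in PDB author numbering."""

    serial: int
    atom_name: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite or mis-shaped coordinates: {coords!r}")
        object.__setattr__(self, "coordinates", coords)


@dataclass
class Frame:
    """One conformation: an ordered list of atoms plus provenance."""

    atoms: list[AtomRecord]
    model_index: int = 0
    source_label: str = ""


@dataclass(frozen=True)
class FragmentSpec:
    """A named atom selection: inclusive residue range + atom-name filter."""

    name: str
    residue_range: tuple[int, int]
    chain_id: str | None = None
    atom_names: frozenset[str] = frozenset({"CA"})

    def __post_init__(self) -> None:
        first, last = self.residue_range
        if first > last:
            raise ValueError(f"residue_range reversed: {self.residue_range}")
        if not self.atom_names:
            raise ValueError("atom_names must be non-empty")
        object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    def with_chain(self, chain_id: str | None) -> "FragmentSpec":
        return replace(self, chain_id=chain_id)


#: GR DBD fragment presets, Cα only, human numbering.
FRAGMENT_PRESETS: dict[str, FragmentSpec] = {
    "lever_arm": FragmentSpec("lever_arm", (450, 456)),
    "core_dbd": FragmentSpec("core_dbd", (421, 491)),
    "core_dbd_md": FragmentSpec("core_dbd_md", (421, 490)),
    "d_loop": FragmentSpec("d_loop", (457, 465)),
    "zf2_helix": FragmentSpec("zf2_helix", (469, 473)),
}

# Canonical intra-residue atom order; anything else sorts alphabetically after.
_BACKBONE_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3}


def _atom_sort_key(rec: AtomRecord) -> tuple:
    rank = _BACKBONE_ORDER.get(rec.atom_name, 4)
    return (rec.chain_id, rec.residue_number, rank, rec.atom_name)


# ---------------------------------------------------------------------------
# parsing


def _parse_atom_line(line: str, lineno: int, het: bool) -> AtomRecord:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # serials overflow in large files; never load-bearing
    name = line[12:16].strip()
    alt_loc = line[16].strip()
    res_name = line[17:20].strip()
    chain_id = line[21].strip()
    icode = line[26].strip()
    if icode:
        raise PdbParseError(
            f"line {lineno}: insertion code {icode!r} unsupported"
        )
    try:
        res_num = int(line[22:26])
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
    except (ValueError, IndexError) as exc:
        raise PdbParseError(
            f"line {lineno}: malformed coordinate/residue field: {exc}"
        ) from exc
    try:
        occ = float(line[54:60])
    except (ValueError, IndexError):
        occ = 1.0
    try:
        b = float(line[60:66])
    except (ValueError, IndexError):
        b = 0.0
    return AtomRecord(
        serial=serial,
        atom_name=name,
        alt_loc=alt_loc,
        residue_name=res_name,
        chain_id=chain_id,
        residue_number=res_num,
        coordinates=xyz,
        occupancy=occ,
        b_factor=b,
        het=het,
    )


def read_pdb(path: str | Path, source_label: str = "") -> list[Frame]:
    """Read a (multi-model) PDB file into one Frame per MODEL record.

    Files without MODEL records yield a single frame (model_index 0).
    Non-zinc HETATM records (waters, buffer components) are skipped.
    """
    path = Path(path)
    label = source_label or path.stem
    frames: list[Frame] = []
    current: list[AtomRecord] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                if in_model and current:
                    frames.append(Frame(current, len(frames), label))
                    current = []
                in_model = True
            elif record == "ENDMDL":
                frames.append(Frame(current, len(frames), label))
                current = []
                in_model = False
            elif record == "ATOM":
                current.append(_parse_atom_line(line, lineno, het=False))
            elif record == "HETATM":
                rec = _parse_atom_line(line, lineno, het=True)
                if rec.residue_name in ("ZN", "ZN2"):
                    current.append(rec)
    if current:
        frames.append(Frame(current, len(frames), label))
    if not frames or all(not f.atoms for f in frames):
        raise EmptyStructureError(f"{path}: no ATOM records found")
    frames = [f for f in frames if f.atoms]
    for i, f in enumerate(frames):
        f.model_index = i
    return frames


# ---------------------------------------------------------------------------
# writing

_PDB_ATOM_FMT = (
    "{rec:<6s}{serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
    "{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}\n"
)


def _format_atom_name(name: str) -> str:
    # Columns 13-16: names up to 3 chars start in column 14.
    return f" {name:<3s}" if len(name) < 4 else name


def write_pdb(frames: Sequence[Frame], path: str | Path) -> Path:
    """Write frames as a multi-model PDB; coordinates at 3-decimal precision."""
    if not frames:
        raise ValueError("cannot write an empty frame list")
    n0 = len(frames[0].atoms)
    for i, f in enumerate(frames):
        if len(f.atoms) != n0:
            raise TopologyError(
                f"frame {i} has {len(f.atoms)} atoms, expected {n0}"
            )
    path = Path(path)
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for f in frames:
            if multi:
                fh.write(f"MODEL     {f.model_index + 1:>4d}\n")
            for j, a in enumerate(f.atoms, start=1):
                fh.write(
                    _PDB_ATOM_FMT.format(
                        rec="HETATM" if a.het else "ATOM",
                        serial=j if a.serial == 0 else a.serial,
                        name=_format_atom_name(a.atom_name),
                        alt=a.alt_loc or " ",
                        res=a.residue_name,
                        chain=a.chain_id or "A",
                        resnum=a.residue_number,
                        x=a.coordinates[0],
                        y=a.coordinates[1],
                        z=a.coordinates[2],
                        occ=a.occupancy,
                        b=a.b_factor,
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


# ---------------------------------------------------------------------------
# selection


@dataclass
class SelectionResult:
    """An ordered coordinate set plus the atoms and indices it came from."""

    coords: np.ndarray  # (N, 3)
    atoms: list[AtomRecord]
    index_map: np.ndarray  # indices into the source frame's atom list
    residue_numbers: np.ndarray  # per selected atom

    def __len__(self) -> int:
        return len(self.atoms)


def _resolve_alt_locs(
    candidates: list[tuple[int, AtomRecord]]
) -> tuple[int, AtomRecord]:
    """Highest occupancy wins; ties go to the lexicographically first alt_loc."""
    return min(candidates, key=lambda ia: (-ia[1].occupancy, ia[1].alt_loc))


def _residue_atoms(
    frame: Frame, spec: FragmentSpec
) -> dict[tuple[str, int], dict[str, tuple[int, AtomRecord]]]:
    """Map (chain, residue) -> atom_name -> (frame index, record), alt-locs resolved.

    Every protein residue in range appears as a key, even when it carries
    none of the requested atom names — completeness is judged downstream.
    """
    first, last = spec.residue_range
    grouped: dict[tuple[str, int], dict[str, list[tuple[int, AtomRecord]]]] = {}
    for i, a in enumerate(frame.atoms):
        if a.het:  # zinc ions etc. never enter fitting selections
            continue
        if spec.chain_id is not None and a.chain_id != spec.chain_id:
            continue
        if not (first <= a.residue_number <= last):
            continue
        res_key = (a.chain_id, a.residue_number)
        grouped.setdefault(res_key, {})
        if a.atom_name in spec.atom_names:
            grouped[res_key].setdefault(a.atom_name, []).append((i, a))
    return {
        res_key: {name: _resolve_alt_locs(cands) for name, cands in by_name.items()}
        for res_key, by_name in grouped.items()
    }


def select(
    frame: Frame, spec: FragmentSpec, allow_missing: bool = False
) -> SelectionResult:
    """Resolve a fragment selection on one frame.

    Atoms are returned in ascending (chain, residue number, canonical
    backbone order N/CA/C/O then alphabetical).  Residues in range that
    miss one of the requested atom names raise :class:`SelectionError`
    unless ``allow_missing`` is set, in which case the incomplete residue
    is dropped.  For multi-frame comparisons use :func:`select_ensemble`,
    which drops such residues consistently from all frames.
    """
    per_res = _residue_atoms(frame, spec)
    if not per_res:
        raise SelectionError(
            f"selection {spec.name!r} (residues {spec.residue_range[0]}-"
            f"{spec.residue_range[1]}, atoms {sorted(spec.atom_names)}, "
            f"chain {spec.chain_id or 'any'}) matches no atoms"
        )
    wanted = spec.atom_names
    chosen: list[tuple[int, AtomRecord]] = []
    for res_key in sorted(per_res):
        by_name = per_res[res_key]
        missing = wanted - set(by_name)
        if missing:
            if allow_missing:
                continue
            raise SelectionError(
                f"residue {res_key[0]}{res_key[1]} lacks atom(s) "
                f"{sorted(missing)} required by selection {spec.name!r}; "
                "pass allow_missing=True to drop incomplete residues"
            )
        chosen.extend(by_name.values())
    if not chosen:
        raise SelectionError(
            f"selection {spec.name!r}: every matching residue is incomplete"
        )
    chosen.sort(key=lambda ia: _atom_sort_key(ia[1]))
    idx = np.array([i for i, _ in chosen], dtype=int)
    atoms = [a for _, a in chosen]
    coords = np.array([a.coordinates for a in atoms])
    resnums = np.array([a.residue_number for a in atoms], dtype=int)
    return SelectionResult(coords, atoms, idx, resnums)


def select_ensemble(
    frames: Iterable[Frame], spec: FragmentSpec, allow_missing: bool = False
) -> list[SelectionResult]:
    """Resolve one selection consistently across frames.

    Without ``allow_missing`` the residue sets must match exactly across
    frames (a mismatch raises :class:`TopologyError`, never a silent
    truncation).  With ``allow_missing`` a residue incomplete in ANY frame
    is dropped from ALL frames, so the returned coordinate sets stay paired.
    """
    frames = list(frames)
    sels = [select(f, spec, allow_missing=allow_missing) for f in frames]
    keys = [
        tuple((a.chain_id, a.residue_number, a.atom_name) for a in s.atoms)
        for s in sels
    ]
    if all(k == keys[0] for k in keys):
        return sels
    if not allow_missing:
        raise TopologyError(
            f"selection {spec.name!r} resolves to different atom sets across "
            "frames; pass allow_missing=True to intersect residues"
        )
    common = set(keys[0])
    for k in keys[1:]:
        common &= set(k)
    if not common:
        raise SelectionError(
            f"selection {spec.name!r}: no residue is complete in every frame"
        )
    out = []
    for s in sels:
        mask = np.array(
            [
                (a.chain_id, a.residue_number, a.atom_name) in common
                for a in s.atoms
            ]
        )
        out.append(
            SelectionResult(
                s.coords[mask],
                [a for a, m in zip(s.atoms, mask) if m],
                s.index_map[mask],
                s.residue_numbers[mask],
            )
        )
    return out
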