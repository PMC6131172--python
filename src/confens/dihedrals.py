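"""Backbone torsions, circular statistics and angular-state classification.

Torsion angles follow the IUPAC convention: degrees in (-180, 180], cis = 0,
trans = 180, sign by the atan2 formulation.  phi(i) is the C(i-1)-N(i)-CA(i)-C(i)
torsion and psi(i) the N(i)-CA(i)-C(i)-N(i+1) torsion, so phi is undefined at a
chain's N-terminus and psi at its C-terminus; missing bridging atoms mark the
affected angle as missing rather than fabricating a value.

Angular states (e.g. the His453 backbone-psi "out" state at 143 +/- 20 degrees
and "in" state at -28 +/- 11 degrees of the GR DBD lever arm) are modelled as
labelled circular distributions; :func:`assign_states` classifies a dihedral
time series by windowed nearest-mean and counts state-to-state transitions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateGeometryError
from .structure_io import Frame

__all__ = [
    "DihedralValue",
    "DihedralSeries",
    "AngularState",
    "VariabilityProfile",
    "StateAssignment",
    "HIS453_OUT",
    "HIS453_IN",
    "HIS453_INTERMEDIATE",
    "HIS453_STATES",
    "dihedral",
    "backbone_dihedrals",
    "dihedral_series",
    "circular_mean_sd",
    "circular_distance",
    "variability_profile",
    "assign_states",
]


def _wrap_deg(x):
    """Wrap degrees into (-180, 180]."""
    w = np.asarray(x, dtype=float) % 360.0
    w = np.where(w > 180.0, w - 360.0, w)
    w = np.where(w == -180.0, 180.0, w)
    return w if w.ndim else float(w)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle about the p2-p3 axis, degrees in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if min(np.linalg.norm(b1), nb2, np.linalg.norm(b3)) < 1e-9:
        raise DegenerateGeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-9:
        raise DegenerateGeometryError("three consecutive points are collinear")
    y = np.dot(np.cross(n1, n2), b2) / nb2
    x = np.dot(n1, n2)
    return _wrap_deg(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# per-residue backbone angles


@dataclass(frozen=True)
class DihedralValue:
    """One residue's phi or psi in one conformation; value None when undefined."""

    residue_number: int
    angle_name: str  # "phi" | "psi"
    value: float | None
    reason: str | None = None  # why missing, when value is None


@dataclass
class DihedralSeries:
    """One residue's phi or psi across frames, degrees in (-180, 180]."""

    residue_number: int
    angle_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any((v <= -180.0) | (v > 180.0)):
            raise ValueError("dihedral values must lie in (-180, 180]")
        self.values = v


def _backbone_index(frame: Frame, chain_id: str | None):
    idx: dict[tuple[str, int, str], np.ndarray] = {}
    for a in frame.atoms:
        if a.het or a.atom_name not in ("N", "CA", "C"):
            continue
        if chain_id is not None and a.chain_id != chain_id:
            continue
        key = (a.chain_id, a.residue_number, a.atom_name)
        # alt-loc duplicates: keep the first (occupancy resolution is a
        # selection concern; backbone alt-locs do not occur in our inputs)
        idx.setdefault(key, a.coordinates)
    return idx


def backbone_dihedrals(
    frame: Frame,
    residue_range: tuple[int, int] | None = None,
    chain_id: str | None = None,
) -> list[DihedralValue]:
    """phi and psi for every residue of one conformation.

    Residues missing a dependency atom (including chain termini) yield a
    DihedralValue with ``value=None`` and a reason string.
    """
    idx = _backbone_index(frame, chain_id)
    chains: dict[str, list[int]] = {}
    for (ch, resnum, _name) in idx:
        chains.setdefault(ch, [])
        if resnum not in chains[ch]:
            chains[ch].append(resnum)
    out: list[DihedralValue] = []
    for ch in sorted(chains):
        residues = sorted(chains[ch])
        for r in residues:
            if residue_range is not None and not (
                residue_range[0] <= r <= residue_range[1]
            ):
                continue
            for angle, quad in (
                ("phi", [(r - 1, "C"), (r, "N"), (r, "CA"), (r, "C")]),
                ("psi", [(r, "N"), (r, "CA"), (r, "C"), (r + 1, "N")]),
            ):
                pts, missing = [], None
                for rn, an in quad:
                    p = idx.get((ch, rn, an))
                    if p is None:
                        missing = f"missing atom {an} of residue {rn}"
                        break
                    pts.append(p)
                if missing:
                    out.append(DihedralValue(r, angle, None, missing))
                else:
                    out.append(DihedralValue(r, angle, dihedral(*pts)))
    return out


def dihedral_series(
    frames: Sequence[Frame],
    residue_number: int,
    angle_name: str,
    chain_id: str | None = None,
) -> DihedralSeries:
    """One residue's phi or psi tracked across a trajectory."""
    values = []
    for i, f in enumerate(frames):
        vals = {
            (v.residue_number, v.angle_name): v
            for v in backbone_dihedrals(
                f, (residue_number, residue_number), chain_id
            )
        }
        v = vals.get((residue_number, angle_name))
        if v is None or v.value is None:
            reason = v.reason if v else "residue not found"
            raise DegenerateGeometryError(
                f"frame {i}: {angle_name}({residue_number}) undefined ({reason})"
            )
        values.append(v.value)
    return DihedralSeries(residue_number, angle_name, np.array(values))


# ---------------------------------------------------------------------------
# circular statistics


def circular_mean_sd(values: Iterable[float]) -> tuple[float, float]:
    """Circular mean and SD of angles in degrees.

    mean = atan2(<sin>, <cos>); sd = sqrt(-2 ln R) in degrees, with R the
    resultant length.  Nearly uniform samples (R < 1e-12) have no defined
    mean and raise.
    """
    v = np.radians(np.asarray(list(values), dtype=float))
    if v.size == 0:
        raise ValueError("need at least one angle")
    s, c = np.mean(np.sin(v)), np.mean(np.cos(v))
    R = float(np.hypot(s, c))
    if R < 1e-12:
        raise DegenerateGeometryError(
            "circular mean undefined: resultant length ~ 0 (uniform angles)"
        )
    mean = _wrap_deg(np.degrees(np.arctan2(s, c)))
    sd = float(np.degrees(np.sqrt(-2.0 * np.log(R))))
    return float(mean), sd


def circular_distance(a, b):
    """Shortest arc |a - b| on the circle, degrees in [0, 180]."""
    d = np.abs(_wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
    return d if np.ndim(d) else float(d)


def _circular_median(values: np.ndarray) -> float:
    """Sample angle minimizing the summed arc distance (first on ties)."""
    dists = [float(np.sum(circular_distance(values, v))) for v in values]
    return float(values[int(np.argmin(dists))])


def _iqr_nearest(values: np.ndarray) -> float:
    # hinge-style sample quantiles: the two-conformation IQR equals the range
    q25, q75 = np.percentile(values, [25, 75], method="nearest")
    return float(q75 - q25)


@dataclass
class VariabilityProfile:
    """Per-residue IQR of phi and psi across conformations; NaN when undefined."""

    residue_numbers: np.ndarray
    phi_iqr: np.ndarray  # degrees
    psi_iqr: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\tphi_iqr_deg\tpsi_iqr_deg\n")
            for r, p, s in zip(self.residue_numbers, self.phi_iqr, self.psi_iqr):
                fh.write(f"{int(r)}\t{p:.3f}\t{s:.3f}\n")


def variability_profile(
    frames: Sequence[Frame],
    residue_range: tuple[int, int] | None = None,
    chain_id: str | None = None,
) -> VariabilityProfile:
    """Interquartile range of phi and psi per residue over an ensemble.

    Values are unwrapped about their circular median (each observation
    shifted by +/-360 into (median-180, median+180]) before the ordinary
    IQR, so the spread is well defined for residues straddling +/-180.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("variability needs >= 2 conformations")
    collected: dict[tuple[int, str], list[float]] = {}
    for f in frames:
        for dv in backbone_dihedrals(f, residue_range, chain_id):
            if dv.value is not None:
                collected.setdefault(
                    (dv.residue_number, dv.angle_name), []
                ).append(dv.value)
    residues = sorted({r for r, _ in collected})
    phi_iqr, psi_iqr = [], []
    for r in residues:
        row = []
        for angle in ("phi", "psi"):
            vals = collected.get((r, angle))
            if not vals or len(vals) < 2:
                row.append(np.nan)
                continue
            arr = np.asarray(vals)
            med = _circular_median(arr)
            unwrapped = med + _wrap_deg(arr - med)
            row.append(_iqr_nearest(unwrapped))
        phi_iqr.append(row[0])
        psi_iqr.append(row[1])
    return VariabilityProfile(
        np.array(residues), np.array(phi_iqr), np.array(psi_iqr)
    )


# ---------------------------------------------------------------------------
# angular states


@dataclass(frozen=True)
class AngularState:
    """A labelled circular distribution used to classify dihedral values."""

    label: str
    mean: float  # degrees
    sd: float  # degrees
    width_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    @property
    def half_width(self) -> float:
        return self.width_multiplier * self.sd

    def contains(self, value) -> bool:
        return bool(circular_distance(value, self.mean) <= self.half_width)


#: His453 backbone-psi states of the GR DBD lever arm.
HIS453_OUT = AngularState("out", 143.0, 20.0)
HIS453_IN = AngularState("in", -28.0, 11.0)
#: Transient on-pathway intermediate of the out-to-in flip; overlaps the
#: "out" window, so it is not part of the default two-state preset.
HIS453_INTERMEDIATE = AngularState("intermediate", 119.0, 13.0)
HIS453_STATES = [HIS453_OUT, HIS453_IN]

UNASSIGNED = "unassigned"


@dataclass
class StateAssignment:
    """Per-frame state labels plus transition statistics."""

    labels: list[str]
    states: list[AngularState]
    n_transitions: int
    transition_counts: Counter  # (from_label, to_label) -> count

    @property
    def n_assigned(self) -> int:
        return sum(1 for l in self.labels if l != UNASSIGNED)

    @property
    def coverage(self) -> float:
        """Fraction of frames falling inside some state window."""
        return self.n_assigned / len(self.labels) if self.labels else 0.0


def assign_states(
    series: DihedralSeries | np.ndarray, states: Sequence[AngularState]
) -> StateAssignment:
    """Classify a dihedral series by windowed nearest state mean.

    A value is labelled with the state of smallest circular distance among
    the states whose window (mean +/- width_multiplier*sd) contains it;
    values inside no window are "unassigned".  Exact distance ties go to
    the earlier state in the list.  Transitions are counted between
    consecutive distinct assigned labels; unassigned gaps are transparent
    (a -> unassigned -> b counts as one a -> b transition).
    """
    states = list(states)
    if not states:
        raise ValueError("need at least one state")
    values = series.values if isinstance(series, DihedralSeries) else np.asarray(series, dtype=float)
    dists = np.stack([circular_distance(values, s.mean) for s in states])
    inside = dists <= np.array([s.half_width for s in states])[:, None]
    masked = np.where(inside, dists, np.inf)
    best = np.argmin(masked, axis=0)  # argmin takes the first index on ties
    any_inside = inside.any(axis=0)
    labels = [
        states[b].label if ok else UNASSIGNED
        for b, ok in zip(best, any_inside)
    ]
    assigned = [l for l in labels if l != UNASSIGNED]
    transitions: Counter = Counter()
    for a, b in zip(assigned, assigned[1:]):
        if a != b:
            transitions[(a, b)] += 1
    return StateAssignment(labels, states, sum(transitions.values()), transitions)
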