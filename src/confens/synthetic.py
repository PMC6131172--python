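"""Synthetic conformational ensembles and dihedral series with ground truth.

Microsecond MD trajectories are expensive and not redistributable, so every
analysis stage in this package is exercised on generated data whose ground
truth is known exactly:

* :func:`make_reference_states` builds k distinct reference conformations
  of an N-atom Cα trace — a seeded pseudo-random coil at realistic 3.8 Å
  consecutive spacing, plus k-1 variants with a contiguous block smoothly
  displaced and rescaled until every pairwise Kabsch-fitted RMSD sits
  within 5% of a requested target.
* :func:`generate_ensemble` runs a Markov chain over those states and emits
  frames with isotropic Gaussian coordinate noise and (optionally) an
  arbitrary proper rigid motion per frame, returning the true state labels.
* :func:`generate_dihedral_series` emulates a two-state backbone-psi flip
  (e.g. His453 of the GR DBD lever arm: "out" 143 +/- 20 deg, "in"
  -28 +/- 11 deg) as a Markov chain with wrapped-Gaussian emission.
* :func:`build_helical_peptide` constructs an ideal-geometry backbone at
  requested (phi, psi) by internal-coordinate chain extension; it is the
  constructive oracle for the backbone-dihedral code.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .dihedrals import HIS453_IN, HIS453_OUT, AngularState, DihedralSeries
from .structure_io import AtomRecord, Frame
from .superpose import kabsch_fit

__all__ = [
    "EnsembleSpec",
    "EnsembleRealization",
    "DihedralSwitcherSpec",
    "make_reference_states",
    "generate_ensemble",
    "generate_dihedral_series",
    "build_helical_peptide",
    "conformational_selection_presets",
    "uniform_switching_matrix",
]


def uniform_switching_matrix(k: int, stay: float) -> np.ndarray:
    """Row-stochastic k x k matrix with P(stay) on the diagonal."""
    if not (0 < stay <= 1):
        raise ValueError("stay probability must be in (0, 1]")
    if k == 1:
        return np.ones((1, 1))
    T = np.full((k, k), (1.0 - stay) / (k - 1))
    np.fill_diagonal(T, stay)
    return T


def _validate_transition_matrix(T: np.ndarray, k: int) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.shape != (k, k):
        raise ValueError(f"transition matrix must be {k}x{k}, got {T.shape}")
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    return T


@dataclass(frozen=True)
class EnsembleSpec:
    """Ground-truth description of a synthetic conformational ensemble.

    Defaults emulate one GR-DBD-sized Cα trace (70 residues, numbered from
    421) with well-separated lever-arm-scale states: inter-state fitted
    RMSD 6.5 Å and per-coordinate noise 0.2 Å, i.e. within-state fitted
    spread well under 0.5 Å.
    """

    n_atoms: int = 70
    k_states: int = 2
    inter_state_rmsd_target: float = 6.5  # Å, pairwise fitted RMSD between states
    noise_sd: float = 0.2  # Å per coordinate
    n_frames: int = 1000
    transition_matrix: np.ndarray | None = None  # default: uniform, stay 0.95
    rigid_motion: bool = True
    seed: int = 0
    first_residue: int = 421
    source_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_atoms < 4:
            raise ValueError("need >= 4 atoms")
        if self.k_states < 1:
            raise ValueError("k_states must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.k_states > 1 and self.inter_state_rmsd_target <= 0:
            raise ValueError(
                "inter_state_rmsd_target must be positive when k_states > 1"
            )
        T = (
            uniform_switching_matrix(self.k_states, 0.95)
            if self.transition_matrix is None
            else _validate_transition_matrix(self.transition_matrix, self.k_states)
        )
        object.__setattr__(self, "transition_matrix", T)


def _random_coil(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-random Cα trace with exact 3.8 Å consecutive spacing."""
    raw = rng.normal(size=(n_atoms + 6, 3))
    # smooth the step directions along the chain so the coil is tangled but
    # not a white-noise jumble; spacing is enforced exactly by normalization
    kernel = np.ones(5) / 5.0
    smooth = np.stack([np.convolve(raw[:, d], kernel, mode="valid") for d in range(3)], axis=1)
    steps = smooth[:n_atoms - 1]
    norms = np.linalg.norm(steps, axis=1, keepdims=True)
    norms[norms < 1e-6] = 1.0
    coords = np.vstack([np.zeros(3), np.cumsum(3.8 * steps / norms, axis=0)])
    return coords - coords.mean(axis=0)


def _displacement_field(
    n_atoms: int, block: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Smooth random displacement confined to a contiguous atom block."""
    first, last = block
    u = np.zeros((n_atoms, 3))
    raw = rng.normal(size=(last - first + 1 + 8, 3))
    kernel = np.ones(9) / 9.0
    smooth = np.stack(
        [np.convolve(raw[:, d], kernel, mode="valid") for d in range(3)], axis=1
    )
    t = np.linspace(0.0, np.pi, last - first + 1)
    envelope = np.sin(t)[:, None]  # tapers to zero at the block edges
    u[first : last + 1] = smooth * envelope
    rms = np.sqrt(np.mean(np.sum(u**2, axis=1)))
    return u / rms  # unit RMS over the whole chain


def make_reference_states(spec: EnsembleSpec) -> list[np.ndarray]:
    """Build k reference conformations at a calibrated mutual fitted RMSD.

    State 0 is the seeded pseudo-random coil; states 1..k-1 displace a
    contiguous central block with independent smooth random fields whose
    scales are iterated until every pairwise fitted RMSD lies within 5% of
    ``inter_state_rmsd_target``.
    """
    rng = np.random.default_rng(spec.seed)
    coil = _random_coil(spec.n_atoms, rng)
    k = spec.k_states
    if k == 1:
        return [coil]
    target = spec.inter_state_rmsd_target
    # central block spanning half the chain keeps bond stretching gentle
    first = spec.n_atoms // 4
    last = spec.n_atoms - 1 - spec.n_atoms // 4
    raw = [_displacement_field(spec.n_atoms, (first, last), rng) for _ in range(k)]
    # Project the rigid-motion tangent space (translations and rotations
    # about the coil) out of each field so the fitted RMSD between states
    # tracks the designed displacement almost exactly, then orthonormalize.
    n = spec.n_atoms
    cm = coil - coil.mean(axis=0)
    modes = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = 1.0
        modes.append(t.ravel())
    for d in range(3):
        omega = np.zeros(3)
        omega[d] = 1.0
        modes.append(np.cross(omega, cm).ravel())
    Q, _ = np.linalg.qr(np.array(modes).T)
    basis: list[np.ndarray] = []
    for f in raw:
        v = f.ravel().astype(float)
        v -= Q @ (Q.T @ v)
        for b in basis:
            v -= (v @ b) * b
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            raise ValueError("degenerate displacement fields; raise n_atoms")
        basis.append(v / norm)
    # Give every displaced state the same shared component:
    # u_i = (w + v_i)/sqrt(2).  All k states (the coil included) are then
    # mutually equidistant before fitting: |s u_i| = s and
    # |s u_i - s u_j|^2 = s^2 |v_i - v_j|^2 / 2 = s^2.
    w = basis[0]
    fields = [
        ((w + v) / np.sqrt(2.0) * np.sqrt(n)).reshape(n, 3) for v in basis[1:]
    ]  # unit RMS displacement over the chain
    scales = np.full(k - 1, target)

    def build(sc: np.ndarray) -> list[np.ndarray]:
        return [coil] + [coil + s * f for s, f in zip(sc, fields)]

    for _ in range(60):
        states = build(scales)
        d = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d[i, j] = d[j, i] = kabsch_fit(states[i], states[j])[1]
        off = d[np.triu_indices(k, k=1)]
        if np.all(np.abs(off / target - 1.0) <= 0.05):
            return states
        # states 1..k-1: nudge each scale by the geometric-mean miss of its pairs
        for s_idx in range(1, k):
            pair_d = np.concatenate([d[s_idx, :s_idx], d[s_idx, s_idx + 1 :]])
            factor = target / np.exp(np.mean(np.log(pair_d)))
            scales[s_idx - 1] *= factor**0.9
    raise ValueError(
        f"could not calibrate {k} states to pairwise RMSD "
        f"{target:.2f} Å within 5% (n_atoms={spec.n_atoms} may be too small)"
    )


def _markov_chain(
    T: np.ndarray, n: int, rng: np.random.Generator, start: int = 0
) -> np.ndarray:
    states = np.empty(n, dtype=int)
    states[0] = start
    cdf = np.cumsum(T, axis=1)
    draws = rng.random(n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        states[t] = int(np.searchsorted(cdf[states[t - 1]], draws[t - 1]))
    return states


def _ca_frame(
    coords: np.ndarray, model_index: int, label: str, first_residue: int
) -> Frame:
    atoms = [
        AtomRecord(
            serial=i + 1,
            atom_name="CA",
            alt_loc="",
            residue_name="ALA",
            chain_id="A",
            residue_number=first_residue + i,
            coordinates=c,
        )
        for i, c in enumerate(coords)
    ]
    return Frame(atoms, model_index, label)


@dataclass
class EnsembleRealization:
    """A generated ensemble plus its ground truth."""

    spec: EnsembleSpec
    references: list[np.ndarray]
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    state_labels: np.ndarray  # (n_frames,)

    @property
    def frames(self) -> list[Frame]:
        return [
            _ca_frame(c, i, self.spec.source_label, self.spec.first_residue)
            for i, c in enumerate(self.coords)
        ]

    def labels_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frame\tstate\n")
            for i, s in enumerate(self.state_labels):
                fh.write(f"{i}\t{int(s)}\n")


def generate_ensemble(spec: EnsembleSpec) -> EnsembleRealization:
    """Markov-switching ensemble over the reference states.

    Frame t = reference of the current state + i.i.d. Gaussian(0, noise_sd)
    per coordinate, then (optionally) an arbitrary proper rigid motion.
    """
    references = make_reference_states(spec)
    rng = np.random.default_rng((spec.seed, 1))
    chain = _markov_chain(spec.transition_matrix, spec.n_frames, rng)
    coords = np.stack([references[s] for s in chain])
    if spec.noise_sd > 0:
        coords = coords + rng.normal(
            scale=spec.noise_sd, size=coords.shape
        )
    if spec.rigid_motion:
        rots = Rotation.random(spec.n_frames, rng=rng).as_matrix()
        trans = rng.uniform(-20.0, 20.0, size=(spec.n_frames, 3))
        coords = np.einsum("mni,mji->mnj", coords, rots) + trans[:, None, :]
    return EnsembleRealization(spec, references, coords, chain)


# ---------------------------------------------------------------------------
# dihedral switcher


@dataclass(frozen=True)
class DihedralSwitcherSpec:
    """Markov-switching angular series with wrapped-Gaussian emission."""

    states: tuple[AngularState, ...] = (HIS453_OUT, HIS453_IN)
    transition_matrix: np.ndarray | None = None  # default: uniform, stay 0.99
    n_frames: int = 10_000
    seed: int = 0
    residue_number: int = 453
    angle_name: str = "psi"

    def __post_init__(self) -> None:
        states = tuple(self.states)
        if not states:
            raise ValueError("need at least one state")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        T = (
            uniform_switching_matrix(len(states), 0.99)
            if self.transition_matrix is None
            else _validate_transition_matrix(self.transition_matrix, len(states))
        )
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "transition_matrix", T)


def generate_dihedral_series(
    spec: DihedralSwitcherSpec,
) -> tuple[DihedralSeries, np.ndarray]:
    """Generate the series and the ground-truth state labels (as strings)."""
    rng = np.random.default_rng(spec.seed)
    chain = _markov_chain(spec.transition_matrix, spec.n_frames, rng)
    means = np.array([s.mean for s in spec.states])
    sds = np.array([s.sd for s in spec.states])
    raw = means[chain] + rng.normal(size=spec.n_frames) * sds[chain]
    wrapped = ((raw + 180.0) % 360.0) - 180.0
    wrapped[wrapped == -180.0] = 180.0
    series = DihedralSeries(spec.residue_number, spec.angle_name, wrapped)
    truth = np.array([spec.states[s].label for s in chain])
    return series, truth


# ---------------------------------------------------------------------------
# ideal-geometry backbone builder (constructive dihedral oracle)

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.0, 116.6, 120.8
_OMEGA = 180.0


def _place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d so |cd|=bond, angle(b,c,d)=angle, torsion(a,b,c,d)=torsion."""
    angle, torsion = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_helical_peptide(
    n_residues: int,
    phi: float | Sequence[float],
    psi: float | Sequence[float],
    first_residue: int = 1,
    source_label: str = "built",
) -> Frame:
    """Ideal-geometry poly-Ala backbone (N, CA, C, O) at requested (phi, psi).

    ``phi``/``psi`` may be scalars or per-residue sequences (phi of the
    first residue is undefined and its entry unused; psi of the last
    residue only orients that residue's carbonyl).  Round-tripping through
    :func:`confens.dihedrals.backbone_dihedrals` recovers the inputs to
    numerical precision.
    """
    if n_residues < 2:
        raise ValueError("need >= 2 residues")
    phis = np.broadcast_to(np.asarray(phi, dtype=float), (n_residues,)).copy()
    psis = np.broadcast_to(np.asarray(psi, dtype=float), (n_residues,)).copy()
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = [(N, CA, C)]
    for i in range(1, n_residues):
        Np, CAp, Cp = backbone[-1]
        Ni = _place(Np, CAp, Cp, _B_C_N, _A_CA_C_N, psis[i - 1])
        CAi = _place(CAp, Cp, Ni, _B_N_CA, _A_C_N_CA, _OMEGA)
        Ci = _place(Cp, Ni, CAi, _B_CA_C, _A_N_CA_C, phis[i])
        backbone.append((Ni, CAi, Ci))
    atoms: list[AtomRecord] = []
    serial = 1
    for i, (Ni, CAi, Ci) in enumerate(backbone):
        # carbonyl O lies opposite the next N: torsion N-CA-C-O = psi + 180
        O = _place(Ni, CAi, Ci, _B_C_O, _A_CA_C_O, psis[i] + 180.0)
        for name, xyz in (("N", Ni), ("CA", CAi), ("C", Ci), ("O", O)):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=name,
                    alt_loc="",
                    residue_name="ALA",
                    chain_id="A",
                    residue_number=first_residue + i,
                    coordinates=xyz,
                )
            )
            serial += 1
    return Frame(atoms, 0, source_label)


# ---------------------------------------------------------------------------
# presets


def conformational_selection_presets(
    seed: int = 0, n_frames: int = 4000
) -> dict[str, EnsembleSpec]:
    """Three stand-in trajectories mirroring the conformational-selection trend.

    The DNA-free GR DBD samples many lever-arm conformations, the
    IR-GBS-bound monomers an intermediate number, and the GBS-bound
    monomers very few; the presets emulate this with 12, 6 and 2
    accessible well-separated states respectively.
    """
    ks = {"free": 12, "IR-GBS": 6, "GBS": 2}
    return {
        label: EnsembleSpec(
            k_states=k,
            n_frames=n_frames,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
            source_label=label,
        )
        for i, (label, k) in enumerate(ks.items())
    }
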