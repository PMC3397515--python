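"""Synthetic filaments and trajectories with known ground truth.

Two generators back the whole test surface of the package:

* Toy helical Cα filaments of prescribed rise, twist and radius. The sign
  of the twist sets the handedness, so a left-handed and a right-handed
  analog of a RecA/RadA-like filament differ only by the twist sign. A
  quartet of such states (left-handed, ring-like bend, intermediate
  twist, right-handed) stands in for the four conformations of the
  filament rotary cycle.

* Trajectories built from internal coordinates in which designated
  residues' phi/psi torsions complete a programmed integer number of full
  360° turns, with optional Gaussian jitter applied in dihedral space.
  Because the noise lives in angle space, the programmed winding numbers
  are exact ground truth for CCDA recovery.

Backbone geometry uses conventional idealized peptide internal
coordinates (N–CA 1.46 Å, CA–C′ 1.52 Å, C′–N 1.33 Å, angles 111–121.7°,
omega 180°).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Structure, Trajectory, superpose

__all__ = [
    "FilamentSpec",
    "RotationProgram",
    "make_filament",
    "make_state_quartet",
    "make_rotation_trajectory",
    "build_backbone",
    "place_atom",
]

# idealized peptide internal coordinates, Å / degrees
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
OMEGA = 180.0


@dataclass
class FilamentSpec:
    """Helical filament parameters; twist sign encodes handedness."""

    n_residues: int = 24
    rise: float = 3.8  # Å per residue
    twist: float = 100.0  # degrees per residue; negative = left-handed
    radius: float = 2.3  # Å
    with_backbone: bool = False

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("n_residues must be ≥ 4")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if not (-180.0 < self.twist <= 180.0):
            raise ValueError("twist must lie in (−180, 180]")


@dataclass
class RotationProgram:
    """Programmed integer windings per (residue_id, angle_kind).

    ``windings`` maps (residue_id, "phi"|"psi") to a signed integer number
    of full turns completed linearly across ``n_frames``. All other
    dihedrals receive jitter only. Feasibility requires the per-frame step
    |w|·360/n_frames to stay below 180° so the series can be unwound.
    """

    windings: dict[tuple[int, str], int] = field(default_factory=dict)
    n_frames: int = 100
    noise_sd: float = 0.0  # degrees
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for (rid, kind), w in self.windings.items():
            if kind not in ("phi", "psi"):
                raise ValueError(f"unknown angle kind {kind!r}")
            if abs(w) * 360.0 / self.n_frames >= 180.0:
                raise ValueError(
                    f"infeasible program: residue {rid} {kind} winding {w} "
                    f"over {self.n_frames} frames steps ≥ 180°/frame")


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d so |cd| = bond, ∠bcd = angle, torsion(a,b,c,d) = torsion.

    Standard internal-coordinate (NeRF) placement; angle and torsion in
    degrees.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.cos(tor) * np.sin(ang),
        -np.sin(tor) * np.sin(ang),  # sign fixes IUPAC torsion handedness
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis, psis, omegas=None, residue_names=None,
                   first_residue_id: int = 1) -> Structure:
    """Build an N–CA–C′ backbone chain from phi/psi (and omega) torsions.

    ``phis[i]``/``psis[i]`` are the torsions of residue i (phi of the
    first residue and psi of the last are irrelevant to the geometry and
    may be NaN). Returns a Structure with N, CA, C roles per residue.
    """
    phis = np.asarray(phis, dtype=float)
    psis = np.asarray(psis, dtype=float)
    n = len(phis)
    if len(psis) != n:
        raise ValueError("phis and psis must have equal length")
    omegas = np.full(n, OMEGA) if omegas is None else np.asarray(omegas, dtype=float)
    coords = np.zeros((3 * n, 3))
    # seed triad: N1 at origin, CA1 along x, C1 in the xy plane
    coords[0] = (0.0, 0.0, 0.0)
    coords[1] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    coords[2] = coords[1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        base = 3 * i
        # N(i+1): torsion psi(i) about CA(i)-C(i)
        coords[base] = place_atom(coords[base - 3], coords[base - 2], coords[base - 1],
                                  BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        # CA(i+1): torsion omega(i) about C(i)-N(i+1)
        coords[base + 1] = place_atom(coords[base - 2], coords[base - 1], coords[base],
                                      BOND_N_CA, ANGLE_C_N_CA, omegas[i - 1])
        # C(i+1): torsion phi(i+1) about N(i+1)-CA(i+1)
        coords[base + 2] = place_atom(coords[base - 1], coords[base], coords[base + 1],
                                      BOND_CA_C, ANGLE_N_CA_C, phis[i])
    names = residue_names if residue_names is not None else ["ALA"] * n
    return Structure(
        residue_ids=np.repeat(np.arange(first_residue_id, first_residue_id + n), 3),
        residue_names=[nm for nm in names for _ in range(3)],
        atom_roles=["N", "CA", "C"] * n,
        coords=coords,
    )


def _helix_ca(n: int, rise: float, twist: float, radius: float) -> np.ndarray:
    i = np.arange(n)
    theta = np.radians(twist) * i
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])


def _arc_ca(n: int, rise: float, bend_fraction: float = 0.75) -> np.ndarray:
    """Cα positions on a planar circular arc covering ``bend_fraction`` turns."""
    total = bend_fraction * 2.0 * np.pi
    arc_len = rise * (n - 1)
    radius = arc_len / total
    theta = np.linspace(0.0, total, n)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                            np.zeros(n)])


def _decorate_backbone(ca: np.ndarray) -> np.ndarray:
    """Add N and C′ atoms around each Cα of an arbitrary Cα curve.

    Atoms are placed in the local Frenet-like frame of the curve with
    idealized bond lengths, giving a generic (non-collinear) backbone so
    phi/psi are defined everywhere.
    """
    n = len(ca)
    tangents = np.gradient(ca, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    coords = np.zeros((3 * n, 3))
    up = np.array([0.12, 0.96, 0.26])
    for i in range(n):
        t = tangents[i]
        side = np.cross(t, up)
        nrm = np.linalg.norm(side)
        if nrm < 1e-8:  # tangent parallel to reference up-vector
            side = np.cross(t, np.array([1.0, 0.0, 0.0]))
            nrm = np.linalg.norm(side)
        side /= nrm
        lift = np.cross(side, t)
        coords[3 * i] = ca[i] - BOND_N_CA * (0.80 * t + 0.45 * lift + 0.40 * side)
        coords[3 * i + 1] = ca[i]
        coords[3 * i + 2] = ca[i] + BOND_CA_C * (0.80 * t - 0.45 * lift + 0.40 * side)
    return coords


def make_filament(spec: FilamentSpec) -> Structure:
    """Generate a helical filament Structure from a FilamentSpec.

    Cα atoms sit exactly on the helix (radius, rise, twist); negating the
    twist yields the mirror-image filament. With ``with_backbone`` each
    residue additionally carries idealized N and C′ atoms so phi/psi
    torsions are defined.
    """
    ca = _helix_ca(spec.n_residues, spec.rise, spec.twist, spec.radius)
    return _structure_from_ca(ca, spec.with_backbone)


def _structure_from_ca(ca: np.ndarray, with_backbone: bool) -> Structure:
    n = len(ca)
    if with_backbone:
        coords = _decorate_backbone(ca)
        return Structure(
            residue_ids=np.repeat(np.arange(1, n + 1), 3),
            residue_names=["ALA"] * (3 * n),
            atom_roles=["N", "CA", "C"] * n,
            coords=coords,
        )
    return Structure(
        residue_ids=np.arange(1, n + 1),
        residue_names=["ALA"] * n,
        atom_roles=["CA"] * n,
        coords=ca,
    )


def make_state_quartet(base: FilamentSpec, min_separation: float = 1.0):
    """Four congruent-topology states standing in for the filament cycle.

    Returns (left-handed helix, ring-like bend, intermediate-twist helix,
    right-handed helix), all with the same residue ids and atom count, and
    verifies that every pair is separated by more than ``min_separation``
    Å fitted Cα RMSD so the states are genuinely distinct.
    """
    t = abs(base.twist)
    n, rise, radius = base.n_residues, base.rise, base.radius
    curves = [
        _helix_ca(n, rise, -t, radius),          # left-handed
        _arc_ca(n, rise),                        # closed-ring analog
        _helix_ca(n, rise, 0.45 * t, 2.2 * radius),  # intermediate
        _helix_ca(n, rise, t, radius),           # right-handed
    ]
    states = [_structure_from_ca(c, base.with_backbone) for c in curves]
    for i in range(4):
        for j in range(i + 1, 4):
            d = superpose(states[i], states[j], selection=("CA",)).rmsd
            if d <= min_separation:
                raise ValueError(
                    f"quartet states {i} and {j} too similar ({d:.2f} Å fitted RMSD)")
    return tuple(states)


def _backbone_zmatrix(top: Structure):
    """Extract (bonds, angles, torsions) of the N–CA–C chain of ``top``."""
    from .dihedrals import dihedral_angle  # local import avoids a cycle

    x = top.coords
    n_atoms = top.n_atoms
    bonds = np.linalg.norm(np.diff(x, axis=0), axis=1)
    angles = np.zeros(n_atoms - 2)
    for i in range(n_atoms - 2):
        v1 = x[i] - x[i + 1]
        v2 = x[i + 2] - x[i + 1]
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angles[i] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    torsions = np.array([dihedral_angle(x[i], x[i + 1], x[i + 2], x[i + 3])
                         for i in range(n_atoms - 3)])
    return bonds, angles, torsions


def _rebuild_from_zmatrix(top: Structure, bonds, angles, torsions) -> np.ndarray:
    coords = np.zeros((top.n_atoms, 3))
    coords[:3] = top.coords[:3]
    for k in range(3, top.n_atoms):
        coords[k] = place_atom(coords[k - 3], coords[k - 2], coords[k - 1],
                               bonds[k - 1], angles[k - 2], torsions[k - 3])
    return coords


def make_rotation_trajectory(topology: Structure, program: RotationProgram) -> Trajectory:
    """Trajectory in which programmed phi/psi torsions wind by w·360° exactly.

    Frames are rebuilt from the topology's internal coordinates; each
    programmed torsion advances linearly from its base value to base +
    w·360° across frames, with Gaussian jitter of ``noise_sd`` degrees
    added per frame (and jitter-only motion on all other backbone
    torsions). The ground-truth CCDA of the output is 360·|w| for every
    programmed entry and 0 elsewhere whenever noise_sd is modest (≲20°).
    """
    roles = topology.atom_roles
    if roles[:3] != ["N", "CA", "C"]:
        raise ValueError("topology must carry N, CA, C backbone roles")
    bonds, angles, base_torsions = _backbone_zmatrix(topology)
    resids = [int(r) for r in topology.residue_order]
    # chain-torsion index k (atoms k..k+3) → (residue_id, angle kind)
    # atom layout: N_i, CA_i, C_i → torsion starting at N_i is psi_i,
    # at CA_i is omega_i, at C_i is phi_{i+1}
    kind_of: dict[int, tuple[int, str]] = {}
    for k in range(len(base_torsions)):
        role = roles[k]
        res_pos = k // 3
        if role == "N":
            kind_of[k] = (resids[res_pos], "psi")
        elif role == "C":
            kind_of[k] = (resids[res_pos + 1], "phi")
        # omega torsions stay fixed (planar peptide bond)

    for key in program.windings:
        if key not in kind_of.values():
            raise ValueError(f"programmed dihedral {key} not present in topology")

    rng = np.random.default_rng(program.seed)
    nf = program.n_frames
    progress = np.linspace(0.0, 1.0, nf)
    frames = np.empty((nf, topology.n_atoms, 3))
    noise = {k: rng.normal(0.0, program.noise_sd, nf) if program.noise_sd > 0
             else np.zeros(nf)
             for k in kind_of}
    for f in range(nf):
        tors = base_torsions.copy()
        for k, key in kind_of.items():
            w = program.windings.get(key, 0)
            tors[k] = base_torsions[k] + w * 360.0 * progress[f] + noise[k][f]
        frames[f] = _rebuild_from_zmatrix(topology, bonds, angles, tors)
    return Trajectory(topology, frames, np.arange(nf, dtype=float))
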