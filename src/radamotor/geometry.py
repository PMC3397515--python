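"""Structures, trajectories, PDB I/O, optimal superposition and RMSD.

This module is the geometric substrate for the targeted-MD restraint and
for RMSD profile analysis: coarse-grained protein structures carrying
backbone atom roles (N, CA, C), multi-frame trajectories, least-squares
rigid superposition (Kabsch family, determinant-corrected so only proper
rotations are returned), and the analytic gradient of the best-fit RMSD
with respect to the mobile coordinates.

Units: coordinates in Å, times in ns, residue numbering 1-based (PDB
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "Trajectory",
    "SuperpositionResult",
    "PdbParseError",
    "read_pdb",
    "write_pdb",
    "superpose",
    "rmsd",
    "rmsd_gradient",
]

BACKBONE_ROLES = ("N", "CA", "C")

#: below this best-fit RMSD (Å) the RMSD gradient is defined as zero
RMSD_GRADIENT_FLOOR = 1e-8


class PdbParseError(ValueError):
    """Raised for malformed PDB records; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class Structure:
    """A coarse-grained structure: per-atom roles, residue labels, coordinates.

    Atoms are grouped by residue; when backbone roles are present each
    residue's atoms appear in N, CA, C order so that phi/psi torsions can
    be read directly off consecutive atoms.
    """

    residue_ids: np.ndarray  # per atom, 1-based
    residue_names: list[str]  # per atom, 3-letter codes
    atom_roles: list[str]  # per atom, in {"N", "CA", "C"}
    coords: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        n = len(self.residue_ids)
        if not (n == len(self.residue_names) == len(self.atom_roles) == len(self.coords)):
            raise ValueError("per-atom arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.residue_ids) >= 0):
            raise ValueError("atoms must be grouped by strictly increasing residue_ids")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def residue_order(self) -> np.ndarray:
        """Residue ids in chain order (unique, strictly increasing)."""
        _, idx = np.unique(self.residue_ids, return_index=True)
        return self.residue_ids[np.sort(idx)]

    def role_indices(self, roles=("CA",)) -> np.ndarray:
        roles = set(roles)
        return np.array([i for i, r in enumerate(self.atom_roles) if r in roles], dtype=int)

    def atom_index(self, residue_id: int, role: str) -> int | None:
        hits = np.where((self.residue_ids == residue_id)
                        & (np.array(self.atom_roles) == role))[0]
        return int(hits[0]) if hits.size else None

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.residue_ids.copy(), list(self.residue_names),
                         list(self.atom_roles), np.asarray(coords, dtype=float))

    def sequence(self) -> str:
        """One-letter sequence over residues (X for unknown 3-letter codes)."""
        first = {}
        for rid, name in zip(self.residue_ids, self.residue_names):
            first.setdefault(int(rid), name)
        return "".join(_THREE_TO_ONE.get(first[r].upper(), "X")
                       for r in self.residue_order)


@dataclass
class Trajectory:
    """Ordered frames sharing one Structure topology; times in ns."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,), ns, strictly increasing

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SuperpositionResult:
    """Rigid transform minimizing RMSD over a selection: x ↦ R x + t."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å, after transform

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM / MODEL / ENDMDL records)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    name = line[12:16].strip()
    resname = line[17:20].strip() or "UNK"
    try:
        resseq = int(line[22:26])
    except ValueError:
        raise PdbParseError(f"non-integer residue number {line[22:26]!r}", lineno)
    try:
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except ValueError:
        raise PdbParseError(f"non-numeric coordinate field in {line[30:54]!r}", lineno)
    return name, resname, resseq, xyz


def read_pdb(path, roles=BACKBONE_ROLES):
    """Read a PDB file into a Structure, or a Trajectory if multi-MODEL.

    Only atoms whose names are in ``roles`` (default N, CA, C) are kept.
    Raises :class:`PdbParseError` (with the line number) on malformed
    records and on files with no usable atoms.
    """
    roles = set(roles)
    models: list[list] = []
    current: list = []
    in_model = False
    n_model_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(current)
                current = []
                in_model = True
                n_model_records += 1
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PdbParseError("truncated ATOM record", lineno)
                name, resname, resseq, xyz = _parse_atom_line(line, lineno)
                if name in roles:
                    current.append((name, resname, resseq, xyz))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PdbParseError(f"no usable atoms (roles {sorted(roles)}) in {path}")

    def to_structure(atoms):
        return Structure(
            residue_ids=np.array([a[2] for a in atoms]),
            residue_names=[a[1] for a in atoms],
            atom_roles=[a[0] for a in atoms],
            coords=np.array([a[3] for a in atoms]),
        )

    top = to_structure(models[0])
    if n_model_records <= 1 and len(models) == 1:
        return top
    frames = []
    for m in models:
        if len(m) != top.n_atoms:
            raise PdbParseError("MODEL blocks differ in atom count")
        frames.append([a[3] for a in m])
    return Trajectory(top, np.array(frames), np.arange(len(frames), dtype=float))


def write_pdb(obj, path):
    """Write a Structure (single model) or Trajectory (multi-MODEL) as PDB.

    Coordinates are written with 3 decimals, so read_pdb∘write_pdb is the
    identity on coordinates to 1e-3 Å. Non-finite coordinates are refused
    with the offending atom index.
    """
    if isinstance(obj, Trajectory):
        top, frames = obj.topology, obj.frames
    else:
        top, frames = obj, None
    check = top.coords if frames is None else frames
    bad = np.argwhere(~np.isfinite(check))
    if bad.size:
        raise ValueError(f"non-finite coordinate at atom index {int(bad[0][-2])}")

    def atom_lines(coords, out):
        serial = 1
        for i in range(top.n_atoms):
            name = top.atom_roles[i]
            pdb_name = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = coords[i]
            out.append(
                f"ATOM  {serial:5d} {pdb_name}{'':1s}{top.residue_names[i]:>3s} A"
                f"{int(top.residue_ids[i]):4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}"
            )
            serial += 1

    lines: list[str] = []
    if frames is None:
        atom_lines(top.coords, lines)
    else:
        for k, fr in enumerate(frames, start=1):
            lines.append(f"MODEL {k:8d}")
            atom_lines(fr, lines)
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _as_coords(obj) -> np.ndarray:
    return obj.coords if isinstance(obj, Structure) else np.asarray(obj, dtype=float)


def _select(obj, selection):
    coords = _as_coords(obj)
    if selection is None:
        return coords
    if isinstance(obj, Structure):
        return coords[obj.role_indices(selection)]
    return coords  # bare arrays are assumed pre-selected


def _check_nondegenerate(a: np.ndarray, b: np.ndarray):
    if len(a) != len(b):
        raise ValueError(f"selection atom counts differ: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    for pts in (a, b):
        c = pts - pts.mean(axis=0)
        # all-collinear point sets leave the rotation about the line free
        if np.linalg.matrix_rank(c, tol=1e-9) < 2:
            raise ValueError("degenerate (collinear) selection geometry")


def superpose(mobile, reference, selection=None) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimizing the RMSD of
    R·x + t against the reference over the selection, together with the
    minimized RMSD. Reflections are never returned (determinant-corrected
    fit), so mirror-image structures retain a nonzero RMSD.
    """
    mob = _select(mobile, selection)
    ref = _select(reference, selection)
    _check_nondegenerate(mob, ref)
    mob_mean = mob.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_mean, mob - mob_mean)
    rmat = rot.as_matrix()
    trans = ref_mean - rmat @ mob_mean
    # recompute from the transform: rmsd equals rmsd-after-transform exactly
    dev = mob @ rmat.T + trans - ref
    return SuperpositionResult(
        rotation=rmat,
        translation=trans,
        rmsd=float(np.sqrt(np.mean(np.sum(dev ** 2, axis=1)))),
    )


def rmsd(a, b, fit: bool = True, selection=None) -> float:
    """RMSD between two coordinate sets in Å.

    With ``fit=True`` (the default everywhere in this package, matching
    the best-fit convention of targeted-MD restraints) the mobile set is
    optimally superposed first; with ``fit=False`` the raw deviation is
    returned.
    """
    ca = _select(a, selection)
    cb = _select(b, selection)
    if len(ca) != len(cb):
        raise ValueError(f"atom counts differ: {len(ca)} vs {len(cb)}")
    if fit:
        return superpose(ca, cb).rmsd
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def rmsd_gradient(mobile, target, selection=None) -> np.ndarray:
    """∂RMSD/∂x for every mobile atom, after best-fit superposition.

    The target is superposed onto the mobile coordinates and the gradient
    of the fitted RMSD with respect to the mobile coordinates is

        g_i = (x_i − y′_i) / (N · RMSD)

    for selected atoms i (y′ the fitted target), zero elsewhere. The
    optimal rotation and translation are stationary, so their implicit
    dependence on x contributes nothing (envelope theorem). At RMSD below
    a small floor the gradient is defined as the zero vector: the fitted
    RMSD is non-differentiable at its minimum, and the restraint force
    vanishes there anyway whenever RMSD0 = RMSD.
    """
    mob_all = _as_coords(mobile)
    if isinstance(mobile, Structure) and selection is not None:
        idx = mobile.role_indices(selection)
    else:
        idx = np.arange(len(mob_all))
    mob = mob_all[idx]
    tgt = _select(target, selection)
    sup = superpose(tgt, mob)  # fit target onto mobile
    fitted_tgt = sup.apply(tgt)
    grad = np.zeros_like(mob_all)
    if sup.rmsd < RMSD_GRADIENT_FLOOR:
        return grad
    n = len(mob)
    grad[idx] = (mob - fitted_tgt) / (n * sup.rmsd)
    return grad
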