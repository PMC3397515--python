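"""Backbone phi/psi time series, angle unwinding, and the CCDA statistic.

CCDA (cumulative changes in backbone dihedral angles) quantifies, per
residue and per backbone torsion, how many complete 360° rotations the
angle performed over a trajectory. Phi is the torsion C′(i−1)–N(i)–CA(i)–
C′(i); psi is N(i)–CA(i)–C′(i)–N(i+1). Because reported CCDA values for
rotary-motor linker residues are quantized to multiples of 360°, the
statistic is defined here as

    CCDA = 360° × |net winding number of the unwound angle series|

where the unwound series maps each per-frame step into (−180°, 180°] and
accumulates. Residues whose CCDA is zero for both angles are classified
zero-rotary (rotation axes of the conformational cycle); all others in
the analysed region are rotary. A residue lacking a defined phi (chain
start) or psi (chain end) carries an explicit NaN marker, never a silent
zero.

Unwinding assumes per-frame angular steps below 180°; trajectory output
strides must be chosen accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import Structure, Trajectory

__all__ = [
    "DihedralSeries",
    "CCDATable",
    "RotaryClassification",
    "DihedralError",
    "dihedral_angle",
    "phi_psi_series",
    "unwind",
    "ccda",
    "ccda_table",
    "classify_rotary",
    "load_reference_linker_table",
]


class DihedralError(ValueError):
    """Raised when a torsion angle is geometrically undefined."""


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion about p2–p3 in degrees, IUPAC convention, in (−180, 180].

    Zero for a cis (eclipsed) arrangement, 180 for trans. Raises
    :class:`DihedralError` when three consecutive points are collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DihedralError("undefined dihedral: three consecutive points collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = float(np.degrees(np.arctan2(m1 @ n2, n1 @ n2)))
    return 180.0 if ang <= -180.0 else ang


def _wrap_step(delta: np.ndarray) -> np.ndarray:
    """Map angular differences into (−180, 180]."""
    return 180.0 - (180.0 - delta) % 360.0


@dataclass
class DihedralSeries:
    """Per-frame values of one backbone torsion of one residue, in degrees."""

    residue_id: int
    angle_kind: str  # "phi" | "psi"
    raw: np.ndarray | None  # per-frame, in (−180, 180]; None if undefined
    unwound: np.ndarray | None = None

    @property
    def defined(self) -> bool:
        return self.raw is not None

    @property
    def winding(self) -> float | None:
        """Net number of full turns over the series (signed, not rounded)."""
        if self.unwound is None:
            return None
        return float((self.unwound[-1] - self.unwound[0]) / 360.0)


def phi_psi_series(traj: Trajectory, topology: Structure | None = None) -> list[DihedralSeries]:
    """Compute phi and psi series for every residue of a trajectory.

    The first residue has no phi and the last no psi; those series are
    returned with ``raw=None``, as is any residue missing a backbone atom.
    """
    top = topology if topology is not None else traj.topology
    resids = [int(r) for r in top.residue_order]
    idx = {(int(r), role): top.atom_index(int(r), role)
           for r in resids for role in ("N", "CA", "C")}
    out: list[DihedralSeries] = []
    for k, rid in enumerate(resids):
        specs = {
            "phi": None if k == 0 else (idx[(resids[k - 1], "C")], idx[(rid, "N")],
                                        idx[(rid, "CA")], idx[(rid, "C")]),
            "psi": None if k == len(resids) - 1 else (idx[(rid, "N")], idx[(rid, "CA")],
                                                      idx[(rid, "C")], idx[(resids[k + 1], "N")]),
        }
        for kind, quad in specs.items():
            if quad is None or any(i is None for i in quad):
                out.append(DihedralSeries(rid, kind, None))
                continue
            i1, i2, i3, i4 = quad
            try:
                raw = np.array([
                    dihedral_angle(fr[i1], fr[i2], fr[i3], fr[i4]) for fr in traj.frames
                ])
            except DihedralError:
                out.append(DihedralSeries(rid, kind, None))
                continue
            out.append(DihedralSeries(rid, kind, raw))
    return out


def unwind(series: DihedralSeries) -> DihedralSeries:
    """Fill the continuous (unwound) angle series.

    Each per-frame step is mapped into (−180°, 180°] and accumulated, so
    ``unwound[0] == raw[0]`` and the total winding is
    ``(unwound[-1] − unwound[0]) / 360``.
    """
    if series.raw is None:
        return series
    if len(series.raw) < 2:
        raise ValueError("unwinding needs at least 2 frames")
    steps = _wrap_step(np.diff(series.raw))
    series.unwound = series.raw[0] + np.concatenate([[0.0], np.cumsum(steps)])
    return series


def ccda(series: DihedralSeries) -> float:
    """CCDA of one series: 360 × |rounded net winding|, degrees; NaN if undefined."""
    if series.raw is None:
        return float("nan")
    if series.unwound is None:
        unwind(series)
    return 360.0 * abs(round(series.winding))


@dataclass
class CCDATable:
    """Per-residue CCDA values (degrees, multiples of 360; NaN = undefined)."""

    frame: pd.DataFrame  # columns: residue_id, residue_name, ccda_phi, ccda_psi
    region: tuple[int, int]

    def to_tsv(self, path):
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.0f")

    @classmethod
    def from_tsv(cls, path) -> "CCDATable":
        df = pd.read_csv(path, sep="\t")
        ids = df["residue_id"].astype(int)
        return cls(df, (int(ids.min()), int(ids.max())))


def ccda_table(traj: Trajectory, topology: Structure | None = None,
               region: tuple[int, int] | None = None) -> CCDATable:
    """CCDA for every residue in an inclusive residue-id range."""
    top = topology if topology is not None else traj.topology
    order = [int(r) for r in top.residue_order]
    if region is None:
        region = (order[0], order[-1])
    lo, hi = int(region[0]), int(region[1])
    resids = [r for r in order if lo <= r <= hi]
    if not resids:
        raise ValueError(f"empty region {region}")
    names = {}
    for rid, name in zip(top.residue_ids, top.residue_names):
        names.setdefault(int(rid), name)
    values = {(s.residue_id, s.angle_kind): ccda(s)
              for s in phi_psi_series(traj, top)}
    rows = [{
        "residue_id": r,
        "residue_name": names[r],
        "ccda_phi": values.get((r, "phi"), float("nan")),
        "ccda_psi": values.get((r, "psi"), float("nan")),
    } for r in resids]
    return CCDATable(pd.DataFrame(rows), (lo, hi))


@dataclass
class RotaryClassification:
    """Partition of a residue region into rotary and zero-rotary sets."""

    rotary: set[int]
    zero_rotary: set[int]
    undefined: set[int]
    region: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "region": list(self.region),
            "rotary": sorted(self.rotary),
            "zero_rotary": sorted(self.zero_rotary),
            "undefined": sorted(self.undefined),
        }


def classify_rotary(table: CCDATable, skip_undefined: bool = False) -> RotaryClassification:
    """Split the region into zero-rotary (both CCDAs zero) and rotary residues.

    Zero-rotary residues act as axes of the conformational motion; rotary
    residues carry at least one full backbone turn. Undefined entries
    raise unless ``skip_undefined`` is set, in which case they are listed
    separately (never silently counted as zero).
    """
    df = table.frame
    und = df.loc[df[["ccda_phi", "ccda_psi"]].isna().any(axis=1), "residue_id"]
    und = {int(r) for r in und}
    if und and not skip_undefined:
        raise ValueError(f"undefined CCDA entries for residues {sorted(und)}; "
                         "pass skip_undefined=True to exclude them")
    ok = df[~df["residue_id"].isin(und)]
    zero = {int(r) for r in ok.loc[(ok["ccda_phi"] == 0) & (ok["ccda_psi"] == 0),
                                   "residue_id"]}
    rot = {int(r) for r in ok["residue_id"]} - zero
    return RotaryClassification(rot, zero, und, table.region)


def load_reference_linker_table() -> CCDATable:
    """Published CCDA values for the RadA rotary-motor linker region I71–K88.

    Eighteen residues, phi/psi values in degrees (all multiples of 360),
    as reported for the four-leg filament transition cycle of the
    S. solfataricus RadA protein. Shipped as package data so the
    classification logic can be exercised against the published pattern.
    """
    with resources.files("radamotor.data").joinpath("linker_ccda_reference.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return CCDATable(df, (int(df["residue_id"].min()), int(df["residue_id"].max())))
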