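"""Backbone geometry primitives.

Internal-coordinate / Cartesian interconversion (NeRF-style atom placement),
dihedral and bond-angle measurement, Kabsch superposition and the loop RMSD
metrics used to evaluate decoys.

Conventions
-----------
* Dihedrals follow the IUPAC sign convention, in degrees, canonicalized to the
  half-open range [-180, 180).
* Coordinates are numpy arrays of shape (3,), in Angstrom.
* A chain break is declared where the C(i)-N(i+1) distance exceeds 2.0 A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CHAIN_BREAK_CN",
    "InternalCoordinate",
    "ResidueId",
    "BackboneResidue",
    "BackboneStructure",
    "GeometryError",
    "wrap_angle",
    "dihedral",
    "bond_angle",
    "place_atom",
    "measure_internal",
    "kabsch_superpose",
    "loop_rmsd",
    "backbone_phi_psi",
]

#: C(i)-N(i+1) distance (A) beyond which consecutive residues are not bonded.
CHAIN_BREAK_CN = 2.0

_COLLINEAR_TOL = 1e-8


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear/coincident points)."""


@dataclass(frozen=True)
class InternalCoordinate:
    """Bond length (A), bond angle (deg, (0,180)) and dihedral (deg, [-180,180))."""

    bond_length: float
    bond_angle: float
    dihedral: float

    def __post_init__(self) -> None:
        if not (self.bond_length > 0 and math.isfinite(self.bond_length)):
            raise ValueError(f"bond_length must be positive, got {self.bond_length}")
        if not (0.0 < self.bond_angle < 180.0):
            raise ValueError(f"bond_angle must be in (0,180), got {self.bond_angle}")
        object.__setattr__(self, "dihedral", wrap_angle(self.dihedral))


@dataclass(frozen=True, order=True)
class ResidueId:
    """Author residue identifier: chain, sequence number, insertion code."""

    chain: str
    seqnum: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "H100A"
        return f"{self.chain}{self.seqnum}{self.icode}"


@dataclass
class BackboneResidue:
    """One residue reduced to backbone (+CB) heavy atoms.

    ``atoms`` maps atom name (N, CA, C, O, CB) to a (3,) coordinate array.
    N, CA and C must be present; CB is absent for glycine.
    """

    residue_name: str
    residue_id: ResidueId
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("N", "CA", "C"):
            if name not in self.atoms:
                raise ValueError(
                    f"residue {self.residue_id} missing backbone atom {name}"
                )
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}

    def copy(self) -> "BackboneResidue":
        return BackboneResidue(
            self.residue_name,
            self.residue_id,
            {k: v.copy() for k, v in self.atoms.items()},
        )


class BackboneStructure:
    """An ordered list of backbone residues, possibly spanning chain breaks."""

    def __init__(self, residues: Iterable[BackboneResidue]):
        self.residues: list[BackboneResidue] = list(residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __iter__(self):
        return iter(self.residues)

    def copy(self) -> "BackboneStructure":
        return BackboneStructure(r.copy() for r in self.residues)

    def chain_breaks(self) -> list[int]:
        """Indices i where residue i and i+1 are NOT peptide-bonded."""
        breaks = []
        for i in range(len(self.residues) - 1):
            a, b = self.residues[i], self.residues[i + 1]
            if a.residue_id.chain != b.residue_id.chain:
                breaks.append(i)
                continue
            d = float(np.linalg.norm(b.atoms["N"] - a.atoms["C"]))
            if d > CHAIN_BREAK_CN:
                breaks.append(i)
        return breaks

    def segments(self) -> list[tuple[int, int]]:
        """Contiguous peptide-bonded segments as (start, end) inclusive index pairs."""
        breaks = set(self.chain_breaks())
        segs, start = [], 0
        for i in range(len(self.residues)):
            if i in breaks or i == len(self.residues) - 1:
                segs.append((start, i))
                start = i + 1
        return segs

    def index_of(self, rid: ResidueId) -> int:
        for i, r in enumerate(self.residues):
            if r.residue_id == rid:
                return i
        raise KeyError(f"residue {rid} not in structure")


# ---------------------------------------------------------------------------
# Angle measurement
# ---------------------------------------------------------------------------

def wrap_angle(deg: float) -> float:
    """Canonicalize an angle in degrees to [-180, 180)."""
    return float((deg + 180.0) % 360.0 - 180.0)


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _COLLINEAR_TOL or nv < _COLLINEAR_TOL:
        raise GeometryError("coincident points in bond_angle")
    cosang = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def dihedral(p0, p1, p2, p3) -> float:
    """IUPAC-signed dihedral p0-p1-p2-p3 in degrees, wrapped to [-180, 180)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < _COLLINEAR_TOL:
        raise GeometryError("coincident central atoms in dihedral")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < _COLLINEAR_TOL or np.linalg.norm(w) < _COLLINEAR_TOL:
        raise GeometryError("collinear atoms in dihedral")
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return wrap_angle(math.degrees(math.atan2(y, x)))


# ---------------------------------------------------------------------------
# NeRF placement and its inverse
# ---------------------------------------------------------------------------

def place_atom(a, b, c, ic: InternalCoordinate) -> np.ndarray:
    """Place atom d from the frame of atoms a, b, c.

    The returned point satisfies |d-c| = bond_length, angle(b,c,d) = bond_angle
    and dihedral(a,b,c,d) = dihedral (natural extension reference frame).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < _COLLINEAR_TOL:
        raise GeometryError("coincident b, c in place_atom")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL:
        raise GeometryError("collinear a, b, c in place_atom")
    n = n / nn
    m = np.cross(n, bc)
    ang = math.radians(ic.bond_angle)
    dih = math.radians(ic.dihedral)
    d_local = np.array(
        [
            -ic.bond_length * math.cos(ang),
            ic.bond_length * math.sin(ang) * math.cos(dih),
            ic.bond_length * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_internal(a, b, c, d) -> InternalCoordinate:
    """Inverse of :func:`place_atom`: recover (length, angle, dihedral) of d."""
    c = np.asarray(c, float)
    d = np.asarray(d, float)
    length = float(np.linalg.norm(d - c))
    if length < _COLLINEAR_TOL:
        raise GeometryError("coincident c, d in measure_internal")
    return InternalCoordinate(length, bond_angle(b, c, d), dihedral(a, b, c, d))


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: Sequence[np.ndarray], reference: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation 3x3, translation 3, rmsd). The transform maps a mobile
    point x to R @ x + t.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape:
        raise ValueError(f"length mismatch: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[0] < 3 or P.shape[1] != 3:
        raise ValueError("need at least 3 points of dimension 3")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    P0 = P - cp
    Q0 = Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return R, t, rmsd


_MODE_ATOMS = {"backbone": ("N", "CA", "C", "O"), "carbonyl_CO": ("C", "O")}


def _gather(struct: BackboneStructure, indices: Iterable[int], names) -> np.ndarray:
    pts = []
    for i in indices:
        res = struct.residues[i]
        for nm in names:
            if nm not in res.atoms:
                raise ValueError(f"residue {res.residue_id} missing atom {nm}")
            pts.append(res.atoms[nm])
    return np.asarray(pts, float)


def loop_rmsd(
    decoy: BackboneStructure,
    native: BackboneStructure,
    loop_indices: Sequence[int],
    mode: str = "backbone",
    loop_subset: Sequence[int] | None = None,
) -> float:
    """RMSD over loop atoms after superposing the rest of the structure.

    ``decoy`` and ``native`` must have the same residue ordering.  The
    framework (every residue NOT in ``loop_indices``) is superposed on N, CA,
    C atoms; the resulting transform is applied to the decoy loop, and the
    RMSD is computed over the loop atoms selected by ``mode`` (``backbone`` =
    N, CA, C, O; ``carbonyl_CO`` = C, O).  ``loop_subset`` optionally restricts
    the measured residues to a sub-span of ``loop_indices`` (e.g. the antibody
    H3 95-100x convention) while the superposition region is unchanged.
    """
    if mode not in _MODE_ATOMS:
        raise ValueError(f"unknown mode {mode!r}")
    if len(decoy) != len(native):
        raise ValueError("decoy and native must have equal residue counts")
    loop_set = set(loop_indices)
    frame = [i for i in range(len(native)) if i not in loop_set]
    if len(frame) < 1:
        raise ValueError("no framework residues to superpose on")
    P = _gather(decoy, frame, ("N", "CA", "C"))
    Q = _gather(native, frame, ("N", "CA", "C"))
    R, t, _ = kabsch_superpose(P, Q)
    measured = list(loop_subset) if loop_subset is not None else list(loop_indices)
    names = _MODE_ATOMS[mode]
    dl = _gather(decoy, measured, names) @ R.T + t
    nl = _gather(native, measured, names)
    diff = dl - nl
    return float(np.sqrt((diff ** 2).sum() / dl.shape[0]))


def backbone_phi_psi(struct: BackboneStructure) -> list[tuple[float | None, float | None]]:
    """Per-residue (phi, psi) in degrees; None at termini/chain breaks."""
    breaks = set(struct.chain_breaks())
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(struct.residues):
        phi = psi = None
        if i > 0 and (i - 1) not in breaks:
            prev = struct.residues[i - 1]
            phi = dihedral(prev.atoms["C"], res.atoms["N"], res.atoms["CA"], res.atoms["C"])
        if i < len(struct) - 1 and i not in breaks:
            nxt = struct.residues[i + 1]
            psi = dihedral(res.atoms["N"], res.atoms["CA"], res.atoms["C"], nxt.atoms["N"])
        out.append((phi, psi))
    return out
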