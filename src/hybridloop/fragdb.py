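"""Loop fragment database: extraction, splitting, indexing and queries.

Loops are located with a simplified dihedral-window secondary-structure
assignment, extracted together with three residues of flanking context on
each side, and split into every contiguous fragment of 3-30 residues.  Each
fragment stores per-residue internal coordinates (so it can be regrown onto a
new framework), its sequence, per-residue Ramachandran-region environment
labels, and an anchor-geometry signature (the four cross distances between
the CA atoms of the two residues on each side of the fragment).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import (
    BackboneResidue,
    BackboneStructure,
    InternalCoordinate,
    backbone_phi_psi,
    bond_angle,
    dihedral,
    place_atom,
)

log = logging.getLogger(__name__)

__all__ = [
    "MIN_FRAGMENT_LEN",
    "MAX_FRAGMENT_LEN",
    "FLANK",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "ramachandran_region",
    "assign_secondary_structure",
    "LoopRecord",
    "extract_loops",
    "extract_h3_record",
    "ResidueGeometry",
    "AnchorGeometry",
    "Fragment",
    "split_fragments",
    "FragmentDatabase",
    "build_database",
    "query",
]

#: Fragment length bounds: all possible fragments of 3-30 residues.
MIN_FRAGMENT_LEN = 3
MAX_FRAGMENT_LEN = 30
#: Residues of context kept on each side of an extracted loop.
FLANK = 3

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

ENVIRONMENTS = ("alpha", "beta", "alphaL", "other")


def ramachandran_region(phi: float | None, psi: float | None) -> str:
    """Coarse Ramachandran environment label in {alpha, beta, alphaL, other}.

    Residues with undefined dihedrals (termini) are labelled ``other``.
    """
    if phi is None or psi is None:
        return "other"
    if phi < 0.0:
        return "alpha" if -100.0 <= psi < 60.0 else "beta"
    return "alphaL" if -60.0 <= psi < 110.0 else "other"


# ---------------------------------------------------------------------------
# Secondary structure (dihedral-window stand-in for DSSP) and loop extraction
# ---------------------------------------------------------------------------

def _window_label(phi: float | None, psi: float | None) -> str:
    if phi is None or psi is None:
        return "C"
    if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
        return "H"
    if -170.0 <= phi <= -70.0 and (90.0 <= psi < 180.0 or psi < -170.0):
        return "E"
    return "C"


def _runs(labels: Sequence[str]) -> list[tuple[str, int, int]]:
    """(label, start, end) runs, end inclusive."""
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        runs.append((labels[i], i, j))
        i = j + 1
    return runs


def assign_secondary_structure(struct: BackboneStructure) -> list[str]:
    """Per-residue H/E/C label from phi/psi windows, with 3-residue smoothing.

    H/E runs shorter than three residues are relabelled C, so every surviving
    secondary-structure element is at least three residues long.
    """
    phipsi = backbone_phi_psi(struct)
    labels = [_window_label(phi, psi) for phi, psi in phipsi]
    # residues adjacent to a chain break cannot continue an element
    for i in set(struct.chain_breaks()):
        pass  # phi/psi are already None across breaks -> labelled C
    smoothed = list(labels)
    for lab, s, e in _runs(labels):
        if lab in ("H", "E") and e - s + 1 < 3:
            for k in range(s, e + 1):
                smoothed[k] = "C"
    return smoothed


@dataclass
class LoopRecord:
    """A loop region plus up to three residues of flanking context each side."""

    source_id: str
    residues: list[BackboneResidue]
    loop_span: tuple[int, int]  # inclusive indices of the loop proper
    source_start: int = 0  # index of residues[0] within the source structure

    @property
    def loop_length(self) -> int:
        return self.loop_span[1] - self.loop_span[0] + 1

    def __len__(self) -> int:
        return len(self.residues)


def extract_loops(struct: BackboneStructure, source_id: str = "") -> list[LoopRecord]:
    """Extract loop records: maximal coil runs connecting H/E elements.

    A coil run qualifies when it is at least three residues long and flanked
    on both sides (within the same peptide-bonded segment) by secondary
    structure elements of at least three residues.  Each record carries up to
    three flanking residues per side.
    """
    labels = assign_secondary_structure(struct)
    records: list[LoopRecord] = []
    for seg_start, seg_end in struct.segments():
        seg_labels = labels[seg_start : seg_end + 1]
        runs = _runs(seg_labels)
        for k, (lab, s, e) in enumerate(runs):
            if lab != "C" or e - s + 1 < 3:
                continue
            if k == 0 or k == len(runs) - 1:
                continue
            prev_lab, ps, pe = runs[k - 1]
            next_lab, ns, ne = runs[k + 1]
            if prev_lab not in "HE" or pe - ps + 1 < 3:
                continue
            if next_lab not in "HE" or ne - ns + 1 < 3:
                continue
            lo = max(0, s - FLANK)
            hi = min(len(seg_labels) - 1, e + FLANK)
            residues = [struct.residues[seg_start + i] for i in range(lo, hi + 1)]
            records.append(
                LoopRecord(
                    source_id=source_id,
                    residues=[r.copy() for r in residues],
                    loop_span=(s - lo, e - lo),
                    source_start=seg_start + lo,
                )
            )
    return records


def extract_h3_record(
    struct: BackboneStructure,
    source_id: str = "",
    chain: str = "H",
    span: tuple[int, int] = (95, 102),
) -> LoopRecord | None:
    """Extract a CDR-H3 style record: author-numbered span on a chain.

    The loop is every residue of ``chain`` whose author number lies in
    ``span`` (insertion codes included), Chothia heavy-chain 95-102 by
    default, plus three flanking residues each side.
    """
    idx = [
        i
        for i, r in enumerate(struct.residues)
        if r.residue_id.chain == chain and span[0] <= r.residue_id.seqnum <= span[1]
    ]
    if not idx or idx != list(range(idx[0], idx[-1] + 1)):
        return None
    lo = max(0, idx[0] - FLANK)
    hi = min(len(struct) - 1, idx[-1] + FLANK)
    residues = [struct.residues[i].copy() for i in range(lo, hi + 1)]
    return LoopRecord(source_id, residues, (idx[0] - lo, idx[-1] - lo), source_start=lo)


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

@dataclass
class ResidueGeometry:
    """Internal coordinates of one residue, relative to its predecessor.

    ``b_cn``, ``a_cacn``, ``a_cnca`` and ``omega`` describe the junction from
    the previous residue's C to this residue's N/CA; ``phi`` additionally
    needs the previous C, ``psi`` the next N.  Fields are None where the
    source record lacked the required neighbouring atoms.
    """

    aa: str  # 1-letter code, 'X' for non-standard
    phi: float | None = None
    psi: float | None = None
    omega: float | None = None
    b_cn: float | None = None
    a_cacn: float | None = None
    a_cnca: float | None = None
    b_nca: float | None = None
    a_ncac: float | None = None
    b_cac: float | None = None


@dataclass(frozen=True)
class AnchorGeometry:
    """The 4 CA-CA cross distances between the two anchors on each side.

    Order: (N2-C1, N2-C2, N1-C1, N1-C2) where N1/N2 are the outer/inner
    N-side anchors and C1/C2 the inner/outer C-side anchors.
    """

    ca_distances: tuple[float, float, float, float]

    def rms_deviation(self, other: "AnchorGeometry") -> float:
        d = np.asarray(self.ca_distances) - np.asarray(other.ca_distances)
        return float(np.sqrt(np.mean(d ** 2)))

    @staticmethod
    def from_anchor_atoms(n1_ca, n2_ca, c1_ca, c2_ca) -> "AnchorGeometry":
        n1, n2, c1, c2 = (np.asarray(p, float) for p in (n1_ca, n2_ca, c1_ca, c2_ca))
        return AnchorGeometry(
            (
                float(np.linalg.norm(n2 - c1)),
                float(np.linalg.norm(n2 - c2)),
                float(np.linalg.norm(n1 - c1)),
                float(np.linalg.norm(n1 - c2)),
            )
        )


@dataclass
class Fragment:
    """A database entry: a window of a loop record, in internal coordinates."""

    source_id: str
    offset: int
    length: int
    sequence: str
    residues: list[ResidueGeometry]
    environments: list[str]
    anchor: AnchorGeometry | None = None
    psi_prev: float | None = None  # psi of the source residue preceding the window
    phi_next: float | None = None  # phi of the source residue following the window

    @property
    def fragment_id(self) -> str:
        return f"{self.source_id}:{self.offset}:{self.length}"

    def reconstruct(self, seed_n, seed_ca, seed_c) -> np.ndarray:
        """Rebuild N/CA/C coordinates from internal coordinates.

        Residue 0 takes the given seed atoms; later residues are placed by
        NeRF extension.  Returns an array of shape (length, 3, 3) ordered
        (N, CA, C) per residue.  Raises if a required field is None.
        """
        coords = np.zeros((self.length, 3, 3))
        coords[0, 0] = np.asarray(seed_n, float)
        coords[0, 1] = np.asarray(seed_ca, float)
        coords[0, 2] = np.asarray(seed_c, float)
        for i in range(1, self.length):
            g = self.residues[i]
            prev_psi = self.residues[i - 1].psi
            if None in (g.b_cn, g.a_cacn, g.a_cnca, g.omega, g.b_nca, g.a_ncac,
                        g.b_cac, g.phi, prev_psi):
                raise ValueError(f"fragment {self.fragment_id}: incomplete geometry")
            pn, pca, pc = coords[i - 1]
            n = place_atom(pn, pca, pc, InternalCoordinate(g.b_cn, g.a_cacn, prev_psi))
            ca = place_atom(pca, pc, n, InternalCoordinate(g.b_nca, g.a_cnca, g.omega))
            c = place_atom(pc, n, ca, InternalCoordinate(g.b_cac, g.a_ncac, g.phi))
            coords[i] = (n, ca, c)
        return coords


def _residue_geometry(record: LoopRecord, i: int) -> ResidueGeometry:
    res = record.residues
    r = res[i]
    aa = THREE_TO_ONE.get(r.residue_name, "X")
    g = ResidueGeometry(
        aa=aa,
        b_nca=float(np.linalg.norm(r.atoms["CA"] - r.atoms["N"])),
        a_ncac=bond_angle(r.atoms["N"], r.atoms["CA"], r.atoms["C"]),
        b_cac=float(np.linalg.norm(r.atoms["C"] - r.atoms["CA"])),
    )
    if i > 0:
        p = res[i - 1]
        g.b_cn = float(np.linalg.norm(r.atoms["N"] - p.atoms["C"]))
        g.a_cacn = bond_angle(p.atoms["CA"], p.atoms["C"], r.atoms["N"])
        g.a_cnca = bond_angle(p.atoms["C"], r.atoms["N"], r.atoms["CA"])
        g.omega = dihedral(p.atoms["CA"], p.atoms["C"], r.atoms["N"], r.atoms["CA"])
        g.phi = dihedral(p.atoms["C"], r.atoms["N"], r.atoms["CA"], r.atoms["C"])
    if i < len(res) - 1:
        n = res[i + 1]
        g.psi = dihedral(r.atoms["N"], r.atoms["CA"], r.atoms["C"], n.atoms["N"])
    return g


def split_fragments(
    record: LoopRecord,
    min_len: int = MIN_FRAGMENT_LEN,
    max_len: int = MAX_FRAGMENT_LEN,
) -> list[Fragment]:
    """All contiguous windows of 3-30 residues of the record.

    Windows with at least two residues of context on each side within the
    record get an anchor signature; edge windows carry none and are only
    retrievable with an infinite anchor tolerance.
    """
    L = len(record)
    if L < min_len:
        return []
    geoms = [_residue_geometry(record, i) for i in range(L)]
    phipsi = [(g.phi, g.psi) for g in geoms]
    frags: list[Fragment] = []
    for k in range(min_len, min(L, max_len) + 1):
        for off in range(L - k + 1):
            window = geoms[off : off + k]
            seq = "".join(g.aa for g in window)
            envs = [ramachandran_region(*phipsi[off + j]) for j in range(k)]
            anchor = None
            if off >= 2 and off + k + 1 <= L - 1:
                anchor = AnchorGeometry.from_anchor_atoms(
                    record.residues[off - 2].atoms["CA"],
                    record.residues[off - 1].atoms["CA"],
                    record.residues[off + k].atoms["CA"],
                    record.residues[off + k + 1].atoms["CA"],
                )
            frags.append(
                Fragment(
                    source_id=record.source_id,
                    offset=off,
                    length=k,
                    sequence=seq,
                    residues=[ResidueGeometry(**vars(g)) for g in window],
                    environments=envs,
                    anchor=anchor,
                    psi_prev=geoms[off - 1].psi if off > 0 else None,
                    phi_next=geoms[off + k].phi if off + k < L else None,
                )
            )
    return frags


# ---------------------------------------------------------------------------
# Database container + text serialization
# ---------------------------------------------------------------------------

_DB_VERSION = "hybridloop-fragdb v1"


class FragmentDatabase:
    """Fragments indexed by length, with corpus metadata."""

    def __init__(self, metadata: dict | None = None):
        self.by_length: dict[int, list[Fragment]] = {}
        self.metadata: dict = metadata or {}

    def add(self, frag: Fragment) -> None:
        self.by_length.setdefault(frag.length, []).append(frag)

    def fragments(self) -> Iterable[Fragment]:
        for length in sorted(self.by_length):
            yield from self.by_length[length]

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_length.values())

    # -- text format --------------------------------------------------------

    @staticmethod
    def _fmt(x: float | None) -> str:
        return "x" if x is None else f"{x:.4f}"

    @staticmethod
    def _parse(s: str) -> float | None:
        return None if s == "x" else float(s)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        lines = [f"#{_DB_VERSION}"]
        for k, v in sorted(self.metadata.items()):
            lines.append(f"#{k}={v}")
        for f in self.fragments():
            anchor = (
                ",".join(f"{d:.4f}" for d in f.anchor.ca_distances)
                if f.anchor is not None
                else "x"
            )
            res = ";".join(
                ",".join(
                    [g.aa]
                    + [
                        self._fmt(x)
                        for x in (g.phi, g.psi, g.omega, g.b_cn, g.a_cacn,
                                  g.a_cnca, g.b_nca, g.a_ncac, g.b_cac)
                    ]
                )
                for g in f.residues
            )
            envs = ",".join(f.environments)
            lines.append(
                "|".join(
                    [
                        f.source_id,
                        str(f.offset),
                        str(f.length),
                        f.sequence,
                        envs,
                        self._fmt(f.psi_prev),
                        self._fmt(f.phi_next),
                        anchor,
                        res,
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FragmentDatabase":
        path = Path(path)
        db = cls()
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
            if first != f"#{_DB_VERSION}":
                raise ValueError(f"unknown fragment database version: {first!r}")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if "=" in line:
                        k, v = line[1:].split("=", 1)
                        db.metadata[k] = v
                    continue
                (src, off, length, seq, envs, psi_prev, phi_next, anchor,
                 res) = line.split("|")
                residues = []
                for chunk in res.split(";"):
                    parts = chunk.split(",")
                    vals = [cls._parse(p) for p in parts[1:]]
                    residues.append(ResidueGeometry(parts[0], *vals))
                a = None
                if anchor != "x":
                    a = AnchorGeometry(tuple(float(x) for x in anchor.split(",")))
                db.add(
                    Fragment(
                        source_id=src,
                        offset=int(off),
                        length=int(length),
                        sequence=seq,
                        residues=residues,
                        environments=envs.split(","),
                        anchor=a,
                        psi_prev=cls._parse(psi_prev),
                        phi_next=cls._parse(phi_next),
                    )
                )
        return db


def build_database(
    corpus: Iterable[str | Path | tuple[str, BackboneStructure]],
    h3_mode: bool = False,
    h3_chain: str = "H",
    h3_span: tuple[int, int] = (95, 102),
) -> FragmentDatabase:
    """Build a fragment database from a corpus of structures.

    ``corpus`` items are either PDB file paths or (source_id, structure)
    pairs.  In H3 mode, loops are the designated author-numbered span on the
    heavy chain instead of DSSP-style coil regions.  Unreadable files are
    logged and skipped.
    """
    from .pipeline import read_structure  # local import to avoid a cycle

    hasher = hashlib.sha256()
    db = FragmentDatabase()
    n_records = 0
    for item in corpus:
        if isinstance(item, tuple):
            source_id, struct = item
        else:
            path = Path(item)
            source_id = path.stem
            try:
                struct = read_structure(path)
            except Exception as exc:  # noqa: BLE001 - skip-and-log contract
                log.warning("skipping unreadable corpus file %s: %s", path, exc)
                continue
        hasher.update(source_id.encode())
        if h3_mode:
            rec = extract_h3_record(struct, source_id, h3_chain, h3_span)
            records = [rec] if rec is not None else []
        else:
            records = extract_loops(struct, source_id)
        for rec in records:
            n_records += 1
            for frag in split_fragments(rec):
                db.add(frag)
    db.metadata.update(
        {
            "corpus_hash": hasher.hexdigest()[:16],
            "h3_mode": str(int(h3_mode)),
            "n_records": str(n_records),
        }
    )
    return db


def query(
    db: FragmentDatabase,
    length: int,
    anchors: AnchorGeometry | None,
    tol: float = 1.0,
    exclude_source: str | set[str] | None = None,
) -> list[Fragment]:
    """Fragments of exactly ``length`` whose anchor signature deviates from
    ``anchors`` by at most ``tol`` (RMS over the 4 CA-CA distances), excluding
    any from the excluded source chains (sequence-identical to the target).
    """
    if not (MIN_FRAGMENT_LEN <= length <= MAX_FRAGMENT_LEN):
        raise ValueError(f"fragment length must be in [3,30], got {length}")
    excluded: set[str]
    if exclude_source is None:
        excluded = set()
    elif isinstance(exclude_source, str):
        excluded = {exclude_source}
    else:
        excluded = set(exclude_source)
    out = []
    for frag in db.by_length.get(length, []):
        if frag.source_id in excluded:
            continue
        if math.isinf(tol):
            out.append(frag)
            continue
        if anchors is None or frag.anchor is None:
            continue
        if frag.anchor.rms_deviation(anchors) <= tol:
            out.append(frag)
    return out
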