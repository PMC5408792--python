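"""Decoy construction: residue-by-residue loop growth.

A decoy of the target length is grown one residue at a time from one of the
two anchor residues.  Target residues paired with a fragment residue in the
sequence alignment copy that residue's internal coordinates exactly; the
rest draw bond lengths/angles from Engh-Huber Gaussian distributions and
(phi, psi) from residue-specific Ramachandran histograms.  The peptide bond
omega is held trans (180 deg) unless copied from a fragment.

The open decoy carries three extra "overlap" atoms: a mobile copy of the far
anchor's N, CA, C built with the anchor's own internal geometry.  Closure
(see :mod:`hybridloop.closure`) drives these onto the real anchor atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fragdb import ONE_TO_THREE, THREE_TO_ONE, Fragment, extract_loops
from .geometry import (
    BackboneResidue,
    BackboneStructure,
    InternalCoordinate,
    backbone_phi_psi,
    bond_angle,
    place_atom,
    wrap_angle,
)
from .selection import AlignmentResult, TargetSpec

__all__ = [
    "RAMA_BIN_WIDTH",
    "RamachandranDistribution",
    "RamachandranSet",
    "estimate_rama_from_structures",
    "resample_h3_distributions",
    "GaussianGeometryParams",
    "ENGH_HUBER",
    "sample_dihedrals",
    "sample_geometry",
    "Decoy",
    "build_decoy",
    "place_carbonyl_oxygen",
    "place_cbeta",
]

#: Ramachandran histogram resolution (degrees per bin, 36x36 grid).
RAMA_BIN_WIDTH = 10.0
_NBINS = int(round(360.0 / RAMA_BIN_WIDTH))

# Ideal carbonyl-O and C-beta geometry (kept fixed; placed after closure).
O_BOND, O_ANGLE = 1.231, 120.8
CB_BOND, CB_ANGLE = 1.530, 110.5
# Improper dihedral C-N-CA-CB for an L-amino acid (verified numerically
# against ideal alanine coordinates).
CB_DIHEDRAL = -122.6


class RamachandranDistribution:
    """Residue-specific 2D histogram over (phi, psi), 10 deg x 10 deg bins."""

    def __init__(self, residue_type: str, probs: np.ndarray):
        probs = np.asarray(probs, float)
        if probs.shape != (_NBINS, _NBINS):
            raise ValueError(f"expected {_NBINS}x{_NBINS} histogram")
        if np.any(probs < 0):
            raise ValueError("negative bin probability")
        total = probs.sum()
        if total <= 0:
            raise ValueError(f"all-zero Ramachandran distribution for {residue_type}")
        if abs(total - 1.0) > 1e-9:
            probs = probs / total
        self.residue_type = residue_type
        self.probs = probs
        self._flat = probs.ravel()
        self._cum = np.cumsum(self._flat)

    @staticmethod
    def bin_index(phi: float, psi: float) -> tuple[int, int]:
        i = int((wrap_angle(phi) + 180.0) // RAMA_BIN_WIDTH)
        j = int((wrap_angle(psi) + 180.0) // RAMA_BIN_WIDTH)
        return min(i, _NBINS - 1), min(j, _NBINS - 1)

    @staticmethod
    def bin_center(i: int, j: int) -> tuple[float, float]:
        return (
            -180.0 + (i + 0.5) * RAMA_BIN_WIDTH,
            -180.0 + (j + 0.5) * RAMA_BIN_WIDTH,
        )

    def prob_at(self, phi: float, psi: float) -> float:
        i, j = self.bin_index(phi, psi)
        return float(self.probs[i, j])

    def allowed(self, phi: float, psi: float, eps: float = 1e-6) -> bool:
        return self.prob_at(phi, psi) > eps

    def sample(self, rng: np.random.Generator) -> tuple[float, float]:
        """Draw a (phi, psi) pair: a bin by probability, then its center."""
        k = int(np.searchsorted(self._cum, rng.random() * self._cum[-1], side="right"))
        k = min(k, self._flat.size - 1)
        return self.bin_center(k // _NBINS, k % _NBINS)

    @classmethod
    def uniform(cls, residue_type: str = "ALL", mask: np.ndarray | None = None):
        """Uniform distribution, optionally restricted to a boolean mask."""
        p = np.ones((_NBINS, _NBINS)) if mask is None else mask.astype(float)
        return cls(residue_type, p / p.sum())


class RamachandranSet:
    """Per-residue-type distributions with a pooled ``ALL`` fallback."""

    VERSION = "hybridloop-rama v1"

    def __init__(self, dists: dict[str, RamachandranDistribution]):
        if "ALL" not in dists:
            raise ValueError("a pooled 'ALL' distribution is required")
        self.dists = dists

    def get(self, residue_type: str) -> RamachandranDistribution:
        key = THREE_TO_ONE.get(residue_type, residue_type)
        return self.dists.get(key, self.dists["ALL"])

    def save(self, path: str | Path) -> None:
        lines = [f"#{self.VERSION}", f"#bin_width={RAMA_BIN_WIDTH}"]
        for key in sorted(self.dists):
            lines.append(f"RES {key}")
            for row in self.dists[key].probs:
                lines.append(" ".join(f"{x:.6e}" for x in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RamachandranSet":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0] != f"#{cls.VERSION}":
            raise ValueError(f"unknown Ramachandran file version in {path}")
        dists: dict[str, RamachandranDistribution] = {}
        key = None
        rows: list[list[float]] = []
        for line in lines[1:]:
            if line.startswith("#"):
                continue
            if line.startswith("RES "):
                if key is not None:
                    dists[key] = RamachandranDistribution(key, np.array(rows))
                key = line.split()[1]
                rows = []
            elif line.strip():
                rows.append([float(x) for x in line.split()])
        if key is not None:
            dists[key] = RamachandranDistribution(key, np.array(rows))
        return cls(dists)

    @classmethod
    def uniform(cls, mask: np.ndarray | None = None) -> "RamachandranSet":
        return cls({"ALL": RamachandranDistribution.uniform("ALL", mask)})


def estimate_rama_from_structures(
    structures: list[tuple[str, BackboneStructure]],
    pseudocount: float = 0.0,
    smooth_sigma: float = 1.0,
) -> RamachandranSet:
    """Residue-specific distributions from the loop residues of a corpus.

    Only loop-proper residues (as located by the secondary-structure based
    extraction) contribute, matching the way the fragment database is built.
    Histograms are smoothed with a wrapped Gaussian kernel of ``smooth_sigma``
    bins (kernel density estimate on the torus), which keeps small corpora
    from producing distributions whose allowed region is a handful of
    isolated bins; set it to 0 for raw counts.
    """
    counts: dict[str, np.ndarray] = {"ALL": np.full((_NBINS, _NBINS), pseudocount)}
    for source_id, struct in structures:
        for rec in extract_loops(struct, source_id):
            phipsi = backbone_phi_psi(BackboneStructure(rec.residues))
            for k in range(rec.loop_span[0], rec.loop_span[1] + 1):
                phi, psi = phipsi[k]
                if phi is None or psi is None:
                    continue
                aa = THREE_TO_ONE.get(rec.residues[k].residue_name, "X")
                i, j = RamachandranDistribution.bin_index(phi, psi)
                counts.setdefault(aa, np.full((_NBINS, _NBINS), pseudocount))
                counts[aa][i, j] += 1
                counts["ALL"][i, j] += 1
    dists = {}
    for key, c in counts.items():
        if c.sum() <= 0:
            continue
        if smooth_sigma > 0:
            from scipy.ndimage import gaussian_filter

            # truncate at 2 sigma so the allowed region stays tight to data
            c = gaussian_filter(c, sigma=smooth_sigma, mode="wrap", truncate=2.0)
        dists[key] = RamachandranDistribution(key, c)
    if "ALL" not in dists:
        raise ValueError("corpus contained no loop residues with defined dihedrals")
    return RamachandranSet(dists)


def resample_h3_distributions(
    general: RamachandranSet, h3: RamachandranSet, weight: float = 0.2
) -> RamachandranSet:
    """Blend sparse H3 dihedral data with general loop data.

    Per residue type the output is the mixture ``(1-w) * h3 + w * general``
    (renormalized); bins populated in either source stay populated for any
    interior weight, which is the point: the H3 histograms become less sparse
    while H3-specific preferences still dominate.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    keys = set(general.dists) | set(h3.dists)
    out = {}
    for key in keys:
        g = general.get(key).probs
        h = h3.get(key).probs
        mix = (1.0 - weight) * h + weight * g
        out[key] = RamachandranDistribution(key, mix)
    return RamachandranSet(out)


# ---------------------------------------------------------------------------
# Gaussian bond-length / bond-angle sampling (Engh-Huber parameters)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianGeometryParams:
    """Mean/sigma per backbone bond and angle type.

    Keys: b_cn (C-N, A), b_nca (N-CA), b_cac (CA-C), a_cacn (CA-C-N, deg),
    a_cnca (C-N-CA), a_ncac (N-CA-C).
    """

    params: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for key, (mu, sigma) in self.params.items():
            if sigma < 0:
                raise ValueError(f"negative sigma for {key}")
            if key.startswith("b_") and not 1.2 <= mu <= 1.6:
                raise ValueError(f"bond mean {mu} for {key} outside 1.2-1.6 A")
            if key.startswith("a_") and not 100.0 <= mu <= 130.0:
                raise ValueError(f"angle mean {mu} for {key} outside 100-130 deg")


#: Engh-Huber backbone restraint values (means/sigmas).
ENGH_HUBER = GaussianGeometryParams(
    {
        "b_cn": (1.329, 0.014),
        "b_nca": (1.458, 0.019),
        "b_cac": (1.525, 0.021),
        "a_cacn": (116.2, 2.0),
        "a_cnca": (121.7, 1.8),
        "a_ncac": (111.2, 2.8),
    }
)


def sample_dihedrals(
    residue_type: str, dist: RamachandranDistribution, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw (phi, psi) for one residue from its Ramachandran distribution."""
    return dist.sample(rng)


def sample_geometry(
    params: GaussianGeometryParams, rng: np.random.Generator
) -> dict[str, float]:
    """Gaussian draws of one residue's bonds/angles, truncated at +-4 sigma."""
    out = {}
    for key, (mu, sigma) in params.params.items():
        if sigma == 0.0:
            out[key] = mu
            continue
        x = rng.normal(mu, sigma)
        for _ in range(16):
            if abs(x - mu) <= 4.0 * sigma:
                break
            x = rng.normal(mu, sigma)
        out[key] = float(min(max(x, mu - 4.0 * sigma), mu + 4.0 * sigma))
    return out


# ---------------------------------------------------------------------------
# Decoy representation
# ---------------------------------------------------------------------------

@dataclass
class Decoy:
    """An open or closed loop decoy.

    ``chain`` holds backbone atoms in build order, three per residue plus the
    three overlap atoms (a mobile copy of the far anchor's N/CA/C); for an
    N-anchor build, position 3i is residue i's N and the chain runs N->C; for
    a C-anchor build the chain runs C->N (position 3r is residue (n-1-r)'s C)
    and the overlap atoms copy the N-side anchor in the order C, CA, N.
    """

    n: int
    restypes: list[str]  # 3-letter codes, loop order (N to C)
    chain: np.ndarray  # (3n+3, 3) build-order coordinates
    phi: np.ndarray  # per loop residue, degrees
    psi: np.ndarray
    omega: np.ndarray
    terminal_dihedral: float  # adjustable dihedral of the overlap extension
    build_anchor: str  # 'N' or 'C'
    provenance: str = "ab_initio"
    decoy_id: str = ""
    closed: bool = False
    energy: float | None = None

    def chain_pos(self, i: int) -> dict[str, int]:
        """Chain indices of residue i's N, CA, C."""
        if self.build_anchor == "N":
            base = 3 * i
            return {"N": base, "CA": base + 1, "C": base + 2}
        base = 3 * (self.n - 1 - i)
        return {"C": base, "CA": base + 1, "N": base + 2}

    def residue_coords(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p = self.chain_pos(i)
        return self.chain[p["N"]], self.chain[p["CA"]], self.chain[p["C"]]

    def loop_structure(self, target: TargetSpec) -> BackboneStructure:
        """Materialize the loop as residues with N, CA, C, O (+CB)."""
        residues = []
        for i in range(self.n):
            npos, ca, c = self.residue_coords(i)
            atoms = {"N": npos.copy(), "CA": ca.copy(), "C": c.copy()}
            atoms["O"] = place_carbonyl_oxygen(npos, ca, c, self.psi[i])
            if self.restypes[i] != "GLY":
                atoms["CB"] = place_cbeta(npos, ca, c)
            residues.append(
                BackboneResidue(self.restypes[i], target.loop_ids[i], atoms)
            )
        return BackboneStructure(residues)


def place_carbonyl_oxygen(n, ca, c, psi: float) -> np.ndarray:
    """Place O in the peptide plane, trans to the next N (psi + 180)."""
    return place_atom(n, ca, c, InternalCoordinate(O_BOND, O_ANGLE, psi + 180.0))


def place_cbeta(n, ca, c) -> np.ndarray:
    """Place an ideal-geometry CB with L-chirality."""
    return place_atom(c, n, ca, InternalCoordinate(CB_BOND, CB_ANGLE, CB_DIHEDRAL))


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

_GEOM_KEYS = ("b_cn", "a_cacn", "a_cnca", "b_nca", "a_ncac", "b_cac")


def _anchor_psi_from_oxygen(res: BackboneResidue) -> float | None:
    """Anchor psi inferred from its carbonyl O (trans across the C=O plane)."""
    if "O" not in res.atoms:
        return None
    from .geometry import dihedral

    return wrap_angle(
        dihedral(res.atoms["N"], res.atoms["CA"], res.atoms["C"], res.atoms["O"]) + 180.0
    )


def _residue_assignment(
    i: int,
    restype3: str,
    frag_map: dict[int, int],
    fragment: Fragment | None,
    rama: RamachandranSet,
    params: GaussianGeometryParams,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Geometry for loop residue i: fragment copy where aligned, else sampled."""
    sampled = sample_geometry(params, rng)
    phi, psi = sample_dihedrals(restype3, rama.get(restype3), rng)
    a = {"phi": phi, "psi": psi, "omega": 180.0, **sampled}
    j = frag_map.get(i)
    if fragment is not None and j is not None:
        g = fragment.residues[j]
        for key in ("phi", "psi", "omega", *_GEOM_KEYS):
            val = getattr(g, key)
            if val is not None:
                a[key] = val
    return a


def build_decoy(
    target: TargetSpec,
    fragment: Fragment | None,
    alignment: AlignmentResult | None,
    anchor: str,
    rama: RamachandranSet,
    params: GaussianGeometryParams = ENGH_HUBER,
    rng: np.random.Generator | None = None,
    provenance: str | None = None,
) -> Decoy:
    """Grow an open decoy from the chosen anchor ('N' or 'C').

    With ``fragment`` and ``alignment`` given, aligned target residues copy
    the fragment residue's internal coordinates exactly; everything else is
    sampled.  ``fragment=None`` is the pure ab initio branch.
    """
    if anchor not in ("N", "C"):
        raise ValueError("anchor must be 'N' or 'C'")
    if rng is None:
        rng = np.random.default_rng()
    n = target.n
    frag_map: dict[int, int] = {}
    if fragment is not None and alignment is not None:
        frag_map = alignment.fragment_for_target()
        if frag_map and (
            min(frag_map) < 0
            or max(frag_map) >= n
            or max(frag_map.values()) >= fragment.length
        ):
            raise ValueError("alignment indices outside target/fragment range")
    restypes = [ONE_TO_THREE.get(aa, "ALA") for aa in target.sequence]
    assign = [
        _residue_assignment(i, restypes[i], frag_map, fragment, rama, params, rng)
        for i in range(n)
    ]
    mean = {k: v[0] for k, v in params.params.items()}

    def _sample_pair(res3: str) -> tuple[float, float]:
        return sample_dihedrals(res3, rama.get(res3), rng)

    chain = np.zeros((3 * n + 3, 3))
    if anchor == "N":
        anc = target.n_anchor
        far = target.c_anchor
        # dihedral attaching loop residue 0's N: psi of the N-side anchor.
        # Its carbonyl O fixes the peptide plane, so infer psi from it when
        # present; otherwise copy from the fragment or sample.
        psi_prev = _anchor_psi_from_oxygen(anc)
        if psi_prev is None and (fragment is not None and frag_map.get(0) == 0):
            psi_prev = fragment.psi_prev
        if psi_prev is None:
            psi_prev = _sample_pair(anc.residue_name)[1]
        prev = (anc.atoms["N"], anc.atoms["CA"], anc.atoms["C"])
        prev_psi = psi_prev
        for i in range(n):
            a = assign[i]
            npos = place_atom(*prev, InternalCoordinate(a["b_cn"], a["a_cacn"], prev_psi))
            ca = place_atom(prev[1], prev[2], npos,
                            InternalCoordinate(a["b_nca"], a["a_cnca"], a["omega"]))
            c = place_atom(prev[2], npos, ca,
                           InternalCoordinate(a["b_cac"], a["a_ncac"], a["phi"]))
            chain[3 * i], chain[3 * i + 1], chain[3 * i + 2] = npos, ca, c
            prev = (npos, ca, c)
            prev_psi = a["psi"]
        # overlap: mobile copy of the C-side anchor, native internal geometry
        b_nca = float(np.linalg.norm(far.atoms["CA"] - far.atoms["N"]))
        b_cac = float(np.linalg.norm(far.atoms["C"] - far.atoms["CA"]))
        a_ncac = bond_angle(far.atoms["N"], far.atoms["CA"], far.atoms["C"])
        term = fragment.phi_next if (fragment is not None
                                     and frag_map.get(n - 1) == fragment.length - 1
                                     and fragment.phi_next is not None) else None
        if term is None:
            term = _sample_pair(far.residue_name)[0]
        n_ov = place_atom(*prev, InternalCoordinate(mean["b_cn"], mean["a_cacn"], prev_psi))
        ca_ov = place_atom(prev[1], prev[2], n_ov,
                           InternalCoordinate(b_nca, mean["a_cnca"], 180.0))
        c_ov = place_atom(prev[2], n_ov, ca_ov,
                          InternalCoordinate(b_cac, a_ncac, term))
        chain[3 * n], chain[3 * n + 1], chain[3 * n + 2] = n_ov, ca_ov, c_ov
    else:
        anc = target.c_anchor
        far = target.n_anchor
        phi_entry = fragment.phi_next if (fragment is not None
                                          and frag_map.get(n - 1) == fragment.length - 1
                                          and fragment.phi_next is not None) else None
        if phi_entry is None:
            phi_entry = _sample_pair(anc.residue_name)[0]
        # reverse chain: seed on the C-side anchor (C, CA, N order)
        prev = (anc.atoms["C"], anc.atoms["CA"], anc.atoms["N"])
        prev_phi = phi_entry
        junction = {"b_cn": mean["b_cn"], "a_cacn": mean["a_cacn"],
                    "a_cnca": mean["a_cnca"], "omega": 180.0}
        for r, i in enumerate(range(n - 1, -1, -1)):
            a = assign[i]
            c = place_atom(*prev,
                           InternalCoordinate(junction["b_cn"], junction["a_cnca"], prev_phi))
            ca = place_atom(prev[1], prev[2], c,
                            InternalCoordinate(a["b_cac"], junction["a_cacn"],
                                               junction["omega"]))
            npos = place_atom(prev[2], c, ca,
                              InternalCoordinate(a["b_nca"], a["a_ncac"], a["psi"]))
            chain[3 * r], chain[3 * r + 1], chain[3 * r + 2] = c, ca, npos
            prev = (c, ca, npos)
            prev_phi = a["phi"]
            junction = {k: a[k] for k in ("b_cn", "a_cacn", "a_cnca")}
            junction["omega"] = a["omega"]
        # overlap: mobile copy of the N-side anchor (C, CA, N order)
        b_nca = float(np.linalg.norm(far.atoms["CA"] - far.atoms["N"]))
        b_cac = float(np.linalg.norm(far.atoms["C"] - far.atoms["CA"]))
        a_ncac = bond_angle(far.atoms["N"], far.atoms["CA"], far.atoms["C"])
        term = _anchor_psi_from_oxygen(far)
        if term is None and (fragment is not None and frag_map.get(0) == 0):
            term = fragment.psi_prev
        if term is None:
            term = _sample_pair(far.residue_name)[1]
        c_ov = place_atom(*prev,
                          InternalCoordinate(junction["b_cn"], junction["a_cnca"], prev_phi))
        ca_ov = place_atom(prev[1], prev[2], c_ov,
                           InternalCoordinate(b_cac, junction["a_cacn"], junction["omega"]))
        n_ov = place_atom(prev[2], c_ov, ca_ov,
                          InternalCoordinate(b_nca, a_ncac, term))
        chain[3 * n], chain[3 * n + 1], chain[3 * n + 2] = c_ov, ca_ov, n_ov

    return Decoy(
        n=n,
        restypes=restypes,
        chain=chain,
        phi=np.array([a["phi"] for a in assign]),
        psi=np.array([a["psi"] for a in assign]),
        omega=np.array([a["omega"] for a in assign]),
        terminal_dihedral=float(term),
        build_anchor=anchor,
        provenance=provenance
        or (fragment.fragment_id if fragment is not None else "ab_initio"),
    )
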