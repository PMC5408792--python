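"""Candidate fragment selection for a target loop.

Implements the length budget (how many fragments, of which lengths, feed the
building stage), Needleman-Wunsch global alignment of fragment to target
sequence scored with environment-specific substitution (ESS) tables, and the
pooled ranking of all candidates.

The fragment budget follows the piecewise rules: the shortest fragment length
considered is n-3 for targets of up to 12 residues and n-4 for longer ones
(floored at 3); fragments must be strictly shorter than the target; and the
number of fragments passed on is 12.5(n-2) for even n and 12.5(n-1) for odd
n, doubled in H3 mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fragdb import (
    ENVIRONMENTS,
    THREE_TO_ONE,
    AnchorGeometry,
    Fragment,
    FragmentDatabase,
    extract_loops,
    ramachandran_region,  # re-export: environment labelling lives with the db
    query,
)
from .geometry import BackboneResidue, BackboneStructure, ResidueId, backbone_phi_psi

log = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "fragment_budget",
    "ramachandran_region",
    "ESSTables",
    "estimate_esst",
    "esst_from_structures",
    "AlignmentResult",
    "nw_align",
    "TargetSpec",
    "rank_fragments",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def fragment_budget(
    n: int, h3_mode: bool = False, multiplier: float = 1.0
) -> tuple[int, int, int]:
    """(min_fragment_length, max_fragment_length, num_fragments) for a target
    loop of length ``n``.

    Fragments are strictly shorter than the target; the H3 variant uses twice
    as many fragments.  ``multiplier`` scales the count for configuration.
    """
    if n < 4:
        raise ValueError(
            f"target length must be >= 4 (no shorter fragment of length >= 3 "
            f"exists for n={n})"
        )
    min_len = max(3, (n - 3) if n <= 12 else (n - 4))
    max_len = min(n - 1, 30)
    count = 12.5 * (n - 2) if n % 2 == 0 else 12.5 * (n - 1)
    if h3_mode:
        count *= 2
    return min_len, max_len, int(round(count * multiplier))


# ---------------------------------------------------------------------------
# Environment-specific substitution tables
# ---------------------------------------------------------------------------

class ESSTables:
    """Per-environment 20x20 substitution scores.

    ``tables[env]`` is a numpy array indexed by (fragment residue, target
    residue) via the order of :data:`AMINO_ACIDS`.  Unknown residues ('X')
    score 0 in every environment.
    """

    VERSION = "hybridloop-esst v1"

    def __init__(self, tables: dict[str, np.ndarray]):
        for env in ENVIRONMENTS:
            if env not in tables:
                raise ValueError(f"missing environment table: {env}")
            t = np.asarray(tables[env], float)
            if t.shape != (20, 20) or not np.all(np.isfinite(t)):
                raise ValueError(f"bad table for environment {env}")
            tables[env] = t
        self.tables = tables

    def score(self, env: str, frag_aa: str, target_aa: str) -> float:
        t = self.tables.get(env)
        if t is None:
            t = self.tables["other"]
        i = _AA_INDEX.get(frag_aa)
        j = _AA_INDEX.get(target_aa)
        if i is None or j is None:
            return 0.0
        return float(t[i, j])

    def save(self, path: str | Path) -> None:
        lines = [f"#{self.VERSION}"]
        for env in ENVIRONMENTS:
            lines.append(f"ENV {env}")
            lines.append("  " + " ".join(AMINO_ACIDS))
            for i, aa in enumerate(AMINO_ACIDS):
                row = " ".join(f"{x:.4f}" for x in self.tables[env][i])
                lines.append(f"{aa} {row}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ESSTables":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0] != f"#{cls.VERSION}":
            raise ValueError(f"unknown ESS table version in {path}")
        tables: dict[str, np.ndarray] = {}
        env = None
        rows: list[list[float]] = []
        for line in lines[1:]:
            if line.startswith("ENV "):
                if env is not None:
                    tables[env] = np.array(rows)
                env = line.split()[1]
                rows = []
            elif line and line[0] in _AA_INDEX:
                rows.append([float(x) for x in line.split()[1:]])
        if env is not None:
            tables[env] = np.array(rows)
        return cls(tables)


def estimate_esst(
    observations: list[tuple[str, str]],
    pseudocount: float = 1.0,
    identity_bonus: float = 2.0,
) -> ESSTables:
    """Estimate ESS tables from (environment, residue) observations.

    Residues sharing a Ramachandran environment are treated as exchangeable:
    the score for substituting fragment residue a for target residue b in
    environment e is the log-odds ln[P(a|e)P(b|e) / (P(a)P(b))] with add-one
    pseudocounts, plus a fixed identity bonus on the diagonal.  This keeps
    the mechanism (environment-conditioned sequence scoring) with transparent
    provenance when the database is built from an arbitrary corpus.
    """
    env_counts = {e: np.full(20, pseudocount) for e in ENVIRONMENTS}
    bg = np.full(20, pseudocount)
    for env, aa in observations:
        i = _AA_INDEX.get(aa)
        if i is None:
            continue
        env_counts.setdefault(env, np.full(20, pseudocount))[i] += 1
        bg[i] += 1
    p_bg = bg / bg.sum()
    tables = {}
    for env in ENVIRONMENTS:
        p = env_counts[env] / env_counts[env].sum()
        ratio = np.log(np.outer(p, p) / np.outer(p_bg, p_bg))
        tables[env] = ratio + identity_bonus * np.eye(20)
    return ESSTables(tables)


def esst_from_structures(
    structures: list[tuple[str, BackboneStructure]],
    pseudocount: float = 1.0,
    identity_bonus: float = 2.0,
) -> ESSTables:
    """Estimate ESS tables from the loop residues of a corpus of structures."""
    obs: list[tuple[str, str]] = []
    for source_id, struct in structures:
        for rec in extract_loops(struct, source_id):
            phipsi = backbone_phi_psi(BackboneStructure(rec.residues))
            for k in range(rec.loop_span[0], rec.loop_span[1] + 1):
                aa = THREE_TO_ONE.get(rec.residues[k].residue_name, "X")
                obs.append((ramachandran_region(*phipsi[k]), aa))
    return estimate_esst(obs, pseudocount, identity_bonus)


# ---------------------------------------------------------------------------
# Needleman-Wunsch alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """Global alignment of a fragment to the target loop sequence.

    ``pairs`` holds (target_index, fragment_index) matches, strictly
    increasing in both indices; ``gaps`` counts unaligned positions
    (end gaps included); ``score`` is the total ESS score.
    """

    pairs: list[tuple[int, int]]
    gaps: int
    score: float

    def fragment_for_target(self) -> dict[int, int]:
        return {t: f for t, f in self.pairs}


def nw_align(
    target_seq: str,
    fragment: Fragment,
    tables: ESSTables,
    gap_penalty: float = 2.0,
) -> AlignmentResult:
    """Global Needleman-Wunsch alignment maximizing the ESS score.

    Matching fragment residue j (in its stored dihedral environment) to
    target residue i scores ``tables[env_j][aa_j][aa_i]``; every gap position
    costs ``gap_penalty``.  Ties in the dynamic program are broken
    deterministically (match > gap-in-fragment > gap-in-target).
    """
    n, m = len(target_seq), fragment.length
    if n == 0 or m == 0:
        raise ValueError("empty sequence in nw_align")
    S = np.empty((n + 1, m + 1))
    S[0, :] = -gap_penalty * np.arange(m + 1)
    S[:, 0] = -gap_penalty * np.arange(n + 1)
    sub = np.empty((n, m))
    for j in range(m):
        env = fragment.environments[j]
        aa_f = fragment.sequence[j]
        for i in range(n):
            sub[i, j] = tables.score(env, aa_f, target_seq[i])
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            S[i, j] = max(
                S[i - 1, j - 1] + sub[i - 1, j - 1],
                S[i - 1, j] - gap_penalty,
                S[i, j - 1] - gap_penalty,
            )
    # deterministic traceback: diagonal, then gap in fragment, then gap in target
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and math.isclose(
            S[i, j], S[i - 1, j - 1] + sub[i - 1, j - 1], abs_tol=1e-12
        ):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and math.isclose(S[i, j], S[i - 1, j] - gap_penalty, abs_tol=1e-12):
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    gaps = (n - len(pairs)) + (m - len(pairs))
    return AlignmentResult(pairs=pairs, gaps=gaps, score=float(S[n, m]))


# ---------------------------------------------------------------------------
# Target specification and candidate ranking
# ---------------------------------------------------------------------------

@dataclass
class TargetSpec:
    """The loop to be modelled.

    ``framework`` is the structure with the loop residues removed;
    ``insert_at`` is the framework index where loop residue 0 goes (i.e. the
    inner N-side anchor is ``framework[insert_at - 1]``).  ``loop_ids`` are
    the author residue ids the built loop residues will carry.  ``native``
    optionally keeps the full input structure (loop included) for RMSD
    evaluation against the experimental conformation.
    """

    framework: BackboneStructure
    insert_at: int
    chain: str
    sequence: str
    loop_ids: list[ResidueId]
    anchors: AnchorGeometry = field(init=False)
    native: BackboneStructure | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.n = len(self.sequence)
        if self.n < 4:
            raise ValueError(f"loop length must be >= 4, got {self.n}")
        if len(self.loop_ids) != self.n:
            raise ValueError("loop_ids length must equal sequence length")
        if self.insert_at < 2 or self.insert_at > len(self.framework) - 2:
            raise ValueError("need two anchor residues on each side of the loop")
        fr = self.framework.residues
        self.anchors = AnchorGeometry.from_anchor_atoms(
            fr[self.insert_at - 2].atoms["CA"],
            fr[self.insert_at - 1].atoms["CA"],
            fr[self.insert_at].atoms["CA"],
            fr[self.insert_at + 1].atoms["CA"],
        )

    # anchor residues ------------------------------------------------------
    @property
    def n_anchor(self) -> BackboneResidue:
        """Inner N-side anchor (peptide-bonded to loop residue 0)."""
        return self.framework.residues[self.insert_at - 1]

    @property
    def c_anchor(self) -> BackboneResidue:
        """Inner C-side anchor (peptide-bonded to the last loop residue)."""
        return self.framework.residues[self.insert_at]

    @classmethod
    def from_structure(
        cls,
        struct: BackboneStructure,
        chain: str,
        loop_start: int,
        loop_end: int,
        sequence: str,
        source_id: str = "",
        keep_native: bool = True,
    ) -> "TargetSpec":
        """Build a target from a full structure containing the loop.

        ``loop_start``/``loop_end`` are inclusive author residue numbers on
        ``chain`` (insertion-coded residues within the span included).  The
        loop residues are excised to form the framework; ``sequence`` must
        match the excised span.
        """
        idx = [
            i
            for i, r in enumerate(struct.residues)
            if r.residue_id.chain == chain
            and loop_start <= r.residue_id.seqnum <= loop_end
        ]
        if not idx or idx != list(range(idx[0], idx[-1] + 1)):
            raise ValueError(
                f"loop span {chain}{loop_start}-{loop_end} not contiguous in input"
            )
        loop_res = [struct.residues[i] for i in idx]
        native_seq = "".join(
            THREE_TO_ONE.get(r.residue_name, "X") for r in loop_res
        )
        if sequence != native_seq:
            raise ValueError(
                f"target sequence {sequence!r} does not match structure span "
                f"{native_seq!r}"
            )
        framework = BackboneStructure(
            r.copy() for i, r in enumerate(struct.residues) if i not in set(idx)
        )
        return cls(
            framework=framework,
            insert_at=idx[0],
            chain=chain,
            sequence=sequence,
            loop_ids=[r.residue_id for r in loop_res],
            native=struct.copy() if keep_native else None,
            source_id=source_id,
        )

    def adjusted_framework(self, loop: BackboneStructure) -> BackboneStructure:
        """Framework with the inner N-anchor's carbonyl O re-placed.

        The anchor's O lies in the amide plane of the anchor-loop peptide
        bond, so once a loop is attached its position follows the realized
        anchor psi (trans to the loop's first N).  Anchor N/CA/C stay fixed.
        """
        from .geometry import InternalCoordinate, dihedral, place_atom, wrap_angle

        fw = BackboneStructure(r.copy() for r in self.framework.residues)
        anc = fw.residues[self.insert_at - 1]
        if "O" in anc.atoms and len(loop) > 0:
            psi = dihedral(
                anc.atoms["N"], anc.atoms["CA"], anc.atoms["C"],
                loop.residues[0].atoms["N"],
            )
            anc.atoms["O"] = place_atom(
                anc.atoms["N"], anc.atoms["CA"], anc.atoms["C"],
                InternalCoordinate(1.231, 120.8, wrap_angle(psi + 180.0)),
            )
        return fw

    def full_structure(self, loop: BackboneStructure) -> BackboneStructure:
        """Framework with a built loop inserted at the target span.

        The inner N-anchor's O is re-placed in the plane of the new anchor-
        loop peptide bond (see :meth:`adjusted_framework`).
        """
        if len(loop) != self.n:
            raise ValueError("loop length mismatch")
        fr = self.adjusted_framework(loop).residues
        return BackboneStructure(
            [r.copy() for r in fr[: self.insert_at]]
            + [r.copy() for r in loop.residues]
            + [r.copy() for r in fr[self.insert_at :]]
        )

    @property
    def loop_indices(self) -> list[int]:
        """Indices of the loop residues within :meth:`full_structure` output."""
        return list(range(self.insert_at, self.insert_at + self.n))


def rank_fragments(
    target: TargetSpec,
    db: FragmentDatabase,
    tables: ESSTables,
    anchor_tol: float = 1.0,
    gap_penalty: float = 2.0,
    h3_mode: bool = False,
    budget_multiplier: float = 1.0,
    exclude_source: str | set[str] | None = None,
) -> list[tuple[Fragment, AlignmentResult]]:
    """Anchor-filter, align and rank candidate fragments for a target.

    Candidates of every permitted length are pooled and sorted by ESS score
    (ties: longer fragment first, then source id, then offset) and truncated
    to the budgeted count.  An empty result signals the caller to fall back
    to pure ab initio building.
    """
    min_len, max_len, num = fragment_budget(target.n, h3_mode, budget_multiplier)
    if exclude_source is None and target.source_id:
        exclude_source = target.source_id
    pool: list[tuple[Fragment, AlignmentResult]] = []
    for length in range(min_len, max_len + 1):
        for frag in query(db, length, target.anchors, anchor_tol, exclude_source):
            aln = nw_align(target.sequence, frag, tables, gap_penalty)
            pool.append((frag, aln))
    pool.sort(
        key=lambda fa: (
            -fa[1].score,
            -fa[0].length,
            fa[0].source_id,
            fa[0].offset,
        )
    )
    return pool[:num]
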