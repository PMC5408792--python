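"""Loop-specific distance-bin statistical potential and decoy selection.

The potential is a residue-pooled adaptation of the RAPDF family of
distance-dependent statistical potentials: only backbone heavy atoms and CB
are typed (CB split by residue chemical class), pairwise distances involving
at least one loop atom are collected into six bins - [0,3) A and five 1 A
bins up to 8 A - and a decoy's energy is the negative sum of
log[P(bin | atom-type pair) / P(bin)] over its qualifying pairs.  Lower is
better.  Decoy sets are reduced to a cap (default 500) by this energy, and
an optional chain of external-command hooks (side-chain addition,
minimization, final ranking) can post-process the selected set; every hook
defaults to a no-op pass-through.
"""

from __future__ import annotations

import logging
import math
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .closure import _exempt
from .fragdb import THREE_TO_ONE
from .geometry import BackboneStructure
from .selection import TargetSpec

log = logging.getLogger(__name__)

__all__ = [
    "BIN_EDGES",
    "NUM_BINS",
    "atom_type",
    "DistancePotentialTable",
    "estimate_potential",
    "score_decoy",
    "RankedDecoySet",
    "select_top",
    "HookConfig",
    "external_stage_hook",
]

#: Distance bin edges (A): one bin 0-3, then five 1 A bins up to 8.
BIN_EDGES = (0.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
NUM_BINS = 6
MAX_DIST = BIN_EDGES[-1]

_HEAVY = ("N", "CA", "C", "O", "CB")

# CB typing by residue chemical class keeps tables estimable from small corpora
_CB_CLASS = {}
for _aa in "AVLIMF":
    _CB_CLASS[_aa] = "CB_hyd"
for _aa in "STNQYCW":
    _CB_CLASS[_aa] = "CB_pol"
for _aa in "DEKRH":
    _CB_CLASS[_aa] = "CB_chg"
_CB_CLASS["P"] = "CB_oth"


def distance_bin(d: float) -> int | None:
    """Bin index for a distance, or None beyond 8 A."""
    if d >= MAX_DIST:
        return None
    for k in range(NUM_BINS):
        if d < BIN_EDGES[k + 1]:
            return k
    return None


def atom_type(residue_name: str, atom_name: str, alphabet: str = "pooled") -> str:
    """Atom-type label for the potential.

    ``pooled`` (default): N/CA/C/O pooled over residue types, CB split by
    residue class.  ``residue_specific``: every (residue, atom) pair is its
    own type.
    """
    if alphabet == "residue_specific":
        return f"{residue_name}:{atom_name}"
    if atom_name == "CB":
        aa = THREE_TO_ONE.get(residue_name, "X")
        return _CB_CLASS.get(aa, "CB_oth")
    return atom_name


class DistancePotentialTable:
    """Conditional and marginal 6-bin distributions per atom-type pair."""

    VERSION = "hybridloop-potential v1"

    def __init__(
        self,
        conditional: dict[tuple[str, str], np.ndarray],
        marginal: np.ndarray,
        pseudocount: float = 1.0,
        alphabet: str = "pooled",
    ):
        self.conditional = {}
        for pair, v in conditional.items():
            v = np.asarray(v, float)
            # fixed-precision file round trips may drift by ~1e-7
            if v.shape != (NUM_BINS,) or abs(v.sum() - 1.0) > 1e-6 or np.any(v < 0):
                raise ValueError(f"bad conditional vector for pair {pair}")
            self.conditional[tuple(sorted(pair))] = v / v.sum()
        marginal = np.asarray(marginal, float)
        if marginal.shape != (NUM_BINS,) or abs(marginal.sum() - 1.0) > 1e-6:
            raise ValueError("bad marginal vector")
        self.marginal = marginal / marginal.sum()
        self.pseudocount = pseudocount
        self.alphabet = alphabet
        self._warned: set[tuple[str, str]] = set()

    def log_ratio(self, t1: str, t2: str, bin_k: int) -> float:
        """ln[P(bin | pair) / P(bin)]; 0 (with a log note) for unknown pairs."""
        pair = tuple(sorted((t1, t2)))
        cond = self.conditional.get(pair)
        if cond is None:
            if pair not in self._warned:
                self._warned.add(pair)
                log.warning("atom-type pair %s absent from potential; scored 0", pair)
            return 0.0
        return math.log(cond[bin_k] / self.marginal[bin_k])

    def save(self, path: str | Path) -> None:
        lines = [
            f"#{self.VERSION}",
            f"#alphabet={self.alphabet}",
            f"#pseudocount={self.pseudocount}",
            "MARGINAL " + " ".join(f"{x:.6e}" for x in self.marginal),
        ]
        for (t1, t2), v in sorted(self.conditional.items()):
            lines.append(f"PAIR {t1} {t2} " + " ".join(f"{x:.6e}" for x in v))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "DistancePotentialTable":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0] != f"#{cls.VERSION}":
            raise ValueError(f"unknown potential table version in {path}")
        meta = {}
        marginal = None
        cond = {}
        for line in lines[1:]:
            if line.startswith("#"):
                k, v = line[1:].split("=", 1)
                meta[k] = v
            elif line.startswith("MARGINAL "):
                marginal = np.array([float(x) for x in line.split()[1:]])
            elif line.startswith("PAIR "):
                parts = line.split()
                cond[(parts[1], parts[2])] = np.array([float(x) for x in parts[3:]])
        return cls(
            cond,
            marginal,
            float(meta.get("pseudocount", 1.0)),
            meta.get("alphabet", "pooled"),
        )


def _qualifying_pairs(
    full: BackboneStructure,
    loop_indices: list[int],
    alphabet: str,
):
    """Yield (type_i, type_j, distance) for scored pairs.

    Pairs are heavy backbone+CB atoms, at least one in the loop, closer than
    8 A, excluding pairs two covalent bonds apart or fewer.
    """
    coords, meta = [], []
    for ri, res in enumerate(full.residues):
        for name in _HEAVY:
            if name in res.atoms:
                coords.append(res.atoms[name])
                meta.append((ri, name, atom_type(res.residue_name, name, alphabet)))
    coords = np.asarray(coords)
    loop_set = set(loop_indices)
    loop_atom_idx = [k for k, (ri, _, _) in enumerate(meta) if ri in loop_set]
    tree = cKDTree(coords)
    seen = set()
    for k in loop_atom_idx:
        ri, name_i, type_i = meta[k]
        for j in tree.query_ball_point(coords[k], MAX_DIST):
            if j == k:
                continue
            key = (min(k, j), max(k, j))
            if key in seen:
                continue
            seen.add(key)
            rj, name_j, type_j = meta[j]
            if _exempt(ri, name_i, rj, name_j):
                continue
            d = float(np.linalg.norm(coords[k] - coords[j]))
            if d < MAX_DIST:
                yield type_i, type_j, d


def estimate_potential(
    corpus: list[tuple[BackboneStructure, list[int]]],
    pseudocount: float = 1.0,
    alphabet: str = "pooled",
) -> DistancePotentialTable:
    """Estimate the potential from annotated structures.

    ``corpus`` holds (structure, loop residue indices) pairs.  Counts are
    accumulated over qualifying pairs (at least one loop atom, d < 8 A),
    binned, and smoothed with an additive pseudocount per bin.
    """
    if not corpus:
        raise ValueError("empty corpus for potential estimation")
    counts: dict[tuple[str, str], np.ndarray] = {}
    for struct, loop_idx in corpus:
        for t1, t2, d in _qualifying_pairs(struct, list(loop_idx), alphabet):
            k = distance_bin(d)
            if k is None:
                continue
            pair = tuple(sorted((t1, t2)))
            counts.setdefault(pair, np.zeros(NUM_BINS))[k] += 1
    if not counts:
        raise ValueError("no qualifying atom pairs in corpus")
    total = np.zeros(NUM_BINS)
    cond = {}
    for pair, c in counts.items():
        total += c
        sm = c + pseudocount
        cond[pair] = sm / sm.sum()
    marg = total + pseudocount
    return DistancePotentialTable(cond, marg / marg.sum(), pseudocount, alphabet)


def score_decoy(
    loop: BackboneStructure,
    target: TargetSpec,
    table: DistancePotentialTable,
) -> float:
    """Energy of a closed decoy loop in its framework; lower is better."""
    full = target.full_structure(loop)
    energy = 0.0
    for t1, t2, d in _qualifying_pairs(full, target.loop_indices, table.alphabet):
        k = distance_bin(d)
        if k is not None:
            energy -= table.log_ratio(t1, t2, k)
    return float(energy)


# ---------------------------------------------------------------------------
# Decoy selection and hook chain
# ---------------------------------------------------------------------------

@dataclass
class RankedDecoySet:
    """Decoys in ascending-energy order with the stage that produced them."""

    decoys: list  # list[Decoy]
    stage: str = "potential"

    def __len__(self) -> int:
        return len(self.decoys)


def select_top(
    decoys: list,
    target: TargetSpec,
    table: DistancePotentialTable,
    cap: int = 500,
) -> RankedDecoySet:
    """Score (where unset), sort ascending by energy, truncate to ``cap``.

    Ties are broken by decoy id, making the selection deterministic and
    idempotent.
    """
    for d in decoys:
        if d.energy is None:
            d.energy = score_decoy(d.loop_structure(target), target, table)
    ranked = sorted(decoys, key=lambda d: (d.energy, d.decoy_id))
    return RankedDecoySet(ranked[:cap])


@dataclass
class HookConfig:
    """Command templates for the optional external post-processing stages.

    Templates may use the placeholders {input_pdb}, {output_pdb} and (for
    final_rank) {scores_out}; the scores file is whitespace-delimited
    (model_id, score) with model ids counting from 1.  Unset stages are
    identity pass-throughs.
    """

    sidechain: str | None = None
    minimize: str | None = None
    final_rank: str | None = None


def external_stage_hook(
    ranked: RankedDecoySet,
    stage: str,
    command_template: str | None,
    target: TargetSpec,
) -> RankedDecoySet:
    """Run one external stage over the decoy set.

    The set is exported as a multi-model PDB, the command is invoked, and the
    result re-imported; ``final_rank`` additionally re-orders by the returned
    scores.  Any failure logs a warning and returns the input set unchanged.
    """
    if command_template is None:
        return ranked
    from .pipeline import read_structure, write_decoys  # avoid import cycle

    try:
        with tempfile.TemporaryDirectory(prefix="hybridloop-hook-") as tmp:
            tmp = Path(tmp)
            in_pdb = tmp / "in.pdb"
            out_pdb = tmp / "out.pdb"
            scores_out = tmp / "scores.txt"
            write_decoys(ranked, target, in_pdb)
            cmd = command_template.format(
                input_pdb=in_pdb, output_pdb=out_pdb, scores_out=scores_out
            )
            subprocess.run(shlex.split(cmd), check=True, capture_output=True)
            if stage in ("sidechain", "minimize"):
                _reimport_coords(ranked, target, out_pdb)
            elif stage == "final_rank":
                order = _read_scores(scores_out, len(ranked.decoys))
                ranked = RankedDecoySet(
                    [ranked.decoys[i] for i in order], stage=stage
                )
            else:
                raise ValueError(f"unknown hook stage {stage!r}")
        ranked.stage = stage
        return ranked
    except Exception as exc:  # noqa: BLE001 - continue-with-warning contract
        log.warning("external %s hook failed (%s); continuing without it", stage, exc)
        return ranked


def _read_scores(path: Path, n: int) -> list[int]:
    scores = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) >= 2:
            scores[int(parts[0]) - 1] = float(parts[1])
    return sorted(range(n), key=lambda i: (scores.get(i, math.inf), i))


def _reimport_coords(ranked: RankedDecoySet, target: TargetSpec, path: Path) -> None:
    """Pull loop backbone coordinates of each MODEL back into the decoys."""
    from .pipeline import read_models

    models = read_models(path)
    if len(models) != len(ranked.decoys):
        raise ValueError(
            f"hook returned {len(models)} models for {len(ranked.decoys)} decoys"
        )
    for decoy, model in zip(ranked.decoys, models):
        by_id = {r.residue_id: r for r in model.residues}
        for i, rid in enumerate(target.loop_ids):
            res = by_id.get(rid)
            if res is None:
                raise ValueError(f"hook output missing loop residue {rid}")
            pos = decoy.chain_pos(i)
            for name in ("N", "CA", "C"):
                decoy.chain[pos[name]] = res.atoms[name]
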