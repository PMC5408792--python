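"""End-to-end orchestration, PDB I/O, configuration and synthetic fixtures.

The prediction pipeline runs database search -> loop building -> closure ->
decoy selection, guarantees a non-empty prediction for every valid target
(falling back to the pure ab initio branch when no fragment passes
selection), and is fully reproducible given (seed, database, config).

The fixture generator builds ideal-geometry helix-loop-helix proteins with
known loop conformations; corpora of such fixtures stand in for PDB-derived
datasets when building databases, Ramachandran distributions, substitution
tables and the distance potential in tests and examples.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .builder import (
    ENGH_HUBER,
    GaussianGeometryParams,
    RamachandranSet,
    estimate_rama_from_structures,
    place_carbonyl_oxygen,
    place_cbeta,
    resample_h3_distributions,
)
from .closure import ClosureConfig, build_with_switching
from .fragdb import (
    ONE_TO_THREE,
    FragmentDatabase,
    build_database,
    extract_loops,
)
from .geometry import (
    BackboneResidue,
    BackboneStructure,
    InternalCoordinate,
    ResidueId,
    backbone_phi_psi,
    place_atom,
)
from .scoring import (
    DistancePotentialTable,
    HookConfig,
    RankedDecoySet,
    estimate_potential,
    external_stage_hook,
    select_top,
)
from .selection import ESSTables, TargetSpec, esst_from_structures, fragment_budget, rank_fragments

log = logging.getLogger(__name__)

__all__ = [
    "read_structure",
    "read_models",
    "write_structure",
    "write_decoys",
    "RunConfig",
    "PredictionReport",
    "run_pipeline",
    "make_fixture",
    "make_corpus_structures",
    "write_corpus",
    "loop_annotations",
]

_KNOWN_ATOMS = ("N", "CA", "C", "O", "CB")


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def _model_to_backbone(model: "gemmi.Model") -> BackboneStructure:
    residues = []
    for chain in model:
        for res in chain:
            if res.name not in ONE_TO_THREE.values():
                log.warning("skipping unknown residue %s %s", res.name, res.seqid)
                continue
            atoms: dict[str, np.ndarray] = {}
            best_occ: dict[str, float] = {}
            for atom in res:
                if atom.name not in _KNOWN_ATOMS:
                    continue
                # highest-occupancy alternate location wins
                if atom.name in atoms and atom.occ <= best_occ[atom.name]:
                    continue
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                best_occ[atom.name] = atom.occ
            if not all(k in atoms for k in ("N", "CA", "C")):
                log.warning("skipping incomplete residue %s %s", res.name, res.seqid)
                continue
            rid = ResidueId(chain.name, res.seqid.num, res.seqid.icode.strip())
            residues.append(BackboneResidue(res.name, rid, atoms))
    if not residues:
        raise ValueError("no parsable ATOM records")
    return BackboneStructure(residues)


def read_structure(path: str | Path) -> BackboneStructure:
    """Read the first model of a PDB file as a backbone structure."""
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    return _model_to_backbone(st[0])


def read_models(path: str | Path) -> list[BackboneStructure]:
    """Read every MODEL of a multi-model PDB file."""
    st = gemmi.read_pdb(str(path))
    return [_model_to_backbone(m) for m in st]


_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _backbone_to_gemmi_model(struct: BackboneStructure, num: int) -> "gemmi.Model":
    model = gemmi.Model(num)
    chains: dict[str, gemmi.Chain] = {}
    for res in struct.residues:
        cname = res.residue_id.chain or "A"
        if cname not in chains:
            chains[cname] = gemmi.Chain(cname)
        r = gemmi.Residue()
        r.name = res.residue_name
        r.seqid = gemmi.SeqId(res.residue_id.seqnum, res.residue_id.icode or " ")
        for name in _KNOWN_ATOMS:
            if name not in res.atoms:
                continue
            a = gemmi.Atom()
            a.name = name
            x, y, z = (float(v) for v in res.atoms[name])
            a.pos = gemmi.Position(x, y, z)
            a.element = gemmi.Element(_ELEMENT[name])
            a.occ = 1.0
            r.add_atom(a)
        chains[cname].add_residue(r)
    for ch in chains.values():
        model.add_chain(ch)
    return model


def write_structure(struct: BackboneStructure, path: str | Path) -> None:
    st = gemmi.Structure()
    st.name = Path(path).stem
    st.add_model(_backbone_to_gemmi_model(struct, 1))
    Path(path).write_text(st.make_pdb_string())


def write_decoys(ranked: RankedDecoySet, target: TargetSpec, path: str | Path) -> None:
    """Write a ranked decoy set as a multi-model PDB (framework + loop).

    REMARK 250 lines carry per-model energy and provenance.
    """
    st = gemmi.Structure()
    st.name = Path(path).stem
    remarks = []
    for k, decoy in enumerate(ranked.decoys, start=1):
        full = target.full_structure(decoy.loop_structure(target))
        st.add_model(_backbone_to_gemmi_model(full, k))
        energy = "NA" if decoy.energy is None else f"{decoy.energy:.4f}"
        remarks.append(
            f"REMARK 250 MODEL {k} ID {decoy.decoy_id or 'decoy'} "
            f"ENERGY {energy} SOURCE {decoy.provenance}"
        )
    st.raw_remarks = remarks
    Path(path).write_text(st.make_pdb_string())


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable pipeline parameters plus the master random seed."""

    seed: int = 0
    h3_mode: bool = False
    anchor_tolerance: float = 1.0  # A RMS over the 4 anchor CA distances
    gap_penalty: float = 2.0
    budget_multiplier: float = 1.0
    cap: int = 500  # decoys kept by the energy function
    budget_per_fragment: int = 100
    failure_cutoff: int = 3000
    closure_tolerance: float = 0.25
    max_sweeps: int = 500
    max_angle_change: float = 30.0
    clash_cutoff: float = 2.5
    allowed_eps: float = 1e-6
    stall_sweeps: int = 15
    min_improvement: float = 1e-7
    ab_initio_decoys: int | None = None  # fallback total; None = budget formula
    h3_general_weight: float = 0.2  # general-data weight in H3 resampling
    hooks: HookConfig = field(default_factory=HookConfig)

    def closure_config(self) -> ClosureConfig:
        return ClosureConfig(
            tolerance=self.closure_tolerance,
            max_sweeps=self.max_sweeps,
            max_angle_change=self.max_angle_change,
            clash_cutoff=self.clash_cutoff,
            failure_cutoff=self.failure_cutoff,
            budget_per_fragment=self.budget_per_fragment,
            allowed_eps=self.allowed_eps,
            stall_sweeps=self.stall_sweeps,
            min_improvement=self.min_improvement,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        hooks = HookConfig(**data.pop("hooks", {}))
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(hooks=hooks, **data)

    def digest(self) -> str:
        d = asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

@dataclass
class PredictionReport:
    ranked: RankedDecoySet
    per_fragment: list[dict]
    counters: dict
    seed: int
    config_hash: str
    db_hash: str
    elapsed_s: float

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "db_hash": self.db_hash,
            "elapsed_s": round(self.elapsed_s, 3),
            "counters": self.counters,
            "per_fragment": self.per_fragment,
            "decoys": [
                {
                    "id": d.decoy_id,
                    "energy": d.energy,
                    "provenance": d.provenance,
                    "build_anchor": d.build_anchor,
                }
                for d in self.ranked.decoys
            ],
        }
        return json.dumps(payload, indent=2)


def _child_rng(seed: int, index: int) -> np.random.Generator:
    # per-fragment streams derived from (seed, index): order-independent
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def run_pipeline(
    target: TargetSpec,
    db: FragmentDatabase,
    rama: RamachandranSet,
    esst: ESSTables,
    potential: DistancePotentialTable,
    cfg: RunConfig | None = None,
    params: GaussianGeometryParams = ENGH_HUBER,
) -> PredictionReport:
    """Run the full prediction: search, build, close, select, hook chain.

    If no fragment passes selection (or none yields a decoy), the pure ab
    initio branch generates the configured total so a non-empty prediction
    is always returned.
    """
    cfg = cfg or RunConfig()
    t0 = time.time()
    ccfg = cfg.closure_config()
    candidates = rank_fragments(
        target,
        db,
        esst,
        anchor_tol=cfg.anchor_tolerance,
        gap_penalty=cfg.gap_penalty,
        h3_mode=cfg.h3_mode,
        budget_multiplier=cfg.budget_multiplier,
    )
    decoys = []
    per_fragment = []
    for i, (frag, aln) in enumerate(candidates):
        got, stats = build_with_switching(
            target, frag, aln, rama, params, ccfg, _child_rng(cfg.seed, i),
            provenance_prefix=frag.fragment_id,
        )
        decoys.extend(got)
        per_fragment.append({"fragment": frag.fragment_id, **stats})

    used_ab_initio = False
    if not decoys:
        used_ab_initio = True
        _, _, budget_n = fragment_budget(target.n, cfg.h3_mode, cfg.budget_multiplier)
        total = cfg.ab_initio_decoys or cfg.budget_per_fragment * max(budget_n, 1)
        chunk = cfg.budget_per_fragment
        idx = 0
        while total > 0:
            sub = ClosureConfig(**{**vars(ccfg), "budget_per_fragment": min(chunk, total)})
            got, stats = build_with_switching(
                target, None, None, rama, params, sub,
                _child_rng(cfg.seed, 1_000_000 + idx),
                provenance_prefix=f"ab_initio:{idx}",
            )
            decoys.extend(got)
            per_fragment.append({"fragment": f"ab_initio:{idx}", **stats})
            total -= min(chunk, total)
            idx += 1
    if not decoys:
        raise RuntimeError(
            "no decoy could be closed for this target (anchors may be unreachable)"
        )

    ranked = select_top(decoys, target, potential, cfg.cap)
    for stage in ("sidechain", "minimize", "final_rank"):
        ranked = external_stage_hook(ranked, stage, getattr(cfg.hooks, stage), target)

    counters = {
        "fragments_used": len(candidates),
        "decoys_generated": sum(p["successes"] for p in per_fragment),
        "decoys_returned": len(ranked),
        "closure_failures": sum(p["closure_failures"] for p in per_fragment),
        "clash_failures": sum(p["clash_failures"] for p in per_fragment),
        "ab_initio_fallback": used_ab_initio,
    }
    return PredictionReport(
        ranked=ranked,
        per_fragment=per_fragment,
        counters=counters,
        seed=cfg.seed,
        config_hash=cfg.digest(),
        db_hash=db.metadata.get("corpus_hash", ""),
        elapsed_s=time.time() - t0,
    )


# ---------------------------------------------------------------------------
# Synthetic fixtures (ideal-geometry helix-loop-helix proteins)
# ---------------------------------------------------------------------------

_HELIX_PHI_PSI = (-57.0, -47.0)
# coil basins that avoid the helix/strand assignment windows
_COIL_BASINS = ((-120.0, 40.0), (-85.0, 20.0), (55.0, 45.0), (-150.0, 30.0))
_FIXTURE_AAS = "ADEFIKLMNQRSTVWY"  # no G (keeps CB) / P / C / H for simplicity


def _chothia_numbers(n: int) -> list[tuple[int, str]]:
    """Chothia-style H3 numbering: 95-102 with insertions after 100."""
    if n <= 8:
        return [(95 + i, "") for i in range(n)]
    head = [(95 + i, "") for i in range(6)]  # 95..100
    ins = [(100, chr(ord("A") + i)) for i in range(n - 8)]
    return head + ins + [(101, ""), (102, "")]


def make_fixture(
    helix1: int = 10,
    loop_length: int = 8,
    helix2: int = 10,
    seed: int = 0,
    loop_dihedrals: list[tuple[float, float]] | None = None,
    chain: str = "A",
    h3_numbering: bool = False,
    max_attempts: int = 500,
) -> tuple[BackboneStructure, dict]:
    """Generate an ideal-geometry helix-loop-helix protein.

    Helices use canonical (phi, psi) = (-57, -47); loop residues draw from
    coil basins (with +-15 deg jitter) unless ``loop_dihedrals`` is given.
    Bond lengths/angles are Engh-Huber means throughout, omega is trans.
    Candidate loop conformations are rejection-sampled until the whole
    protein is free of heavy-atom clashes, so the "native" is physically
    sensible; explicitly supplied ``loop_dihedrals`` are used as given.
    Returns the structure and a machine-readable truth record (sequence,
    loop author numbers, loop dihedrals, loop backbone coordinates).
    Different seeds share identical helices and differ only in the loop.
    """
    from .closure import structure_has_clash

    if loop_length < 3:
        raise ValueError("loop length must be >= 3")
    rng = np.random.default_rng(seed)
    total = helix1 + loop_length + helix2
    seq = "".join(rng.choice(list(_FIXTURE_AAS)) for _ in range(total))

    def _draw_loop() -> list[tuple[float, float]]:
        out = []
        for _ in range(loop_length):
            basin = _COIL_BASINS[rng.integers(len(_COIL_BASINS))]
            out.append(
                (
                    float(basin[0] + rng.uniform(-15, 15)),
                    float(basin[1] + rng.uniform(-15, 15)),
                )
            )
        return out

    def _build(dihedrals) -> np.ndarray:
        phis, psis = [], []
        for i in range(total):
            if helix1 <= i < helix1 + loop_length:
                phi, psi = dihedrals[i - helix1]
            else:
                phi, psi = _HELIX_PHI_PSI
            phis.append(phi)
            psis.append(psi)
        mean = {k: v[0] for k, v in ENGH_HUBER.params.items()}
        coords = np.zeros((total, 3, 3))  # N, CA, C
        coords[0, 0] = (0.0, 0.0, 0.0)
        coords[0, 1] = (mean["b_nca"], 0.0, 0.0)
        coords[0, 2] = place_atom(
            (0.0, 1.0, 0.0),
            coords[0, 0],
            coords[0, 1],
            InternalCoordinate(mean["b_cac"], mean["a_ncac"], -120.0),
        )
        for i in range(1, total):
            pn, pca, pc = coords[i - 1]
            n = place_atom(pn, pca, pc,
                           InternalCoordinate(mean["b_cn"], mean["a_cacn"], psis[i - 1]))
            ca = place_atom(pca, pc, n,
                            InternalCoordinate(mean["b_nca"], mean["a_cnca"], 180.0))
            c = place_atom(pc, n, ca,
                           InternalCoordinate(mean["b_cac"], mean["a_ncac"], phis[i]))
            coords[i] = (n, ca, c)
        return coords

    def _materialize(coords, dihedrals) -> BackboneStructure:
        psis = [
            dihedrals[i - helix1][1] if helix1 <= i < helix1 + loop_length
            else _HELIX_PHI_PSI[1]
            for i in range(total)
        ]
        residues = []
        for i in range(total):
            n, ca, c = coords[i]
            name3 = ONE_TO_THREE[seq[i]]
            atoms = {"N": n.copy(), "CA": ca.copy(), "C": c.copy(),
                     "O": place_carbonyl_oxygen(n, ca, c, psis[i])}
            if name3 != "GLY":
                atoms["CB"] = place_cbeta(n, ca, c)
            residues.append(
                BackboneResidue(name3, ResidueId("TMP", i + 1, ""), atoms)
            )
        return BackboneStructure(residues)

    if loop_dihedrals is not None:
        if len(loop_dihedrals) != loop_length:
            raise ValueError("loop_dihedrals length mismatch")
        coords = _build(loop_dihedrals)
    else:
        for _ in range(max_attempts):
            loop_dihedrals = _draw_loop()
            coords = _build(loop_dihedrals)
            if not structure_has_clash(_materialize(coords, loop_dihedrals)):
                break
        else:
            raise RuntimeError(
                f"could not generate a clash-free fixture in {max_attempts} attempts"
            )
    phis = [
        loop_dihedrals[i - helix1][0] if helix1 <= i < helix1 + loop_length
        else _HELIX_PHI_PSI[0]
        for i in range(total)
    ]
    psis = [
        loop_dihedrals[i - helix1][1] if helix1 <= i < helix1 + loop_length
        else _HELIX_PHI_PSI[1]
        for i in range(total)
    ]

    if h3_numbering:
        chain = "H"
        loop_nums = _chothia_numbers(loop_length)
        numbering = (
            [(95 - helix1 + i, "") for i in range(helix1)]
            + loop_nums
            + [(103 + i, "") for i in range(helix2)]
        )
    else:
        numbering = [(i + 1, "") for i in range(total)]

    residues = []
    for i in range(total):
        n, ca, c = coords[i]
        name3 = ONE_TO_THREE[seq[i]]
        atoms = {"N": n.copy(), "CA": ca.copy(), "C": c.copy(),
                 "O": place_carbonyl_oxygen(n, ca, c, psis[i])}
        if name3 != "GLY":
            atoms["CB"] = place_cbeta(n, ca, c)
        num, icode = numbering[i]
        residues.append(BackboneResidue(name3, ResidueId(chain, num, icode), atoms))
    struct = BackboneStructure(residues)

    loop_idx = list(range(helix1, helix1 + loop_length))
    truth = {
        "sequence": seq,
        "chain": chain,
        "loop_sequence": seq[helix1 : helix1 + loop_length],
        "loop_start": numbering[helix1][0],
        "loop_end": numbering[helix1 + loop_length - 1][0],
        "loop_numbers": [numbering[i] for i in loop_idx],
        "loop_dihedrals": [list(d) for d in loop_dihedrals],
        "loop_coordinates": [
            {k: [float(x) for x in struct.residues[i].atoms[k]] for k in ("N", "CA", "C", "O")}
            for i in loop_idx
        ],
        "seed": seed,
    }
    return struct, truth


def make_corpus_structures(
    n_structures: int = 12,
    loop_lengths: tuple[int, ...] = (4, 5, 6, 7, 8),
    seed: int = 0,
    h3: bool = False,
) -> list[tuple[str, BackboneStructure]]:
    """A corpus of synthetic helix-loop-helix proteins, in memory."""
    out = []
    for k in range(n_structures):
        length = loop_lengths[k % len(loop_lengths)]
        struct, _ = make_fixture(
            loop_length=length, seed=seed * 100_003 + k, h3_numbering=h3
        )
        out.append((f"synth{k:03d}", struct))
    return out


def write_corpus(
    out_dir: str | Path,
    n_structures: int = 12,
    loop_lengths: tuple[int, ...] = (4, 5, 6, 7, 8),
    seed: int = 0,
    h3: bool = False,
) -> list[Path]:
    """Write a synthetic corpus to PDB files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, struct in make_corpus_structures(n_structures, loop_lengths, seed, h3):
        p = out_dir / f"{sid}.pdb"
        write_structure(struct, p)
        paths.append(p)
    return paths


def loop_annotations(struct: BackboneStructure, source_id: str = "") -> list[int]:
    """Indices of loop-proper residues within ``struct`` (for the potential)."""
    idx: list[int] = []
    for rec in extract_loops(struct, source_id):
        idx.extend(
            range(rec.source_start + rec.loop_span[0],
                  rec.source_start + rec.loop_span[1] + 1)
        )
    return idx
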