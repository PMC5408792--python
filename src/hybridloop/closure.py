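"""Loop closure by Ramachandran-constrained cyclic coordinate descent.

The free end of an open decoy carries mobile copies of the far anchor's N,
CA, C atoms.  CCD sweeps over the loop's phi/psi dihedrals (plus the
terminal dihedral of the overlap extension): for each, the closed-form
optimal rotation about the bond axis is computed, clipped to a maximum
per-update change, and applied only if the residue's new (phi, psi) still
falls in an allowed (non-negligible probability) bin of its Ramachandran
distribution.  The closure objective - the sum of squared deviations of the
three overlap atoms from the real anchor atoms - never increases on an
accepted update.

Decoys that close are checked for steric clashes; on any failure the next
decoy is built from the alternate anchor ("switching") until the per-fragment
success budget or the failure cut-off (3000) is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

try:  # optional JIT path; the pure-Python sweep below is the reference
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

#: Dispatch flag for the CCD inner loop; tests flip it to exercise the
#: reference implementation and check parity with the compiled kernel.
USE_NUMBA = _HAVE_NUMBA

from .builder import Decoy, GaussianGeometryParams, ENGH_HUBER, RamachandranSet, build_decoy
from .fragdb import Fragment
from .geometry import BackboneStructure, wrap_angle
from .selection import AlignmentResult, TargetSpec

__all__ = [
    "ClosureConfig",
    "ClosureResult",
    "ccd_close",
    "clash_check",
    "build_with_switching",
]

#: Maximum CA-CA span per residue (A) used for the reachability pre-check.
MAX_SPAN_PER_RESIDUE = 3.8


@dataclass
class ClosureConfig:
    """Closure / decoy-generation parameters (all configurable)."""

    tolerance: float = 0.25  # A RMSD over the three overlap atoms
    max_sweeps: int = 500
    max_angle_change: float = 30.0  # deg per accepted update
    clash_cutoff: float = 2.5  # A between heavy atoms
    failure_cutoff: int = 3000  # combined closure+clash failures per fragment
    budget_per_fragment: int = 100
    allowed_eps: float = 1e-6  # minimum bin probability that counts as allowed
    stall_sweeps: int = 15  # sweeps without improvement before giving up
    min_improvement: float = 1e-7  # A^2 objective decrease that counts as progress

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class ClosureResult:
    decoy: Decoy
    success: bool
    iterations: int
    final_deviation: float
    objective_trace: list[tuple[float, float]] = field(default_factory=list)


def _anchor_targets(decoy: Decoy, target: TargetSpec) -> np.ndarray:
    """Fixed far-anchor atom positions, in the decoy's chain order."""
    if decoy.build_anchor == "N":
        a = target.c_anchor.atoms
        return np.array([a["N"], a["CA"], a["C"]])
    a = target.n_anchor.atoms
    return np.array([a["C"], a["CA"], a["N"]])


def _dihedral_entries(decoy: Decoy, target: TargetSpec):
    """(axis_b, axis_c, downstream_start, residue_index, which) in sweep order.

    Axis endpoints are chain indices or, for the entry dihedral whose axis
    lies on the fixed build anchor, literal coordinates.  ``which`` is
    'phi'/'psi' for loop residues, or 'entry'/'term' for the torsions of the
    framework anchor copies at either end of the chain (no Ramachandran
    constraint applies to those).  In a C-anchor (reverse) build the first
    dihedral of residue i along the chain is psi, the second phi.
    """
    n = decoy.n
    entries = []
    if decoy.build_anchor == "N":
        anc = target.n_anchor
        entries.append((anc.atoms["CA"], anc.atoms["C"], 0, -1, "entry"))
    else:
        anc = target.c_anchor
        entries.append((anc.atoms["CA"], anc.atoms["N"], 0, -1, "entry"))
    for k in range(n):
        i = k if decoy.build_anchor == "N" else n - 1 - k
        first, second = ("phi", "psi") if decoy.build_anchor == "N" else ("psi", "phi")
        entries.append((3 * k, 3 * k + 1, 3 * k + 2, i, first))
        entries.append((3 * k + 1, 3 * k + 2, 3 * k + 3, i, second))
    entries.append((3 * n, 3 * n + 1, 3 * n + 2, -1, "term"))
    return entries


def ccd_close(
    decoy: Decoy,
    target: TargetSpec,
    rama: RamachandranSet,
    cfg: ClosureConfig | None = None,
) -> ClosureResult:
    """Close an open decoy onto the far anchor.

    Success means the RMSD of the three overlap atoms over the real anchor
    N/CA/C drops to ``cfg.tolerance`` or below.  Anchors further apart than
    the chain can possibly stretch fail immediately.
    """
    cfg = cfg or ClosureConfig()
    F = _anchor_targets(decoy, target)
    chain = decoy.chain
    n = decoy.n

    def rms() -> float:
        return float(np.sqrt(((chain[3 * n :] - F) ** 2).sum() / 3.0))

    dev = rms()
    if dev <= cfg.tolerance:
        decoy.closed = True
        return ClosureResult(decoy, True, 0, dev)

    span = float(
        np.linalg.norm(target.c_anchor.atoms["CA"] - target.n_anchor.atoms["CA"])
    )
    if span > MAX_SPAN_PER_RESIDUE * (n + 1):
        return ClosureResult(decoy, False, 0, dev)

    entries = _dihedral_entries(decoy, target)
    if USE_NUMBA:
        return _ccd_sweeps_numba(decoy, F, entries, rama, cfg)
    return _ccd_sweeps_python(decoy, F, entries, rama, cfg)


def _ccd_sweeps_python(
    decoy: Decoy, F: np.ndarray, entries, rama: RamachandranSet, cfg: ClosureConfig
) -> ClosureResult:
    """Reference implementation of the CCD sweep loop."""
    chain = decoy.chain
    n = decoy.n
    values = {"phi": decoy.phi, "psi": decoy.psi}
    trace: list[tuple[float, float]] = []
    obj = float(((chain[3 * n :] - F) ** 2).sum())
    dev = math.sqrt(obj / 3.0)
    stalled = 0
    for sweep in range(1, cfg.max_sweeps + 1):
        obj_at_sweep_start = obj
        for b_idx, c_idx, ds, res_i, which in entries:
            b = chain[b_idx] if isinstance(b_idx, int) else b_idx
            c = chain[c_idx] if isinstance(c_idx, int) else c_idx
            axis = c - b
            norm = math.sqrt(axis @ axis)
            if norm < 1e-9:
                continue
            axis = axis / norm
            M = chain[3 * n :]
            proj = b + ((M - b) @ axis)[:, None] * axis
            r = M - proj
            s = np.cross(axis[None, :], r)
            f = F - proj
            a_coef = float((f * r).sum())
            b_coef = float((f * s).sum())
            if a_coef == 0.0 and b_coef == 0.0:
                continue
            theta_opt = math.degrees(math.atan2(b_coef, a_coef))
            theta_opt = max(-cfg.max_angle_change, min(cfg.max_angle_change, theta_opt))
            if abs(theta_opt) < 1e-12:
                continue
            # a positive rotation about the b->c axis adds theta to the dihedral;
            # the objective decreases monotonically from 0 towards the optimum,
            # so if the full step leaves the allowed Ramachandran region a
            # smaller same-sign step is still downhill - try half/quarter steps
            theta = None
            if which in ("term", "entry"):
                theta = theta_opt
            else:
                phi_v, psi_v = decoy.phi[res_i], decoy.psi[res_i]
                dist = rama.get(decoy.restypes[res_i])
                for cand in (theta_opt, theta_opt / 2.0, theta_opt / 4.0):
                    if which == "phi":
                        new_phi, new_psi = wrap_angle(phi_v + cand), psi_v
                    else:
                        new_phi, new_psi = phi_v, wrap_angle(psi_v + cand)
                    if dist.allowed(new_phi, new_psi, cfg.allowed_eps):
                        theta = cand
                        break
                if theta is None:
                    continue
            # Rodrigues rotation (matrix form) of downstream atoms about the axis
            th = math.radians(theta)
            ct, st = math.cos(th), math.sin(th)
            kx, ky, kz = axis
            K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
            R = ct * np.eye(3) + st * K + (1.0 - ct) * np.outer(axis, axis)
            chain[ds:] = (chain[ds:] - b) @ R.T + b
            if which == "term":
                decoy.terminal_dihedral = wrap_angle(decoy.terminal_dihedral + theta)
            elif which != "entry":
                values[which][res_i] = wrap_angle(values[which][res_i] + theta)
            new_obj = float(((chain[3 * n :] - F) ** 2).sum())
            trace.append((obj, new_obj))
            obj = new_obj
            dev = math.sqrt(obj / 3.0)
            if dev <= cfg.tolerance:
                decoy.closed = True
                return ClosureResult(decoy, True, sweep, dev, trace)
        if obj_at_sweep_start - obj < cfg.min_improvement:
            stalled += 1
            if stalled >= cfg.stall_sweeps:
                return ClosureResult(decoy, False, sweep, dev, trace)
        else:
            stalled = 0
    return ClosureResult(decoy, False, cfg.max_sweeps, dev, trace)


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _wrapd(x):
        return (x + 180.0) % 360.0 - 180.0

    @numba.njit(cache=True)
    def _ccd_kernel(chain, F, kinds, bidx, cidx, ds_arr, res_arr,
                    entry_b, entry_c, phi, psi, probs3d, pidx,
                    eps, tol, max_sweeps, max_angle, stall_sweeps,
                    min_improvement, trace):
        # kinds: 0=phi, 1=psi, 2=term, 3=entry; mirrors _ccd_sweeps_python
        m = chain.shape[0]
        ne = kinds.shape[0]
        obj = 0.0
        for j in range(3):
            for d in range(3):
                diff = chain[m - 3 + j, d] - F[j, d]
                obj += diff * diff
        tol2 = 3.0 * tol * tol
        tn = 0
        term_delta = 0.0
        stalled = 0
        sweep = 0
        for sweep in range(1, max_sweeps + 1):
            obj0 = obj
            for e in range(ne):
                kind = kinds[e]
                if kind == 3:
                    bx, by, bz = entry_b[0], entry_b[1], entry_b[2]
                    cx, cy, cz = entry_c[0], entry_c[1], entry_c[2]
                else:
                    bx, by, bz = chain[bidx[e], 0], chain[bidx[e], 1], chain[bidx[e], 2]
                    cx, cy, cz = chain[cidx[e], 0], chain[cidx[e], 1], chain[cidx[e], 2]
                ax, ay, az = cx - bx, cy - by, cz - bz
                nrm = math.sqrt(ax * ax + ay * ay + az * az)
                if nrm < 1e-9:
                    continue
                ax, ay, az = ax / nrm, ay / nrm, az / nrm
                a_coef = 0.0
                b_coef = 0.0
                for j in range(3):
                    mx = chain[m - 3 + j, 0] - bx
                    my = chain[m - 3 + j, 1] - by
                    mz = chain[m - 3 + j, 2] - bz
                    t = mx * ax + my * ay + mz * az
                    rx, ry, rz = mx - t * ax, my - t * ay, mz - t * az
                    sx = ay * rz - az * ry
                    sy = az * rx - ax * rz
                    sz = ax * ry - ay * rx
                    fx = F[j, 0] - (bx + t * ax)
                    fy = F[j, 1] - (by + t * ay)
                    fz = F[j, 2] - (bz + t * az)
                    a_coef += fx * rx + fy * ry + fz * rz
                    b_coef += fx * sx + fy * sy + fz * sz
                if a_coef == 0.0 and b_coef == 0.0:
                    continue
                theta_opt = math.degrees(math.atan2(b_coef, a_coef))
                if theta_opt > max_angle:
                    theta_opt = max_angle
                elif theta_opt < -max_angle:
                    theta_opt = -max_angle
                if abs(theta_opt) < 1e-12:
                    continue
                theta = 1e30
                ri = res_arr[e]
                if kind >= 2:
                    theta = theta_opt
                else:
                    for half in range(3):
                        cand = theta_opt / (2.0 ** half)
                        if kind == 0:
                            nphi = _wrapd(phi[ri] + cand)
                            npsi = psi[ri]
                        else:
                            nphi = phi[ri]
                            npsi = _wrapd(psi[ri] + cand)
                        bi = int((nphi + 180.0) // 10.0)
                        bj = int((npsi + 180.0) // 10.0)
                        if bi > 35:
                            bi = 35
                        if bj > 35:
                            bj = 35
                        if probs3d[pidx[ri], bi, bj] > eps:
                            theta = cand
                            break
                    if theta > 1e29:
                        continue
                th = math.radians(theta)
                ct, st = math.cos(th), math.sin(th)
                omc = 1.0 - ct
                R00 = ct + ax * ax * omc
                R01 = ax * ay * omc - az * st
                R02 = ax * az * omc + ay * st
                R10 = ay * ax * omc + az * st
                R11 = ct + ay * ay * omc
                R12 = ay * az * omc - ax * st
                R20 = az * ax * omc - ay * st
                R21 = az * ay * omc + ax * st
                R22 = ct + az * az * omc
                for q in range(ds_arr[e], m):
                    vx = chain[q, 0] - bx
                    vy = chain[q, 1] - by
                    vz = chain[q, 2] - bz
                    chain[q, 0] = bx + R00 * vx + R01 * vy + R02 * vz
                    chain[q, 1] = by + R10 * vx + R11 * vy + R12 * vz
                    chain[q, 2] = bz + R20 * vx + R21 * vy + R22 * vz
                if kind == 0:
                    phi[ri] = _wrapd(phi[ri] + theta)
                elif kind == 1:
                    psi[ri] = _wrapd(psi[ri] + theta)
                elif kind == 2:
                    term_delta += theta
                new_obj = 0.0
                for j in range(3):
                    for d in range(3):
                        diff = chain[m - 3 + j, d] - F[j, d]
                        new_obj += diff * diff
                trace[tn, 0] = obj
                trace[tn, 1] = new_obj
                tn += 1
                obj = new_obj
                if obj <= tol2:
                    return 1, sweep, obj, term_delta, tn
            if obj0 - obj < min_improvement:
                stalled += 1
                if stalled >= stall_sweeps:
                    return 0, sweep, obj, term_delta, tn
            else:
                stalled = 0
        return 0, max_sweeps, obj, term_delta, tn


def _ccd_sweeps_numba(
    decoy: Decoy, F: np.ndarray, entries, rama: RamachandranSet, cfg: ClosureConfig
) -> ClosureResult:
    """Compiled CCD sweep loop; update-for-update identical to the reference."""
    chain = decoy.chain
    kind_code = {"phi": 0, "psi": 1, "term": 2, "entry": 3}
    ne = len(entries)
    kinds = np.zeros(ne, np.int64)
    bidx = np.zeros(ne, np.int64)
    cidx = np.zeros(ne, np.int64)
    ds_arr = np.zeros(ne, np.int64)
    res_arr = np.zeros(ne, np.int64)
    entry_b = np.zeros(3)
    entry_c = np.zeros(3)
    for e, (b, c, ds, res_i, which) in enumerate(entries):
        kinds[e] = kind_code[which]
        ds_arr[e] = ds
        res_arr[e] = max(res_i, 0)
        if which == "entry":
            entry_b[:] = b
            entry_c[:] = c
        else:
            bidx[e] = b
            cidx[e] = c
    # stack the per-residue Ramachandran histograms once
    key_rows: dict[str, int] = {}
    rows = []
    pidx = np.zeros(decoy.n, np.int64)
    for i, rt in enumerate(decoy.restypes):
        if rt not in key_rows:
            key_rows[rt] = len(rows)
            rows.append(rama.get(rt).probs)
        pidx[i] = key_rows[rt]
    probs3d = np.ascontiguousarray(np.stack(rows))
    trace = np.empty((cfg.max_sweeps * ne, 2))
    ok, sweeps, obj, term_delta, tn = _ccd_kernel(
        chain, F, kinds, bidx, cidx, ds_arr, res_arr, entry_b, entry_c,
        decoy.phi, decoy.psi, probs3d, pidx,
        cfg.allowed_eps, cfg.tolerance, cfg.max_sweeps, cfg.max_angle_change,
        cfg.stall_sweeps, cfg.min_improvement, trace,
    )
    decoy.terminal_dihedral = wrap_angle(decoy.terminal_dihedral + term_delta)
    success = bool(ok)
    if success:
        decoy.closed = True
    return ClosureResult(
        decoy, success, int(sweeps), math.sqrt(obj / 3.0), trace[:tn].copy()
    )


# ---------------------------------------------------------------------------
# Clash check
# ---------------------------------------------------------------------------

_HEAVY = ("N", "CA", "C", "O", "CB")

# atom pairs within the same residue that are <= 2 bonds apart
_SAME_RES_EXEMPT = {
    frozenset(p)
    for p in [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
              ("N", "C"), ("CA", "O"), ("N", "CB"), ("C", "CB")]
}
# (atom in residue i, atom in residue i+1) pairs <= 2 bonds apart
_ADJ_EXEMPT = {("C", "N"), ("CA", "N"), ("O", "N"), ("C", "CA")}


def _exempt(res_i: int, name_i: str, res_j: int, name_j: str) -> bool:
    if res_i == res_j:
        return frozenset((name_i, name_j)) in _SAME_RES_EXEMPT
    if res_j == res_i + 1:
        return (name_i, name_j) in _ADJ_EXEMPT
    if res_i == res_j + 1:
        return (name_j, name_i) in _ADJ_EXEMPT
    return False


def structure_has_clash(struct: BackboneStructure, cutoff: float = 2.5) -> bool:
    """True iff any non-exempt heavy-atom pair in ``struct`` is under ``cutoff``.

    Residues are treated as sequentially bonded in list order (single-chain
    use; the >2-bond exemption rule matches :func:`clash_check`).
    """
    coords, meta = [], []
    for ri, res in enumerate(struct.residues):
        for name in _HEAVY:
            if name in res.atoms:
                coords.append(res.atoms[name])
                meta.append((ri, name))
    arr = np.asarray(coords)
    tree = cKDTree(arr)
    for i, j in tree.query_pairs(cutoff):
        ri, ni = meta[i]
        rj, nj = meta[j]
        if not _exempt(ri, ni, rj, nj):
            return True
    return False


def clash_check(
    loop: BackboneStructure,
    framework: BackboneStructure,
    cutoff: float = 2.5,
    insert_at: int | None = None,
) -> bool:
    """True iff any loop heavy atom clashes.

    A clash is a non-exempt pair of heavy atoms (backbone + CB) closer than
    ``cutoff``, between a loop atom and any framework atom or any other loop
    atom; pairs separated by two covalent bonds or fewer are exempt.
    ``insert_at`` is the framework index where the loop is spliced in, needed
    to exempt the bonded junctions (defaults to no junction exemptions).
    """
    # sequential residue numbering across framework-with-loop for exemptions
    loop_seq_base = insert_at if insert_at is not None else None

    fw_coords = []
    fw_meta = []
    for fi, res in enumerate(framework.residues):
        # framework residues before the insertion keep their index; those
        # after shift by the loop length so adjacency works at both junctions
        if loop_seq_base is None:
            seq = -10_000 - fi  # never adjacent to loop residues
        elif fi < loop_seq_base:
            seq = fi
        else:
            seq = fi + len(loop)
        for name in _HEAVY:
            if name in res.atoms:
                fw_coords.append(res.atoms[name])
                fw_meta.append((seq, name))
    loop_coords = []
    loop_meta = []
    for li, res in enumerate(loop.residues):
        seq = (loop_seq_base + li) if loop_seq_base is not None else li
        for name in _HEAVY:
            if name in res.atoms:
                loop_coords.append(res.atoms[name])
                loop_meta.append((seq, name))
    loop_arr = np.asarray(loop_coords)

    if fw_coords:
        tree = cKDTree(np.asarray(fw_coords))
        for k, (seq_i, name_i) in enumerate(loop_meta):
            for j in tree.query_ball_point(loop_arr[k], cutoff):
                seq_j, name_j = fw_meta[j]
                if not _exempt(seq_j, name_j, seq_i, name_i):
                    return True
    # intra-loop pairs
    for a in range(len(loop_meta)):
        for bb in range(a + 1, len(loop_meta)):
            sa, na = loop_meta[a]
            sb, nb = loop_meta[bb]
            if _exempt(sa, na, sb, nb):
                continue
            if np.linalg.norm(loop_arr[a] - loop_arr[bb]) < cutoff:
                return True
    return False


# ---------------------------------------------------------------------------
# Build -> close -> check with anchor switching
# ---------------------------------------------------------------------------

def build_with_switching(
    target: TargetSpec,
    fragment: Fragment | None,
    alignment: AlignmentResult | None,
    rama: RamachandranSet,
    params: GaussianGeometryParams = ENGH_HUBER,
    cfg: ClosureConfig | None = None,
    rng: np.random.Generator | None = None,
    provenance_prefix: str | None = None,
) -> tuple[list[Decoy], dict[str, int]]:
    """Generate up to ``budget_per_fragment`` closed, clash-free decoys.

    Each failure (closure or clash) flips the build anchor for the next
    attempt; generation stops after the success budget or after
    ``failure_cutoff`` combined failures.
    """
    cfg = cfg or ClosureConfig()
    rng = rng or np.random.default_rng()
    prefix = provenance_prefix or (
        fragment.fragment_id if fragment is not None else "ab_initio"
    )
    anchor = "N"
    decoys: list[Decoy] = []
    stats = {"attempts": 0, "successes": 0, "failures": 0,
             "closure_failures": 0, "clash_failures": 0}
    while stats["successes"] < cfg.budget_per_fragment and (
        stats["failures"] < cfg.failure_cutoff
    ):
        stats["attempts"] += 1
        decoy = build_decoy(target, fragment, alignment, anchor, rama, params, rng)
        result = ccd_close(decoy, target, rama, cfg)
        if not result.success:
            stats["failures"] += 1
            stats["closure_failures"] += 1
            anchor = "C" if anchor == "N" else "N"
            continue
        loop = decoy.loop_structure(target)
        framework = target.adjusted_framework(loop)
        if clash_check(loop, framework, cfg.clash_cutoff, target.insert_at):
            stats["failures"] += 1
            stats["clash_failures"] += 1
            anchor = "C" if anchor == "N" else "N"
            continue
        decoy.decoy_id = f"{prefix}:{stats['successes']}"
        decoys.append(decoy)
        stats["successes"] += 1
    return decoys, stats
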