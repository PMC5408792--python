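"""Closure: Ramachandran-constrained CCD, clash checking, anchor switching."""

from __future__ import annotations

import numpy as np
import pytest

import hybridloop.closure as closure_mod
from hybridloop.builder import ENGH_HUBER, Decoy, build_decoy
from hybridloop.closure import (
    ClosureConfig,
    build_with_switching,
    ccd_close,
    clash_check,
    structure_has_clash,
)
from hybridloop.geometry import BackboneResidue, BackboneStructure, ResidueId, dihedral
from hybridloop.selection import AlignmentResult
from tests.conftest import fixture_target, native_full_length_fragment


def _native_decoy(seed=21, n=8, rama=None, anchor="N"):
    struct, truth, target = fixture_target(n, seed=seed)
    frag = native_full_length_fragment(struct, target)
    aln = AlignmentResult([(i, i) for i in range(n)], 0, 0.0)
    decoy = build_decoy(target, frag, aln, anchor, rama,
                        rng=np.random.default_rng(0))
    return struct, target, decoy


class TestCcdClose:
    def test_already_closed_unchanged(self, rama):
        """A native-copy decoy is already closed: 0 sweeps, no movement."""
        struct, target, decoy = _native_decoy(rama=rama)
        before = decoy.chain.copy()
        res = ccd_close(decoy, target, rama, ClosureConfig())
        assert res.success and res.iterations == 0
        assert np.array_equal(decoy.chain, before)
        assert res.final_deviation <= 0.25

    def test_unreachable_anchors_fail_before_iterating(self, rama):
        struct, truth, target = fixture_target(6, seed=31)
        # shove the C-side framework far away: span >> 3.8 * (n+1)
        for r in target.framework.residues[target.insert_at:]:
            for k in r.atoms:
                r.atoms[k] = r.atoms[k] + np.array([60.0, 0.0, 0.0])
        decoy = build_decoy(target, None, None, "N", rama,
                            rng=np.random.default_rng(0))
        res = ccd_close(decoy, target, rama, ClosureConfig())
        assert not res.success
        assert res.iterations == 0
        assert res.objective_trace is None or len(res.objective_trace) == 0

    def test_random_loops_close_with_objective_audit(self, permissive_rama):
        """Random reachable loops close; accepted updates never increase the
        objective; final dihedrals stay in allowed bins."""
        struct, truth, target = fixture_target(8, seed=11)
        closed = 0
        n_trials = 60
        for s in range(n_trials):
            decoy = build_decoy(target, None, None, "N" if s % 2 else "C",
                                permissive_rama, rng=np.random.default_rng(s))
            res = ccd_close(decoy, target, permissive_rama, ClosureConfig())
            for before, after in res.objective_trace:
                assert after <= before + 1e-9
            if res.success:
                closed += 1
                dist = permissive_rama.get("ALL")
                for i in range(decoy.n):
                    assert dist.allowed(decoy.phi[i], decoy.psi[i])
        assert closed / n_trials >= 0.9

    def test_tracked_dihedrals_match_measured_coordinates(self, permissive_rama):
        """After closure the bookkeeping phi/psi equal values re-measured
        from the final Cartesian chain."""
        struct, truth, target = fixture_target(6, seed=33)
        for s in range(10):
            decoy = build_decoy(target, None, None, "N", permissive_rama,
                                rng=np.random.default_rng(s))
            res = ccd_close(decoy, target, permissive_rama, ClosureConfig())
            if not res.success:
                continue
            for i in range(1, decoy.n):
                prev_c = decoy.residue_coords(i - 1)[2]
                n, ca, c = decoy.residue_coords(i)
                assert dihedral(prev_c, n, ca, c) == pytest.approx(
                    decoy.phi[i], abs=1e-6
                )
            for i in range(decoy.n - 1):
                n, ca, c = decoy.residue_coords(i)
                nxt = decoy.residue_coords(i + 1)[0]
                assert dihedral(n, ca, c, nxt) == pytest.approx(
                    decoy.psi[i], abs=1e-6
                )

    def test_python_and_numba_paths_agree(self, rama):
        """The compiled kernel reproduces the reference sweep exactly."""
        if not closure_mod._HAVE_NUMBA:
            pytest.skip("numba unavailable; only the reference path exists")
        struct, truth, target = fixture_target(6, seed=34)
        for s in range(6):
            d1 = build_decoy(target, None, None, "N", rama,
                             rng=np.random.default_rng(s))
            d2 = Decoy(**vars(d1))
            d2.chain = d1.chain.copy()
            d2.phi = d1.phi.copy()
            d2.psi = d1.psi.copy()
            try:
                closure_mod.USE_NUMBA = False
                r1 = ccd_close(d1, target, rama, ClosureConfig())
            finally:
                closure_mod.USE_NUMBA = closure_mod._HAVE_NUMBA
            r2 = ccd_close(d2, target, rama, ClosureConfig())
            assert r1.success == r2.success
            assert r1.iterations == r2.iterations
            assert np.allclose(d1.chain, d2.chain, atol=1e-9)


def _two_residue_system(dist):
    """A loop residue and a framework residue separated by ``dist`` A."""
    loop = BackboneStructure([
        BackboneResidue("ALA", ResidueId("A", 10), {
            "N": [0.0, 0, 0], "CA": [1.46, 0, 0], "C": [2.0, 1.4, 0],
        })
    ])
    fw = BackboneStructure([
        BackboneResidue("ALA", ResidueId("A", 50), {
            "N": [dist, 0, 5.0], "CA": [dist + 1.46, 0, 5.0],
            "C": [dist + 2.0, 1.4, 5.0],
        })
    ])
    return loop, fw


class TestClashCheck:
    def test_distant_loop_no_clash(self):
        loop, fw = _two_residue_system(20.0)
        assert not clash_check(loop, fw, 2.5)

    def test_close_atom_is_clash(self):
        loop = BackboneStructure([
            BackboneResidue("ALA", ResidueId("A", 10), {
                "N": [0.0, 0, 0], "CA": [1.46, 0, 0], "C": [2.0, 1.4, 0],
            })
        ])
        fw = BackboneStructure([
            BackboneResidue("ALA", ResidueId("A", 50), {
                "N": [0.0, 0, 1.0], "CA": [10.0, 0, 0], "C": [11.0, 1.4, 0],
            })
        ])
        assert clash_check(loop, fw, 2.5)

    def test_matches_brute_force_scan(self, rama, target8):
        """KDTree-based verdict equals an all-pairs O(N^2) oracle."""
        from hybridloop.closure import _HEAVY, _exempt

        struct, truth, target = target8
        rng = np.random.default_rng(6)
        for s in range(12):
            decoy = build_decoy(target, None, None, "N", rama,
                                rng=np.random.default_rng(100 + s))
            loop = decoy.loop_structure(target)
            fw = target.adjusted_framework(loop)
            got = clash_check(loop, fw, 2.5, target.insert_at)
            # oracle: plain double loop, no spatial index
            ia = target.insert_at
            fw_atoms = [
                (fi if fi < ia else fi + len(loop), nm, r.atoms[nm])
                for fi, r in enumerate(fw.residues)
                for nm in _HEAVY if nm in r.atoms
            ]
            lp_atoms = [
                (ia + li, nm, r.atoms[nm])
                for li, r in enumerate(loop.residues)
                for nm in _HEAVY if nm in r.atoms
            ]
            oracle = False
            for si, ni, ci in lp_atoms:
                for sj, nj, cj in fw_atoms:
                    if _exempt(sj, nj, si, ni):
                        continue
                    if np.linalg.norm(ci - cj) < 2.5:
                        oracle = True
            for a in range(len(lp_atoms)):
                for b in range(a + 1, len(lp_atoms)):
                    sa, na, ca_ = lp_atoms[a]
                    sb, nb, cb_ = lp_atoms[b]
                    if _exempt(sa, na, sb, nb):
                        continue
                    if np.linalg.norm(ca_ - cb_) < 2.5:
                        oracle = True
            assert got == oracle

    def test_bonded_junction_exempt(self, rama):
        """The native loop reinserted into its own framework never clashes."""
        struct, truth, target = fixture_target(7, seed=35)
        native_loop = BackboneStructure(
            [struct.residues[i].copy() for i in target.loop_indices]
        )
        assert not clash_check(native_loop, target.framework, 2.5,
                               target.insert_at)

    def test_structure_has_clash_on_overlapping_copy(self, target8):
        struct, truth, target = target8
        assert not structure_has_clash(struct)
        bad = struct.copy()
        bad.residues[2].atoms["CA"] = bad.residues[12].atoms["CA"].copy()
        assert structure_has_clash(bad)


class TestBuildWithSwitching:
    def test_cooperative_fragment_fills_budget(self, rama, target8):
        """A native-derived fragment yields exactly the budgeted decoy count."""
        struct, truth, target = target8
        frag = native_full_length_fragment(struct, target)
        aln = AlignmentResult([(i, i) for i in range(target.n)], 0, 0.0)
        cfg = ClosureConfig(budget_per_fragment=10)
        decoys, stats = build_with_switching(
            target, frag, aln, rama, ENGH_HUBER, cfg, np.random.default_rng(0)
        )
        assert len(decoys) == 10
        assert stats["successes"] == 10
        assert stats["attempts"] == stats["successes"] + stats["failures"]
        for d in decoys:
            assert d.closed

    def test_impossible_geometry_stops_at_failure_cutoff(self, rama):
        """Unreachable anchors: empty list after exactly 3000 failures."""
        struct, truth, target = fixture_target(6, seed=36)
        for r in target.framework.residues[target.insert_at:]:
            for k in r.atoms:
                r.atoms[k] = r.atoms[k] + np.array([80.0, 0.0, 0.0])
        cfg = ClosureConfig(budget_per_fragment=5)
        decoys, stats = build_with_switching(
            target, None, None, rama, ENGH_HUBER, cfg, np.random.default_rng(0)
        )
        assert decoys == []
        assert stats["failures"] == 3000
        assert stats["attempts"] == 3000

    def test_anchor_flips_after_each_failure(self, rama, monkeypatch):
        """Forced failures alternate the build anchor N, C, N, ..."""
        struct, truth, target = fixture_target(6, seed=37)
        seen = []
        real_build = closure_mod.build_decoy

        def spy_build(target_, frag, aln, anchor, *a, **kw):
            seen.append(anchor)
            return real_build(target_, frag, aln, anchor, *a, **kw)

        def always_fail(decoy, target_, rama_, cfg_):
            from hybridloop.closure import ClosureResult

            return ClosureResult(decoy, False, 1, 99.0)

        monkeypatch.setattr(closure_mod, "build_decoy", spy_build)
        monkeypatch.setattr(closure_mod, "ccd_close", always_fail)
        cfg = ClosureConfig(budget_per_fragment=5, failure_cutoff=6)
        decoys, stats = build_with_switching(
            target, None, None, rama, ENGH_HUBER, cfg, np.random.default_rng(0)
        )
        assert decoys == []
        assert seen == ["N", "C", "N", "C", "N", "C"]

    def test_returned_decoys_satisfy_all_invariants(self, rama, target8):
        """Closed within tolerance, clash-free, dihedrals in allowed bins,
        attempts bounded by budget + cutoff."""
        struct, truth, target = target8
        cfg = ClosureConfig(budget_per_fragment=5, failure_cutoff=300)
        decoys, stats = build_with_switching(
            target, None, None, rama, ENGH_HUBER, cfg, np.random.default_rng(3)
        )
        assert stats["attempts"] <= cfg.budget_per_fragment + cfg.failure_cutoff
        for d in decoys:
            assert d.closed
            # overlap atoms sit on the far anchor
            F = closure_mod._anchor_targets(d, target)
            dev = np.sqrt(((d.chain[3 * d.n:] - F) ** 2).sum() / 3)
            assert dev <= cfg.tolerance + 1e-9
            loop = d.loop_structure(target)
            assert not clash_check(loop, target.adjusted_framework(loop),
                                   cfg.clash_cutoff, target.insert_at)
            for i in range(d.n):
                assert rama.get(d.restypes[i]).allowed(d.phi[i], d.psi[i])
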