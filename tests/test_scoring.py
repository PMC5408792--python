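"""Distance potential, decoy ranking, and external hook chain."""

from __future__ import annotations

import math
import sys

import numpy as np
import pytest

from hybridloop.builder import build_decoy
from hybridloop.geometry import BackboneResidue, BackboneStructure, ResidueId
from hybridloop.scoring import (
    BIN_EDGES,
    NUM_BINS,
    DistancePotentialTable,
    HookConfig,
    RankedDecoySet,
    _qualifying_pairs,
    atom_type,
    distance_bin,
    estimate_potential,
    external_stage_hook,
    score_decoy,
    select_top,
)
from tests.conftest import fixture_target


def uniform_table(pairs):
    """Conditional identical to marginal for every pair: zero potential."""
    marg = np.full(NUM_BINS, 1.0 / NUM_BINS)
    return DistancePotentialTable({p: marg.copy() for p in pairs}, marg.copy())


ALL_PAIRS = [
    tuple(sorted((a, b)))
    for i, a in enumerate(["N", "CA", "C", "O", "CB_hyd", "CB_pol", "CB_chg", "CB_oth"])
    for b in ["N", "CA", "C", "O", "CB_hyd", "CB_pol", "CB_chg", "CB_oth"][i:]
]


class TestDistanceBins:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.0, 0), (2.99, 0), (3.0, 1), (3.5, 1), (4.0, 2), (7.99, 5),
         (8.0, None), (9.0, None)],
    )
    def test_bin_edges(self, d, expected):
        assert distance_bin(d) == expected

    def test_six_bins(self):
        assert NUM_BINS == 6
        assert BIN_EDGES == (0.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


class TestScoreDecoy:
    def test_uniform_table_gives_zero_energy(self, rama, target8):
        """conditional == marginal everywhere -> energy exactly 0."""
        struct, truth, target = target8
        table = uniform_table(ALL_PAIRS)
        decoy = build_decoy(target, None, None, "N", rama,
                            rng=np.random.default_rng(0))
        loop = decoy.loop_structure(target)
        assert score_decoy(loop, target, table) == 0.0

    def test_two_atom_toy_matches_hand_arithmetic(self):
        """One scored pair: energy equals the hand-computed -ln ratio."""
        cond = np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
        marg = np.array([0.25, 0.15, 0.15, 0.15, 0.15, 0.15])
        table = DistancePotentialTable({("CA", "CA"): cond}, marg)
        assert table.log_ratio("CA", "CA", 0) == pytest.approx(math.log(0.5 / 0.25))
        assert table.log_ratio("CA", "CA", 3) == pytest.approx(math.log(0.1 / 0.15))

    def test_energy_matches_independent_pair_scan(self, rama, potential, target8):
        """score_decoy equals a from-scratch double-loop recomputation."""
        from hybridloop.closure import _HEAVY, _exempt

        struct, truth, target = target8
        decoy = build_decoy(target, None, None, "N", rama,
                            rng=np.random.default_rng(1))
        loop = decoy.loop_structure(target)
        got = score_decoy(loop, target, potential)

        full = target.full_structure(loop)
        atoms = [
            (ri, nm, atom_type(r.residue_name, nm), r.atoms[nm])
            for ri, r in enumerate(full.residues)
            for nm in _HEAVY if nm in r.atoms
        ]
        loop_set = set(target.loop_indices)
        expected = 0.0
        for a in range(len(atoms)):
            for b in range(a + 1, len(atoms)):
                ra, na, ta, ca = atoms[a]
                rb, nb, tb, cb = atoms[b]
                if ra not in loop_set and rb not in loop_set:
                    continue
                if _exempt(ra, na, rb, nb):
                    continue
                d = float(np.linalg.norm(ca - cb))
                k = distance_bin(d)
                if k is None:
                    continue
                expected -= potential.log_ratio(ta, tb, k)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_energy_invariant_under_rigid_motion(self, rama, potential, target8):
        from scipy.spatial.transform import Rotation

        struct, truth, target = target8
        decoy = build_decoy(target, None, None, "N", rama,
                            rng=np.random.default_rng(2))
        loop = decoy.loop_structure(target)
        e1 = score_decoy(loop, target, potential)

        R = Rotation.random(random_state=4).as_matrix()
        t = np.array([5.0, -3.0, 11.0])

        def move(structd):
            for r in structd.residues:
                for k in r.atoms:
                    r.atoms[k] = R @ r.atoms[k] + t

        import copy

        target2 = copy.deepcopy(target)
        move(target2.framework)
        loop2 = loop.copy()
        move(loop2)
        e2 = score_decoy(loop2, target2, potential)
        assert e1 == pytest.approx(e2, abs=1e-9)

    def test_distant_loop_scores_only_intra_loop_pairs(self, potential):
        """A loop >8 A from everything contributes intra-loop terms only."""
        struct, truth, target = fixture_target(6, seed=41)
        from hybridloop.builder import build_decoy
        from hybridloop.builder import RamachandranSet

        rama = RamachandranSet.uniform()
        decoy = build_decoy(target, None, None, "N", rama,
                            rng=np.random.default_rng(3))
        loop = decoy.loop_structure(target)
        far_loop = loop.copy()
        for r in far_loop.residues:
            for k in r.atoms:
                r.atoms[k] = r.atoms[k] + np.array([200.0, 0.0, 0.0])
        e_far = score_decoy(far_loop, target, potential)
        # oracle: intra-loop-only energy computed directly
        pairs = list(
            _qualifying_pairs(
                target.full_structure(far_loop), target.loop_indices,
                potential.alphabet,
            )
        )
        expected = -sum(
            potential.log_ratio(t1, t2, distance_bin(d)) for t1, t2, d in pairs
        )
        assert e_far == pytest.approx(expected)
        # and every qualifying pair involves loop atoms on both sides
        loop_coords = {
            tuple(np.round(r.atoms[k], 3))
            for r in far_loop.residues for k in r.atoms
        }
        assert all(d < 8.0 for _, _, d in pairs)

    def test_unknown_pair_scores_zero(self):
        table = uniform_table([("CA", "CA")])
        assert table.log_ratio("N", "O", 2) == 0.0


class TestEstimatePotential:
    def test_toy_corpus_matches_hand_counts(self):
        """Two CA-only residue pairs at known distances: table equals
        hand-accumulated counts with pseudocounts."""
        def ca_res(num, x):
            return BackboneResidue("GLY", ResidueId("A", num), {
                "N": [x - 1.3, 10.0, 0.0], "CA": [x, 0.0, 0.0],
                "C": [x + 1.4, -10.0, 0.0],
            })

        # residues far apart except CA-CA at 3.5 (bin 1) and 6.5 (bin 4)
        s1 = BackboneStructure([ca_res(1, 0.0), ca_res(5, 3.5)])
        s2 = BackboneStructure([ca_res(1, 0.0), ca_res(5, 6.5)])
        table = estimate_potential(
            [(s1, [0]), (s2, [0])], pseudocount=1.0
        )
        cond = table.conditional[("CA", "CA")]
        expected = np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0])
        assert np.allclose(cond, expected / expected.sum())

    def test_pairs_beyond_eight_angstroms_ignored(self):
        def ca_res(num, x):
            return BackboneResidue("GLY", ResidueId("A", num), {
                "N": [x - 1.3, 30.0, 0.0], "CA": [x, 0.0, 0.0],
                "C": [x + 1.4, -30.0, 0.0],
            })

        s = BackboneStructure([ca_res(1, 0.0), ca_res(5, 9.0)])
        with pytest.raises(ValueError, match="no qualifying"):
            estimate_potential([(s, [0])])

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            estimate_potential([])

    def test_vectors_normalized(self, potential):
        for v in potential.conditional.values():
            assert v.sum() == pytest.approx(1.0)
            assert np.all(v > 0)
        assert potential.marginal.sum() == pytest.approx(1.0)

    def test_save_load_round_trip(self, potential, tmp_path):
        path = tmp_path / "pot.txt"
        potential.save(path)
        p2 = DistancePotentialTable.load(path)
        assert set(p2.conditional) == set(potential.conditional)
        for pair in potential.conditional:
            assert np.allclose(p2.conditional[pair],
                               potential.conditional[pair], atol=1e-5)


def _scored_decoys(target, rama, count, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    out = []
    for k in range(count):
        d = build_decoy(target, None, None, "N", rama, rng=rng)
        d.decoy_id = f"d{k:04d}"
        d.energy = float(rng.normal())
        out.append(d)
    return out


class TestSelectTop:
    def test_under_cap_returns_all(self, rama, potential, target8):
        _, _, target = target8
        decoys = _scored_decoys(target, rama, 80)
        ranked = select_top(decoys, target, potential, cap=500)
        assert len(ranked) == 80

    def test_over_cap_keeps_energy_minimal_subset(self, rama, potential, target8):
        _, _, target = target8
        decoys = _scored_decoys(target, rama, 1200)
        ranked = select_top(decoys, target, potential, cap=500)
        assert len(ranked) == 500
        oracle = sorted(decoys, key=lambda d: (d.energy, d.decoy_id))[:500]
        assert [d.decoy_id for d in ranked.decoys] == [d.decoy_id for d in oracle]

    def test_idempotent(self, rama, potential, target8):
        _, _, target = target8
        decoys = _scored_decoys(target, rama, 50)
        r1 = select_top(decoys, target, potential, cap=20)
        r2 = select_top(r1.decoys, target, potential, cap=20)
        assert [d.decoy_id for d in r1.decoys] == [d.decoy_id for d in r2.decoys]

    def test_scores_computed_when_absent(self, rama, potential, target8):
        _, _, target = target8
        decoys = _scored_decoys(target, rama, 5)
        for d in decoys:
            d.energy = None
        ranked = select_top(decoys, target, potential, cap=5)
        assert all(d.energy is not None and np.isfinite(d.energy)
                   for d in ranked.decoys)
        energies = [d.energy for d in ranked.decoys]
        assert energies == sorted(energies)


class TestExternalHooks:
    def _ranked(self, target, rama, potential, count=4):
        decoys = _scored_decoys(target, rama, count, rng_seed=7)
        return select_top(decoys, target, potential, cap=count)

    def test_unconfigured_hook_is_identity(self, rama, potential, target8):
        _, _, target = target8
        ranked = self._ranked(target, rama, potential)
        out = external_stage_hook(ranked, "final_rank", None, target)
        assert out is ranked

    def test_reversing_final_rank_stub(self, rama, potential, target8, tmp_path):
        """A stub ranker that reverses the order does reverse the set."""
        _, _, target = target8
        ranked = self._ranked(target, rama, potential)
        stub = tmp_path / "rev.py"
        stub.write_text(
            "import sys\n"
            "pdb, out = sys.argv[1], sys.argv[2]\n"
            "n = sum(1 for l in open(pdb) if l.startswith('MODEL'))\n"
            "open(out, 'w').write('\\n'.join(f'{i+1} {n-i}' for i in range(n)))\n"
        )
        cmd = f"{sys.executable} {stub} {{input_pdb}} {{scores_out}}"
        out = external_stage_hook(ranked, "final_rank", cmd, target)
        assert [d.decoy_id for d in out.decoys] == [
            d.decoy_id for d in reversed(ranked.decoys)
        ]

    def test_perturbing_minimizer_stub(self, rama, potential, target8, tmp_path):
        """A stub minimizer that shifts coordinates: count preserved,
        re-imported coordinates differ."""
        _, _, target = target8
        ranked = self._ranked(target, rama, potential)
        before = [d.chain.copy() for d in ranked.decoys]
        stub = tmp_path / "min.py"
        stub.write_text(
            "import sys\n"
            "src, dst = sys.argv[1], sys.argv[2]\n"
            "out = []\n"
            "for line in open(src):\n"
            "    if line.startswith(('ATOM', 'HETATM')):\n"
            "        x = float(line[30:38]) + 0.3\n"
            "        line = line[:30] + f'{x:8.3f}' + line[38:]\n"
            "    out.append(line)\n"
            "open(dst, 'w').writelines(out)\n"
        )
        cmd = f"{sys.executable} {stub} {{input_pdb}} {{output_pdb}}"
        out = external_stage_hook(ranked, "minimize", cmd, target)
        assert len(out.decoys) == len(before)
        for d, b in zip(out.decoys, before):
            assert not np.allclose(d.chain[: 3 * d.n], b[: 3 * d.n])
            assert np.allclose(d.chain[0] - b[0], [0.3, 0.0, 0.0], atol=2e-3)

    def test_failing_command_passes_through_with_warning(self, rama, potential,
                                                         target8, caplog):
        _, _, target = target8
        ranked = self._ranked(target, rama, potential)
        out = external_stage_hook(
            ranked, "final_rank", "/nonexistent-cmd {input_pdb}", target
        )
        assert [d.decoy_id for d in out.decoys] == [
            d.decoy_id for d in ranked.decoys
        ]
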