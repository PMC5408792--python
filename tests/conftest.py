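"""Shared fixtures: synthetic corpus, database, distributions, targets.

Everything is generated programmatically at session start; no data files are
shipped.  Seeds are fixed so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridloop.builder import (
    RamachandranDistribution,
    RamachandranSet,
    estimate_rama_from_structures,
)
from hybridloop.fragdb import build_database, extract_loops, split_fragments
from hybridloop.pipeline import loop_annotations, make_corpus_structures, make_fixture
from hybridloop.scoring import estimate_potential
from hybridloop.selection import TargetSpec, esst_from_structures


@pytest.fixture(scope="session")
def corpus():
    """Twelve synthetic helix-loop-helix proteins, loop lengths 4-8."""
    return make_corpus_structures(12, (4, 5, 6, 7, 8), seed=2)


@pytest.fixture(scope="session")
def db(corpus):
    return build_database(corpus)


@pytest.fixture(scope="session")
def rama(corpus):
    return estimate_rama_from_structures(corpus)


@pytest.fixture(scope="session")
def esst(corpus):
    return esst_from_structures(corpus)


@pytest.fixture(scope="session")
def potential(corpus):
    annotated = [(s, loop_annotations(s, sid)) for sid, s in corpus]
    return estimate_potential([(s, idx) for s, idx in annotated if idx])


@pytest.fixture(scope="session")
def permissive_rama():
    """Uniform over a generous coil+helix+sheet region of the Ramachandran plot."""
    mask = np.zeros((36, 36), bool)
    for i in range(36):
        for j in range(36):
            phi, psi = RamachandranDistribution.bin_center(i, j)
            if phi < -20.0 or (phi >= 0.0 and -90.0 <= psi < 130.0):
                mask[i, j] = True
    return RamachandranSet.uniform(mask)


def fixture_target(loop_length: int, seed: int):
    """A fixture protein and its TargetSpec (loop excised, native kept)."""
    struct, truth = make_fixture(loop_length=loop_length, seed=seed)
    target = TargetSpec.from_structure(
        struct,
        truth["chain"],
        truth["loop_start"],
        truth["loop_end"],
        truth["loop_sequence"],
        source_id=f"fixture{seed}",
    )
    return struct, truth, target


@pytest.fixture(scope="session")
def target8():
    """8-residue loop target with native structure and truth record."""
    return fixture_target(8, seed=11)


def native_full_length_fragment(struct, target):
    """A fragment spanning the whole native loop (for exact-copy tests)."""
    rec = extract_loops(struct, "native")[0]
    frags = [
        f
        for f in split_fragments(rec, max_len=30)
        if f.length == target.n and f.offset == rec.loop_span[0]
    ]
    assert len(frags) == 1
    return frags[0]


def shortened_native_fragment(struct, target, shorten: int = 2):
    """The native loop minus ``shorten`` residues, anchors copied from the
    target (synthetic near-native database entry)."""
    import dataclasses

    rec = extract_loops(struct, "homolog")[0]
    frags = [
        f
        for f in split_fragments(rec)
        if f.length == target.n - shorten and f.offset == rec.loop_span[0] + 1
    ]
    assert frags, "no shortened native fragment available"
    return dataclasses.replace(frags[0], anchor=target.anchors)
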