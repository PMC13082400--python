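import itertools

import numpy as np
import pytest

from grainphi import (MappingTable, MicroUniverse, SearchConstraints, UnitDef,
                      apportion_background, candidate_systems, evaluate_system,
                      find_complexes, is_maximally_irreducible_within,
                      micro_unit, random_universe)
from grainphi.errors import GuardError
from grainphi.examples import example1_universe

AND = MappingTable((0, 0, 0, 1))


def _micro_pool(universe):
    pool = []
    n = universe.n
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            units = tuple(micro_unit(i, universe.unit_labels[i]) for i in combo)
            pool.append(evaluate_system(universe, units))
    return pool


def test_example2_pair_admissible_full_system_not(ex2):
    pool = _micro_pool(ex2)
    by_micro = {c.micro_constituents: c for c in pool}
    ok, _ = is_maximally_irreducible_within(by_micro[frozenset({0, 1})], pool)
    assert ok
    verdict, witness = is_maximally_irreducible_within(
        by_micro[frozenset({0, 1, 2, 3})], pool)
    assert not verdict
    assert witness.micro_constituents in (frozenset({0, 1}), frozenset({2, 3}))


def test_fig2b_vertical_pair_inadmissible(fig2b):
    pool = _micro_pool(fig2b)
    by_micro = {c.micro_constituents: c for c in pool}
    pair = by_micro[frozenset({0, 2})]
    assert pair.phi > 0  # weakly integrated ...
    verdict, witness = is_maximally_irreducible_within(pair, pool)
    assert not verdict  # ... but a single unit alone does better
    assert len(witness.micro_constituents) == 1


def test_example1_candidate_enumeration(ex1):
    cands = candidate_systems(ex1)
    labels = sorted(tuple(c.labels) for c in cands)
    # {A}, {B}, {A,B}, and one single-macro-unit system per mapping
    assert ("A",) in labels and ("B",) in labels and ("A", "B") in labels
    macro = [l for l in labels if len(l) == 1 and "/" in l[0]]
    assert len(macro) == 14
    assert len(cands) == 17


def test_example1_complex_is_macro(ex1):
    report = find_complexes(ex1)
    assert len(report.complexes) == 1
    top = report.complexes[0]
    assert top.phi == pytest.approx(0.788, abs=5e-4)
    assert top.micro_constituents == frozenset({0, 1})
    assert not top.units[0].is_micro


def test_two_independent_copies_give_two_complexes():
    # two disconnected copies of the two-unit example: block-diagonal rules
    base = example1_universe()
    n = 4
    sbn = np.empty((2**n, n))
    for row in range(2**n):
        a, b, c, d = [(row >> k) & 1 for k in range(n)]
        sbn[row, 0] = base.sbn_tpm[a + 2 * b, 0]
        sbn[row, 1] = base.sbn_tpm[a + 2 * b, 1]
        sbn[row, 2] = base.sbn_tpm[c + 2 * d, 0]
        sbn[row, 3] = base.sbn_tpm[c + 2 * d, 1]
    u = MicroUniverse(("A", "B", "C", "D"), sbn, ((0, 0, 0, 0),))
    report = find_complexes(u)
    assert len(report.complexes) == 2
    blocks = sorted(c.micro_constituents for c in report.complexes)
    assert blocks == [frozenset({0, 1}), frozenset({2, 3})]
    for c in report.complexes:
        assert c.phi == pytest.approx(0.788, abs=5e-4)


@pytest.mark.parametrize("seed", range(4))
def test_complexes_never_overlap(seed):
    u = random_universe(3, seed=seed)
    report = find_complexes(u)
    for a, b in itertools.combinations(report.complexes, 2):
        assert not (a.micro_constituents & b.micro_constituents)


def test_candidates_satisfy_disjointness(ex2):
    for cand in candidate_systems(ex2):
        claimed = set()
        for unit in cand.units:
            mine = unit.micro_constituents | unit.background
            assert not (claimed & mine)
            claimed |= mine


def test_apportionment_empty_pool_is_noop(ex1):
    units = (UnitDef("alpha", (0, 1), 1, AND),)
    apportioned, best = apportion_background(ex1, units, frozenset())
    assert apportioned[0].background == frozenset()
    baseline = evaluate_system(ex1, units)
    assert best.phi == pytest.approx(baseline.phi, abs=1e-12)


def test_apportionment_maximizes_phi():
    u = random_universe(3, seed=11, history_length=2)
    detector = MappingTable(tuple((s >> 1) & 1 for s in range(16)))
    units = (UnitDef("J", (0, 1), 2, detector),)
    apportioned, best = apportion_background(u, units, frozenset({2}))
    unapportioned = evaluate_system(u, units)
    assert best.phi >= unapportioned.phi - 1e-12
    for unit in apportioned:
        assert unit.background <= frozenset({2})


def test_search_guard_on_large_universe():
    rng = np.random.default_rng(0)
    sbn = 0.2 + 0.6 * rng.random((2**7, 7))
    u = MicroUniverse(tuple("ABCDEFG"), sbn, (tuple([0] * 7),))
    with pytest.raises(GuardError):
        candidate_systems(u)
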