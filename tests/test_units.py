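import pytest

from grainphi import (IDENTITY, NEGATION, MappingTable, UnitDef,
                      compose_micro_mapping, enumerate_mappings, micro_unit,
                      unit_state)
from grainphi.errors import GuardError

AND = MappingTable((0, 0, 0, 1))


@pytest.mark.parametrize("k,tau,count", [
    (2, 1, 14),
    (1, 1, 2),
    (1, 2, 14),
    (2, 2, 2**16 - 2),
])
def test_mapping_count_closed_form(k, tau, count):
    mappings = list(enumerate_mappings(k, tau, guard=16))
    assert len(mappings) == count
    assert len({m.bits for m in mappings}) == count


def test_mapping_enumeration_guard():
    with pytest.raises(GuardError):
        list(enumerate_mappings(3, 2))


def test_k1_tau1_mappings_are_identity_and_negation():
    assert list(enumerate_mappings(1, 1)) == [NEGATION, IDENTITY]


def test_constant_mapping_rejected():
    with pytest.raises(ValueError, match="non-constant"):
        MappingTable((0, 0, 0, 0))


def test_identity_hierarchy_composes_to_identity():
    meso = UnitDef("m", (3,), 1, IDENTITY)
    macro = UnitDef("M", (meso,), 1, IDENTITY)
    assert macro.tau == 1
    table = compose_micro_mapping(macro)
    assert table == {(0,): 0, (1,): 1}


def test_tau_multiplies_down_the_hierarchy():
    # meso unit over 4 micro updates, macro over 2 meso updates -> tau = 8
    final_state = MappingTable(tuple((r >> 3) & 1 for r in range(16)))
    meso = UnitDef("m", (0,), 4, final_state)
    macro = UnitDef("M", (meso,), 2, MappingTable((0, 1, 0, 1)))
    assert meso.tau == 4
    assert macro.tau == 8


def test_and_of_ands_equals_four_input_and():
    left = UnitDef("l", (0, 1), 1, AND)
    right = UnitDef("r", (2, 3), 1, AND)
    top = UnitDef("t", (left, right), 1, AND)
    table = compose_micro_mapping(top)
    for state in range(16):
        assert table[(state,)] == (1 if state == 0b1111 else 0)


def test_unit_state_identity():
    unit = micro_unit(0)
    assert unit_state(unit, [(0,), (1,)]) == 1


def test_unit_state_example2_alpha():
    alpha = UnitDef("alpha", (0, 1), 1, AND)
    assert unit_state(alpha, [(0, 0, 1, 1)]) == 0
    assert unit_state(alpha, [(1, 1, 0, 0)]) == 1


def test_unit_state_sequence_sensitive():
    # "1 iff the constituent was on one update ago and is off now"
    detector = UnitDef("d", (0,), 2, MappingTable((0, 1, 0, 0)))
    assert unit_state(detector, [(1,), (0,)]) == 1
    assert unit_state(detector, [(0,), (1,)]) == 0


def test_unit_state_short_history_names_requirement():
    detector = UnitDef("d", (0,), 2, MappingTable((0, 1, 0, 0)))
    with pytest.raises(ValueError, match="at least 2"):
        unit_state(detector, [(1,)])


def test_overlapping_constituents_rejected():
    inner = UnitDef("i", (0, 1), 1, AND)
    with pytest.raises(ValueError, match="disjoint"):
        UnitDef("J", (inner, 1), 1, AND)


def test_heterogeneous_constituent_grains_rejected():
    slow = UnitDef("s", (0,), 2, MappingTable((0, 1, 0, 0)))
    with pytest.raises(ValueError, match="unequal micro update grains"):
        UnitDef("J", (slow, 1), 1, AND)


def test_background_nesting_enforced():
    inner = UnitDef("i", (0,), 1, IDENTITY, background=frozenset({5}))
    with pytest.raises(ValueError, match="not contained"):
        UnitDef("J", (inner,), 1, IDENTITY, background=frozenset({4}))
    # containing apportionment is accepted
    UnitDef("J", (inner,), 1, IDENTITY, background=frozenset({4, 5}))


def test_composition_matches_direct_evaluation():
    # flattened table agrees with evaluating the hierarchy on raw sequences
    left = UnitDef("l", (0, 1), 1, AND)
    top = UnitDef("t", (left,), 2, MappingTable((0, 1, 1, 0)))
    table = compose_micro_mapping(top)
    for s1 in range(4):
        for s2 in range(4):
            seq = [[(s >> 0) & 1, (s >> 1) & 1] for s in (s1, s2)]
            assert table[(s1, s2)] == top.state_from_micro_sequence(seq)
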