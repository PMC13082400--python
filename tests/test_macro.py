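import numpy as np
import pytest

from grainphi import (MacroSystem, MappingTable, UnitDef,
                      macro_cause_effect_tpms, micro_cause_effect_tpms,
                      micro_unit, random_universe)
from grainphi.macro import _occupancy, step1_modified_probs
from grainphi.tpm import marginalize_inputs

AND = MappingTable((0, 0, 0, 1))


def test_step1_full_coverage_leaves_tpm_unchanged(ex1):
    alpha = UnitDef("alpha", (0, 1), 1, AND)
    system = MacroSystem(ex1, (alpha,))
    assert np.array_equal(step1_modified_probs(system, alpha), ex1.sbn_tpm)


def test_step1_excluded_unit_fully_noised(ex1):
    # a system consisting only of B: A's activation becomes the uniform
    # average of its column, (0.05 + 0.05 + 0.06 + 0.95) / 4
    beta = micro_unit(1, "B")
    system = MacroSystem(ex1, (beta,))
    modified = step1_modified_probs(system, beta)
    assert np.allclose(modified[:, 0], 0.2775, atol=1e-12)
    assert np.array_equal(modified[:, 1], ex1.sbn_tpm[:, 1])


def test_step1_example2_other_units_noised(ex2):
    alpha = UnitDef("alpha", (0, 1), 1, AND)
    beta = UnitDef("beta", (2, 3), 1, AND)
    system = MacroSystem(ex2, (alpha, beta))
    modified = step1_modified_probs(system, alpha)
    # C and D become input-independent constants; A and B stay intact
    for col in (2, 3):
        assert np.ptp(modified[:, col]) == 0.0
    assert np.array_equal(modified[:, :2], ex2.sbn_tpm[:, :2])


def test_step1_apportioned_background_keeps_own_inputs():
    u = random_universe(3, seed=3)
    alpha = UnitDef("alpha", (0,), 1, MappingTable((0, 1)),
                    background=frozenset({2}))
    system = MacroSystem(u, (alpha,))
    modified = step1_modified_probs(system, alpha)
    # unit 2 keeps inputs from {0, 2}, loses inputs from unit 1
    expected = marginalize_inputs(u.sbn_tpm[:, 2], 3, [1])
    assert np.allclose(modified[:, 2], expected, atol=1e-12)


def test_occupancy_example2_and_mappings(ex2):
    alpha = UnitDef("alpha", (0, 1), 1, AND)
    beta = UnitDef("beta", (2, 3), 1, AND)
    r = _occupancy(MacroSystem(ex2, (alpha, beta)))
    # macro (0,0): the nine micro states with (A,B) != (1,1), (C,D) != (1,1)
    lows = [s for s in range(16) if (s & 0b11) != 0b11 and (s >> 2) != 0b11]
    assert np.allclose(r[lows, 0], 1 / 9, atol=1e-15)
    assert r[:, 0].sum() == pytest.approx(1.0)
    # macro (1,1): only the all-on micro state
    assert r[0b1111, 3] == 1.0


@pytest.mark.parametrize("seed", range(10))
def test_identity_tau1_reduces_to_micro(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 5))
    u = random_universe(n, seed=seed)
    k = int(rng.integers(1, n + 1))
    subset = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
    units = tuple(micro_unit(i, u.unit_labels[i]) for i in subset)
    macro = macro_cause_effect_tpms(MacroSystem(u, units))
    micro = micro_cause_effect_tpms(u, subset)
    assert np.allclose(macro.cause, micro.cause, atol=1e-12)
    assert np.allclose(macro.effect, micro.effect, atol=1e-12)
    assert macro.state == micro.state


@pytest.mark.parametrize("seed", range(3))
def test_macro_tpms_row_stochastic_at_tau2(seed):
    u = random_universe(3, seed=seed, history_length=2)
    unit = UnitDef("J", (0, 1), 2, MappingTable(tuple((s >> 1) & 1
                                                      for s in range(16))))
    tpms = macro_cause_effect_tpms(MacroSystem(u, (unit,)))
    assert np.allclose(tpms.cause.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(tpms.effect.sum(axis=1), 1.0, atol=1e-12)


def test_full_noising_idempotent():
    u = random_universe(3, seed=5)
    once = marginalize_inputs(u.sbn_tpm[:, 1], 3, range(3))
    twice = marginalize_inputs(once, 3, range(3))
    assert np.array_equal(once, twice)


def test_overlapping_units_rejected(ex2):
    a = UnitDef("a", (0, 1), 1, AND)
    b = UnitDef("b", (1, 2), 1, AND)
    with pytest.raises(ValueError, match="overlap"):
        MacroSystem(ex2, (a, b))


def test_heterogeneous_tau_rejected(ex2):
    a = UnitDef("a", (0, 1), 1, AND)
    b = UnitDef("b", (2,), 2, MappingTable((0, 1, 0, 0)))
    with pytest.raises(ValueError, match="heterogeneous"):
        MacroSystem(ex2, (a, b))


def test_short_history_rejected(ex1):
    unit = UnitDef("J", (0, 1), 2, MappingTable(tuple((s >> 3) & 1
                                                      for s in range(16))))
    with pytest.raises(ValueError, match="history"):
        macro_cause_effect_tpms(MacroSystem(ex1, (unit,)))


def test_step2_tau1_equals_state_by_state(ex1):
    from grainphi.macro import step2_sequence_probs
    from grainphi.tpm import expand_to_state_by_state
    assert np.allclose(step2_sequence_probs(ex1.sbn_tpm, 1),
                       expand_to_state_by_state(ex1.sbn_tpm), atol=1e-15)


def test_step2_mass_conserved_and_deterministic_chain():
    from grainphi.macro import step2_sequence_probs
    u = random_universe(2, seed=4)
    seq = step2_sequence_probs(u.sbn_tpm, 2)
    assert np.allclose(seq.sum(axis=1), 1.0, atol=1e-12)
    # deterministic cycle 0 -> 1 -> 2 -> 3 -> 0: point mass on the one path
    det = np.zeros((4, 2))
    for s in range(4):
        nxt = (s + 1) % 4
        det[s] = [(nxt >> 0) & 1, (nxt >> 1) & 1]
    seq = step2_sequence_probs(det, 3)
    assert np.allclose(seq.sum(axis=1), 1.0)
    for s in range(4):
        rank = ((s + 1) % 4) + 4 * ((s + 2) % 4) + 16 * ((s + 3) % 4)
        assert seq[s, rank] == 1.0
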