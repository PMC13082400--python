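import numpy as np
import pytest

from grainphi import (CauseEffectTPMs, enumerate_partitions,
                      micro_cause_effect_tpms, phi_s, random_universe)
from grainphi.phi import intrinsic_information
from grainphi.tpm import MicroUniverse, expand_to_state_by_state

from _brute import brute_partitions, brute_phi


def _tpms(cause, effect, state, m):
    return CauseEffectTPMs(cause=np.asarray(cause, float),
                           effect=np.asarray(effect, float),
                           state=state, labels=tuple("AB"[:m]))


def test_uniform_tpm_has_zero_intrinsic_information():
    tpm = np.full((4, 4), 0.25)
    for direction in ("cause", "effect"):
        _, ii = intrinsic_information(tpm, 0, direction)
        assert ii == pytest.approx(0.0, abs=1e-12)


def test_deterministic_copy_one_bit():
    tpm = np.eye(2)
    state, ii = intrinsic_information(tpm, 0, "effect")
    assert state == 0
    assert ii == pytest.approx(1.0)  # log2(1 / 0.5)


def test_partition_set_two_units():
    cuts = {p.cut for p in enumerate_partitions(2)}
    assert cuts == {
        frozenset({(0, 1)}),            # one unidirectional cut
        frozenset({(1, 0)}),            # the other
        frozenset({(0, 1), (1, 0)}),    # full bipartition
    }


def test_single_unit_partition_noises_self():
    parts = enumerate_partitions(1)
    assert len(parts) == 1
    assert parts[0].cut == frozenset({(0, 0)})


@pytest.mark.parametrize("m", [2, 3, 4])
def test_partition_enumeration_matches_brute_force(m):
    ours = {p.cut for p in enumerate_partitions(m)}
    assert ours == set(brute_partitions(m))


@pytest.mark.parametrize("m", [2, 3])
def test_partition_parts_cover_exactly(m):
    for p in enumerate_partitions(m):
        flat = sorted(i for part in p.parts for i in part)
        assert flat == list(range(m))


def test_phi_zero_for_factorized_system():
    # two independent noisy units: every cross cut changes nothing
    sbn = np.array([[0.2, 0.7]] * 4)
    sbn[:, 0] = [0.2, 0.8, 0.2, 0.8]  # A depends on itself only
    sbn[:, 1] = [0.7, 0.7, 0.3, 0.3]  # B depends on itself only
    u = MicroUniverse(("A", "B"), sbn, ((0, 0),))
    result = phi_s(micro_cause_effect_tpms(u, (0, 1)))
    assert result.phi == 0.0


@pytest.mark.parametrize("seed", range(10))
def test_phi_nonnegative(seed):
    u = random_universe(3, seed=seed)
    result = phi_s(micro_cause_effect_tpms(u, (0, 1, 2)))
    assert result.phi >= 0.0


@pytest.mark.parametrize("seed", range(5))
def test_phi_permutation_equivariance(seed):
    u = random_universe(3, seed=seed)
    perm = (2, 0, 1)
    # permuted universe: unit k of v behaves as unit perm[k] of u
    n = 3
    sbn_new = np.empty_like(u.sbn_tpm)
    for row in range(2**n):
        bits = [(row >> k) & 1 for k in range(n)]
        orig_row = sum(bits[k] << perm[k] for k in range(n))
        for col in range(n):
            sbn_new[row, col] = u.sbn_tpm[orig_row, perm[col]]
    state = tuple(u.current_state[perm[k]] for k in range(n))
    v = MicroUniverse(("A", "B", "C"), sbn_new, (state,))
    r_u = phi_s(micro_cause_effect_tpms(u, (0, 1, 2)))
    r_v = phi_s(micro_cause_effect_tpms(v, (0, 1, 2)))
    assert r_v.phi == pytest.approx(r_u.phi, abs=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_phi_matches_brute_oracle(seed):
    n = 2 + seed % 3
    u = random_universe(n, seed=seed)
    tpms = micro_cause_effect_tpms(u, tuple(range(n)))
    expected = brute_phi(tpms.cause.tolist(), tpms.effect.tolist(), tpms.state)
    assert phi_s(tpms).phi == pytest.approx(expected, abs=1e-12)


def test_example1_single_units_reducible(ex1):
    # with the neighbor clamped at 0 a unit's effect TPM is state-independent
    for system in ((0,), (1,)):
        assert phi_s(micro_cause_effect_tpms(ex1, system)).phi == 0.0


def test_phi_result_reports_mip_and_states(ex1):
    result = phi_s(micro_cause_effect_tpms(ex1, (0, 1)))
    assert result.phi == pytest.approx(min(result.phi_cause, result.phi_effect))
    assert result.phi <= result.ii_cause + 1e-12
    assert result.phi <= result.ii_effect + 1e-12
    assert len(result.mip.cut) == 2  # full bipartition of the coupled pair
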