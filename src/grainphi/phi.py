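"""System integrated information (phi_s) from cause and effect TPMs.

Implements the IIT 4.0 system-level quantities in bits (base-2 logs):

* intrinsic information ``ii`` of a system state about a candidate cause or
  effect state: selectivity times informativeness, where informativeness is
  measured against the unconstrained transition probability obtained by
  perturbing the system uniformly into all its states;
* directional system partitions (every part of a k-partition loses either
  its inputs from the rest, its outputs to the rest, or both; severed
  connections are noised by uniform marginalization);
* integrated information ``phi`` over a partition: the loss of
  informativeness about the selected cause/effect state when the severed
  connections are noised, weighted by the intact selectivity;
* ``phi_s``: the minimum of cause and effect integrated information at the
  minimum partition (the partition that makes the least difference,
  compared on per-severed-connection normalized values).

The computation is exact (full enumeration); it is intended for desk-scale
systems of up to ~8 units.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .background import CauseEffectTPMs
from .tpm import all_states, marginalize_inputs

#: absolute tolerance when comparing phi values
PHI_ATOL = 1e-10


@dataclass(frozen=True)
class SystemPartition:
    """A directional system partition.

    ``parts`` are disjoint nonempty index sets covering the system;
    ``cut`` is the set of severed directed unit pairs (source, target).
    """

    parts: tuple[tuple[int, ...], ...]
    cut: frozenset

    def __str__(self) -> str:
        parts = ",".join("{" + "".join(map(str, p)) + "}" for p in self.parts)
        cut = ";".join(f"{a}->{b}" for a, b in sorted(self.cut))
        return f"parts[{parts}] cut[{cut}]"


@dataclass
class PhiResult:
    """phi_s together with the quantities that determine it."""

    phi: float
    cause_state: int
    effect_state: int
    ii_cause: float
    ii_effect: float
    mip: SystemPartition
    phi_cause: float
    phi_effect: float
    tied_mip: bool = False


def _set_partitions(items: tuple[int, ...]):
    """All partitions of ``items`` into >= 1 blocks (restricted growth)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def enumerate_partitions(n_units: int) -> list[SystemPartition]:
    """The IIT 4.0 directional system-partition set.

    For one unit, the only partition severs the unit's self-connection
    (complete noising), so single units can still be irreducible.  For
    larger systems: every partition of the units into k >= 2 parts, with
    each part losing its inputs from the rest, its outputs to the rest, or
    both; duplicate cut sets are emitted once, in canonical order.
    """
    units = tuple(range(n_units))
    if n_units == 1:
        return [SystemPartition(parts=((0,),), cut=frozenset({(0, 0)}))]
    seen: dict[frozenset, SystemPartition] = {}
    for blocks in _set_partitions(units):
        if len(blocks) < 2:
            continue
        blocks = tuple(tuple(sorted(b)) for b in sorted(blocks))
        for dirs in product(("in", "out"), repeat=len(blocks)):
            cut = set()
            for block, d in zip(blocks, dirs):
                rest = [u for u in units if u not in block]
                if d == "out":
                    cut.update((a, b) for a in block for b in rest)
                else:
                    cut.update((b, a) for a in block for b in rest)
            key = frozenset(cut)
            if key not in seen:
                seen[key] = SystemPartition(parts=blocks, cut=key)
    return [seen[k] for k in sorted(seen, key=lambda c: (len(c), sorted(c)))]


def _per_unit_on_probabilities(tpm: np.ndarray, m: int) -> np.ndarray:
    """(2**m, m) array of p(x'_i = 1 | s) extracted from a product-form TPM."""
    states = all_states(m)
    return tpm @ states.astype(float)


def _partitioned_on_probabilities(p1: np.ndarray, m: int,
                                  cut: frozenset) -> np.ndarray:
    """Noise severed inputs: uniform marginalization per target unit."""
    out = np.empty_like(p1)
    for i in range(m):
        sources = [a for (a, b) in cut if b == i]
        out[:, i] = marginalize_inputs(p1[:, i], m, sources)
    return out


def _joint_probability(p1_row: np.ndarray, target: int, m: int) -> float:
    """prod_i p(x'_i = bit_i(target)) from per-unit on-probabilities."""
    prob = 1.0
    for i in range(m):
        bit = (target >> i) & 1
        prob *= p1_row[i] if bit else 1.0 - p1_row[i]
    return prob


def _xlog2(x: float, num: float, den: float) -> float:
    """x * log2(num/den) with the 0*log(0) -> 0 convention."""
    if x == 0.0 or num == 0.0:
        return 0.0
    if den == 0.0:
        return np.inf if x > 0 else -np.inf
    return x * np.log2(num / den)


def intrinsic_information(tpm: np.ndarray, state: int, direction: str
                          ) -> tuple[int, float]:
    """Selected cause/effect state and its intrinsic information in bits.

    Effect direction: ii_e(s, s') = p_e(s'|s) log2[p_e(s'|s) / p_e(s')],
    with p_e(s') the unconstrained probability of s' (uniform perturbation
    of the current state).  Cause direction: the selectivity is the Bayesian
    posterior over prior states given s (uniform prior), and informativeness
    compares the forward probability of s from the candidate cause with its
    unconstrained probability.  Ties break toward the lowest state index.
    """
    tpm = np.asarray(tpm, dtype=float)
    n_states = tpm.shape[0]
    if direction == "effect":
        row = tpm[state]
        unconstrained = tpm.mean(axis=0)
        best_state, best_ii = 0, -np.inf
        for s_prime in range(n_states):
            ii = _xlog2(row[s_prime], row[s_prime], unconstrained[s_prime])
            if ii > best_ii + PHI_ATOL:
                best_state, best_ii = s_prime, ii
        return best_state, best_ii
    if direction == "cause":
        col = tpm[:, state]
        denom = col.sum()
        if denom <= 0:
            raise ValueError("current state has zero probability under the cause TPM")
        posterior = col / denom
        unconstrained = denom / n_states
        best_state, best_ii = 0, -np.inf
        for s_prime in range(n_states):
            ii = _xlog2(posterior[s_prime], col[s_prime], unconstrained)
            if ii > best_ii + PHI_ATOL:
                best_state, best_ii = s_prime, ii
        return best_state, best_ii
    raise ValueError("direction must be 'cause' or 'effect'")


def phi_s(tpms: CauseEffectTPMs, partitions: list[SystemPartition] | None = None
          ) -> PhiResult:
    """System integrated information of a system given its T_c and T_e.

    phi_s is the minimum of the cause- and effect-side integrated
    information over the minimum partition.  The minimum partition is the
    one with the smallest integrated information per severed connection;
    the reported phi values are unnormalized.
    """
    m = tpms.n_units
    s0 = tpms.state
    cause_tpm = np.asarray(tpms.cause, dtype=float)
    effect_tpm = np.asarray(tpms.effect, dtype=float)
    if partitions is None:
        partitions = enumerate_partitions(m)

    effect_state, ii_effect = intrinsic_information(effect_tpm, s0, "effect")
    cause_state, ii_cause = intrinsic_information(cause_tpm, s0, "cause")

    # intact quantities entering phi
    p1_e = _per_unit_on_probabilities(effect_tpm, m)
    p1_c = _per_unit_on_probabilities(cause_tpm, m)
    p_e_intact = effect_tpm[s0, effect_state]
    cause_col = cause_tpm[:, s0]
    cause_denom = cause_col.sum()
    if cause_denom <= 0:
        raise ValueError("current state has zero probability under the cause TPM")
    selectivity_c = cause_col[cause_state] / cause_denom
    p_c_intact = cause_tpm[cause_state, s0]

    best = None
    tied = False
    for partition in partitions:
        p1_e_cut = _partitioned_on_probabilities(p1_e, m, partition.cut)
        p1_c_cut = _partitioned_on_probabilities(p1_c, m, partition.cut)
        p_e_cut = _joint_probability(p1_e_cut[s0], effect_state, m)
        p_c_cut = _joint_probability(p1_c_cut[cause_state], s0, m)
        phi_e = max(0.0, _xlog2(p_e_intact, p_e_intact, p_e_cut))
        phi_c = max(0.0, _xlog2(selectivity_c, p_c_intact, p_c_cut))
        phi = min(phi_c, phi_e)
        score = phi / len(partition.cut)
        if best is None or score < best[0] - PHI_ATOL:
            best = (score, phi, phi_c, phi_e, partition)
            tied = False
        elif abs(score - best[0]) <= PHI_ATOL:
            # among equally normalized partitions, the minimum partition is
            # the one severing the most connections (the union of tied cuts)
            tied = True
            if len(partition.cut) > len(best[4].cut):
                best = (best[0], phi, phi_c, phi_e, partition)
    assert best is not None
    _, phi, phi_c, phi_e, mip = best
    return PhiResult(
        phi=phi,
        cause_state=cause_state,
        effect_state=effect_state,
        ii_cause=ii_cause,
        ii_effect=ii_effect,
        mip=mip,
        phi_cause=phi_c,
        phi_effect=phi_e,
        tied_mip=tied,
    )
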