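"""Macro cause/effect TPMs via the four-step construction.

Given a universe and a system of (possibly macro) units, the system's cause
and effect TPMs at the units' grain are built in four steps:

1. for each unit J, noise the micro connections that are extrinsic to J's
   update: constituents of J keep all inputs; other system constituents and
   unapportioned background are fully noised; a unit's apportioned
   background keeps inputs only from that unit and its apportionment;
2. chain the modified one-step probabilities into probabilities of
   sequences of tau micro updates;
3. causally marginalize the background conditional on the trailing tau
   micro states (current state for effects; a Bayesian average over the
   state tau updates back, driven by the earliest state in the window, for
   causes);
4. compress micro state-by-sequence probabilities into macro state-by-state
   probabilities using the units' mappings, perturbing each macro unit into
   its states via a uniform distribution over the qualifying micro
   sequences, and recombine per-unit results as a product.

With tau = 1 and identity mappings the construction reduces exactly to the
micro-grain conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .background import CauseEffectTPMs
from .errors import GuardError
from .tpm import (MicroUniverse, all_states, expand_to_state_by_state,
                  marginalize_inputs, state_index)
from .units import UnitDef, compose_micro_mapping, sequence_rank, unit_state

#: refuse sequence spaces larger than this (|states of U^S| ** tau)
SEQUENCE_SPACE_GUARD = 2**20


@dataclass(frozen=True)
class MacroSystem:
    """A candidate system of non-overlapping units over a universe."""

    universe: MicroUniverse
    units: tuple[UnitDef, ...]

    def __post_init__(self) -> None:
        n = self.universe.n
        claimed: dict[int, str] = {}
        for unit in self.units:
            for i in unit.micro_constituents | unit.background:
                if not 0 <= i < n:
                    raise ValueError(f"unit {unit.label}: micro index {i} out of range")
                if i in claimed:
                    raise ValueError(
                        f"units {claimed[i]} and {unit.label} overlap on micro "
                        f"unit {self.universe.unit_labels[i]}"
                    )
                claimed[i] = unit.label
        taus = {unit.tau for unit in self.units}
        if len(taus) != 1:
            raise ValueError(
                f"units with heterogeneous micro update grains {sorted(taus)} "
                "are unsupported; all units of a system must share tau"
            )

    @property
    def tau(self) -> int:
        return self.units[0].tau

    @property
    def system_micro(self) -> tuple[int, ...]:
        out: set[int] = set()
        for unit in self.units:
            out |= unit.micro_constituents
        return tuple(sorted(out))

    @property
    def background_micro(self) -> tuple[int, ...]:
        sys = set(self.system_micro)
        return tuple(i for i in range(self.universe.n) if i not in sys)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(unit.label for unit in self.units)

    def current_macro_state(self) -> tuple[int, ...]:
        self.universe.require_history(self.tau)
        return tuple(unit_state(u, self.universe.current_history) for u in self.units)


def step1_modified_probs(system: MacroSystem, target: UnitDef) -> np.ndarray:
    """Modified state-by-node probabilities p_hat_J for one target unit."""
    universe = system.universe
    n = universe.n
    sys_micro = set(system.system_micro)
    target_micro = target.micro_constituents
    apportionments = {unit.label: unit.background for unit in system.units}
    out = np.empty_like(universe.sbn_tpm)
    for i in range(n):
        col = universe.sbn_tpm[:, i]
        if i in target_micro:
            out[:, i] = col  # constituent of the unit being updated: intact
            continue
        owner = next((lab for lab, w in apportionments.items() if i in w), None)
        if owner is not None:
            # apportioned background: keep inputs from its unit and
            # apportionment, noise everything else
            keep = set(next(u for u in system.units if u.label == owner)
                       .micro_constituents)
            keep |= set(apportionments[owner])
            out[:, i] = marginalize_inputs(col, n, set(range(n)) - keep)
        else:
            # other system constituents and unapportioned background:
            # fully noised (input-independent uniform average)
            out[:, i] = marginalize_inputs(col, n, range(n))
    return out


def step2_sequence_probs(modified_sbn, tau: int):
    """State-by-sequence probabilities under a (modified) universe TPM.

    Entry (u, r) is the probability of the sequence of ``tau`` successor
    states with rank ``r`` (earliest state least significant), starting
    from state ``u``: the Markov chain-rule product over tau steps.
    """
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    tpm = expand_to_state_by_state(modified_sbn)
    n_states = tpm.shape[0]
    if n_states**tau > SEQUENCE_SPACE_GUARD:
        raise GuardError(
            f"sequence space of size {n_states}**{tau} exceeds the guard "
            f"({SEQUENCE_SPACE_GUARD})"
        )
    out = tpm.copy()  # tau = 1: columns are the first successor state
    lasts = np.arange(n_states)  # last state of the sequence in each column
    for _ in range(tau - 1):
        width = out.shape[1]
        new = np.empty((n_states, width * n_states))
        for s_next in range(n_states):
            new[:, s_next * width:(s_next + 1) * width] = \
                out * tpm[lasts, s_next][None, :]
        out = new
        lasts = np.repeat(np.arange(n_states), width)
    return out


def _sequence_outcome_probs(system: MacroSystem, target: UnitDef,
                            q_weights: np.ndarray) -> np.ndarray:
    """(2**|U^S|, 2): probability that the target unit lands in state j,
    for every current micro state of the system's constituents, with the
    initial background distributed per ``q_weights``."""
    universe = system.universe
    n = universe.n
    tau = system.tau
    sys_micro = system.system_micro
    bg_micro = system.background_micro
    n_sys = 2 ** len(sys_micro)

    tpm_hat = expand_to_state_by_state(step1_modified_probs(system, target))

    # initial distribution over full states, one column per system state
    init = np.zeros((2**n, n_sys))
    for s_idx in range(n_sys):
        for w_idx, weight in enumerate(q_weights):
            if weight == 0.0:
                continue
            state = [0] * n
            for k, i in enumerate(sys_micro):
                state[i] = (s_idx >> k) & 1
            for k, i in enumerate(bg_micro):
                state[i] = (w_idx >> k) & 1
            init[state_index(state), s_idx] += weight

    # group full states by the local state of the target's constituents
    target_micro = tuple(sorted(target.micro_constituents))
    states = all_states(n)
    local = states[:, target_micro] @ (1 << np.arange(len(target_micro)))
    masks = [local == v for v in range(2 ** len(target_micro))]

    g_table = compose_micro_mapping(target)
    out = np.zeros((n_sys, 2))

    def recurse(v: np.ndarray, prefix: tuple[int, ...]) -> None:
        if len(prefix) == tau:
            out[:, g_table[prefix]] += v.sum(axis=0)
            return
        stepped = tpm_hat.T @ v
        for sigma in range(2 ** len(target_micro)):
            nxt = stepped * masks[sigma][:, None]
            if nxt.any():
                recurse(nxt, prefix + (sigma,))

    recurse(init, ())
    return out


def _cause_weights(system: MacroSystem) -> np.ndarray:
    """q_c over background states: Bayes from the earliest state in the
    current tau-step window, uniform prior over the state tau updates back."""
    universe = system.universe
    tau = system.tau
    universe.require_history(tau)
    earliest = universe.current_history[-tau]
    tss = expand_to_state_by_state(universe.sbn_tpm)
    col = tss[:, state_index(earliest)]
    denom = col.sum()
    if denom <= 0:
        raise ValueError(
            f"state {earliest} is unreachable from every prior state; "
            "cause marginalization is undefined"
        )
    sys_micro = system.system_micro
    bg_micro = system.background_micro
    weights = np.zeros(2 ** len(bg_micro))
    n = universe.n
    for w_idx in range(len(weights)):
        total = 0.0
        for s_idx in range(2 ** len(sys_micro)):
            state = [0] * n
            for k, i in enumerate(sys_micro):
                state[i] = (s_idx >> k) & 1
            for k, i in enumerate(bg_micro):
                state[i] = (w_idx >> k) & 1
            total += col[state_index(state)]
        weights[w_idx] = total / denom
    return weights


def _effect_weights(system: MacroSystem) -> np.ndarray:
    u0 = system.universe.current_state
    bg = system.background_micro
    weights = np.zeros(2 ** len(bg))
    weights[state_index([u0[i] for i in bg])] = 1.0
    return weights


def _occupancy(system: MacroSystem) -> np.ndarray:
    """r(u^S, s): (2**|U^S|, 2**|S|) proportion of qualifying sequences.

    Entry (u, s) is the fraction of micro-state sequences mapped to macro
    state s that end in micro state u; each macro unit is perturbed into
    its state via a uniform distribution over qualifying sequences.
    """
    sys_micro = system.system_micro
    tau = system.tau
    n_sys = 2 ** len(sys_micro)
    if n_sys**tau > SEQUENCE_SPACE_GUARD:
        raise GuardError(
            f"sequence space of size {n_sys}**{tau} exceeds the guard "
            f"({SEQUENCE_SPACE_GUARD})"
        )
    pos = {i: k for k, i in enumerate(sys_micro)}
    unit_tables = []
    for unit in system.units:
        table = compose_micro_mapping(unit)
        unit_micro = tuple(sorted(unit.micro_constituents))
        unit_tables.append((unit_micro, table))

    counts = np.zeros((n_sys, 2 ** len(system.units)))
    for seq in product(range(n_sys), repeat=tau):
        macro_bits = []
        for unit_micro, table in unit_tables:
            local_seq = tuple(
                sum(((s >> pos[i]) & 1) << k for k, i in enumerate(unit_micro))
                for s in seq
            )
            macro_bits.append(table[local_seq])
        s_idx = sum(b << k for k, b in enumerate(macro_bits))
        counts[seq[-1], s_idx] += 1.0
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        missing = int(np.argmin(totals))
        raise ValueError(f"macro state index {missing} is unreachable by any "
                         "micro-state sequence")
    return counts / totals


def macro_cause_effect_tpms(system: MacroSystem) -> CauseEffectTPMs:
    """Run steps 1-4 for every unit and assemble T_c and T_e."""
    n_units = len(system.units)
    r = _occupancy(system)
    q_by_direction = {
        "cause": _cause_weights(system),
        "effect": _effect_weights(system),
    }
    tpms = {}
    for direction, q in q_by_direction.items():
        per_unit = np.empty((2**n_units, n_units, 2))
        for u_idx, unit in enumerate(system.units):
            outcome = _sequence_outcome_probs(system, unit, q)  # (2**|U^S|, 2)
            per_unit[:, u_idx, :] = r.T @ outcome
        tpm = np.ones((2**n_units, 2**n_units))
        states = all_states(n_units)
        for u_idx in range(n_units):
            p1 = per_unit[:, u_idx, 1][:, None]
            bit = states[:, u_idx][None, :]
            tpm *= np.where(bit == 1, p1, 1.0 - p1)
        tpms[direction] = tpm
    s0 = system.current_macro_state()
    return CauseEffectTPMs(
        cause=tpms["cause"],
        effect=tpms["effect"],
        state=state_index(s0),
        labels=system.labels,
    )
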