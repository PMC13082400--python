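"""Causal marginalization of background units at the micro grain.

A candidate system S within a universe U sees the remaining units
W = U \\ S as *background conditions*.  For effects, the background is held
at its current state.  For causes, the background's past state is inferred
by Bayes' rule from the current universe state, assuming a uniform marginal
over previous states.  Either way the per-unit transition probabilities are
averaged over background states first and then recombined as a product,
which restores conditional independence among the system's units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tpm import MicroUniverse, all_states, expand_to_state_by_state, state_index


@dataclass(frozen=True)
class BackgroundDistribution:
    """Distribution over background states w, for one direction of analysis."""

    direction: str  # "cause" or "effect"
    background_units: tuple[int, ...]
    weights: np.ndarray  # one weight per state of the background units

    def __post_init__(self) -> None:
        if self.direction not in ("cause", "effect"):
            raise ValueError("direction must be 'cause' or 'effect'")
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < -1e-15):
            raise ValueError("background weights must form a distribution")


@dataclass
class CauseEffectTPMs:
    """Cause and effect TPMs of a system, at any grain.

    Both are row-stochastic state-by-state matrices over the system's state
    space, in exact per-unit product form, together with the index of the
    system's current state.
    """

    cause: np.ndarray
    effect: np.ndarray
    state: int
    labels: tuple[str, ...]

    @property
    def n_units(self) -> int:
        return len(self.labels)


def _embed(system: tuple[int, ...], background: tuple[int, ...],
           s_idx: int, w_idx: int, n: int) -> int:
    """Universe state index from system- and background-state indices."""
    state = [0] * n
    for k, unit in enumerate(system):
        state[unit] = (s_idx >> k) & 1
    for k, unit in enumerate(background):
        state[unit] = (w_idx >> k) & 1
    return state_index(state)


def effect_background(universe: MicroUniverse, system: tuple[int, ...]) -> BackgroundDistribution:
    """Point mass on the background's current state (q_e)."""
    background = tuple(i for i in range(universe.n) if i not in system)
    u0 = universe.current_state
    weights = np.zeros(2 ** len(background))
    weights[state_index([u0[i] for i in background])] = 1.0
    return BackgroundDistribution("effect", background, weights)


def cause_background(universe: MicroUniverse, system: tuple[int, ...],
                     current: tuple[int, ...] | None = None) -> BackgroundDistribution:
    """Bayesian distribution over past background states (q_c).

    q_c(w|u) = sum_sbar p(u | sbar, w) / sum_ubar p(u | ubar), with a
    uniform marginal over previous universe states.  Raises if the current
    state is unreachable from every prior state (zero denominator), which
    signals a modeling mistake in a universe meant to be noisy.
    """
    background = tuple(i for i in range(universe.n) if i not in system)
    u = current if current is not None else universe.current_state
    tss = expand_to_state_by_state(universe.sbn_tpm)
    col = tss[:, state_index(u)]
    denom = col.sum()
    if denom <= 0:
        raise ValueError(
            f"current state {u} is unreachable from every prior state; "
            "cause marginalization is undefined"
        )
    weights = np.zeros(2 ** len(background))
    for w_idx in range(len(weights)):
        total = 0.0
        for s_idx in range(2 ** len(system)):
            total += col[_embed(system, background, s_idx, w_idx, universe.n)]
        weights[w_idx] = total / denom
    return BackgroundDistribution("cause", background, weights)


def _product_tpm(per_unit_p1: np.ndarray) -> np.ndarray:
    """(2**m, m) per-unit on-probabilities -> (2**m, 2**m) product TPM."""
    m = per_unit_p1.shape[1]
    states = all_states(m)
    tpm = np.ones((2**m, 2**m))
    for i in range(m):
        p1 = per_unit_p1[:, i][:, None]
        bit = states[:, i][None, :]
        tpm *= np.where(bit == 1, p1, 1.0 - p1)
    return tpm


def _system_tpm(universe: MicroUniverse, system: tuple[int, ...],
                q: BackgroundDistribution) -> np.ndarray:
    background = q.background_units
    per_unit = np.zeros((2 ** len(system), len(system)))
    for s_idx in range(2 ** len(system)):
        for w_idx, weight in enumerate(q.weights):
            if weight == 0.0:
                continue
            row = universe.sbn_tpm[_embed(system, background, s_idx, w_idx, universe.n)]
            for k, unit in enumerate(system):
                per_unit[s_idx, k] += weight * row[unit]
    return _product_tpm(per_unit)


def system_effect_tpm(universe: MicroUniverse, system: tuple[int, ...]) -> np.ndarray:
    """Effect TPM T_e: background clamped at its current state."""
    if not system:
        raise ValueError("system must be nonempty")
    return _system_tpm(universe, system, effect_background(universe, system))


def system_cause_tpm(universe: MicroUniverse, system: tuple[int, ...]) -> np.ndarray:
    """Cause TPM T_c: background averaged under the Bayesian weights q_c."""
    if not system:
        raise ValueError("system must be nonempty")
    return _system_tpm(universe, system, cause_background(universe, system))


def micro_cause_effect_tpms(universe: MicroUniverse,
                            system: tuple[int, ...]) -> CauseEffectTPMs:
    """Cause and effect TPMs for a micro-grain candidate system."""
    system = tuple(int(i) for i in system)
    u0 = universe.current_state
    return CauseEffectTPMs(
        cause=system_cause_tpm(universe, system),
        effect=system_effect_tpm(universe, system),
        state=state_index([u0[i] for i in system]),
        labels=tuple(universe.unit_labels[i] for i in system),
    )
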