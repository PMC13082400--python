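"""Example universes built from parametric additive unit rules.

Every in-text example system is a small grid of noisy-logic units whose
activation probability is a base rate plus additive increments contingent on
the current states of specific input units.  The rules here are pure
functions of printed constants, so the fixtures regenerate identically on
every call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .tpm import MicroUniverse, all_states


@dataclass(frozen=True)
class AdditiveRuleSpec:
    """Additive activation rule: base rate plus state-contingent increments.

    ``increments`` maps predicates over the current universe state (as a
    tuple of bits) to additive probability deltas.  Any input state whose
    total leaves [0, 1] is rejected outright -- silent clipping would change
    the model.
    """

    base: float
    increments: tuple[tuple[Callable[[tuple[int, ...]], bool], float], ...]

    def probability(self, state: tuple[int, ...]) -> float:
        p = self.base + sum(delta for pred, delta in self.increments if pred(state))
        if not 0.0 <= p <= 1.0:
            raise ValueError(
                f"additive rule yields probability {p} outside [0, 1] "
                f"for input state {state}"
            )
        return p


def universe_from_rules(
    labels: Sequence[str],
    rules: Sequence[AdditiveRuleSpec],
    history: Sequence[Sequence[int]],
) -> MicroUniverse:
    n = len(labels)
    states = all_states(n)
    sbn = np.empty((2**n, n))
    for row, state in enumerate(map(tuple, states)):
        for i, rule in enumerate(rules):
            sbn[row, i] = rule.probability(state)
    return MicroUniverse(tuple(labels), sbn, tuple(tuple(s) for s in history))


def example1_universe() -> MicroUniverse:
    """Two mutually coupled noisy-AND-like units {A, B}, state (0, 0).

    Each unit turns on with probability 0.05 at baseline (unaffected when
    only the unit itself is 1), 0.06 when only its neighbor is 1, and 0.95
    when both the unit and its neighbor are 1.
    """

    def rule(self_i: int, other_i: int) -> AdditiveRuleSpec:
        return AdditiveRuleSpec(
            base=0.05,
            increments=(
                (lambda s, a=self_i, b=other_i: s[a] == 0 and s[b] == 1, 0.01),
                (lambda s, a=self_i, b=other_i: s[a] == 1 and s[b] == 1, 0.90),
            ),
        )

    return universe_from_rules(("A", "B"), (rule(0, 1), rule(1, 0)), [(0, 0)])


# layout of the 2x2 grid examples: A-B and C-D horizontal pairs,
# A/C and B/D vertical pairs, A/D and B/C diagonal pairs
_GRID_HORIZONTAL = {0: 1, 1: 0, 2: 3, 3: 2}
_GRID_VERTICAL = {0: 2, 1: 3, 2: 0, 3: 1}
_GRID_DIAGONAL = {0: 3, 1: 2, 2: 1, 3: 0}


def example2_universe() -> MicroUniverse:
    """Four units {A, B, C, D} on a 2x2 grid, state (0, 0, 0, 0).

    Rule per unit: base 0.05; +0.01 if the unit itself is 1; +0.1 if its
    horizontal neighbor is 1; +0.8 if its vertical AND diagonal neighbors
    are both 1 (a noisy AND over the opposite horizontal pair).  Partial
    (one-of-two) vertical/diagonal activation contributes nothing.
    """

    def rule(i: int) -> AdditiveRuleSpec:
        h, v, d = _GRID_HORIZONTAL[i], _GRID_VERTICAL[i], _GRID_DIAGONAL[i]
        return AdditiveRuleSpec(
            base=0.05,
            increments=(
                (lambda s, a=i: s[a] == 1, 0.01),
                (lambda s, a=h: s[a] == 1, 0.10),
                (lambda s, a=v, b=d: s[a] == 1 and s[b] == 1, 0.80),
            ),
        )

    return universe_from_rules(
        ("A", "B", "C", "D"), tuple(rule(i) for i in range(4)), [(0, 0, 0, 0)]
    )


def fig2_universe(vertical_delta: float = 0.0) -> MicroUniverse:
    """Four units on a 2x2 grid with tunable vertical coupling, state 0000.

    Rule per unit: base 0.05; +0.05 if the unit itself is 1; +0.6 if its
    horizontal neighbor is 1; +``vertical_delta`` if its vertical neighbor
    is 1.  ``vertical_delta`` in [0, 0.3] (0, 0.01 and 0.25 are the cases of
    interest; larger values overflow the probability scale).
    """
    if not 0.0 <= vertical_delta <= 0.3:
        raise ValueError("vertical_delta must be in [0, 0.3]")

    def rule(i: int) -> AdditiveRuleSpec:
        h, v = _GRID_HORIZONTAL[i], _GRID_VERTICAL[i]
        return AdditiveRuleSpec(
            base=0.05,
            increments=(
                (lambda s, a=i: s[a] == 1, 0.05),
                (lambda s, a=h: s[a] == 1, 0.60),
                (lambda s, a=v: s[a] == 1, vertical_delta),
            ),
        )

    return universe_from_rules(
        ("A", "B", "C", "D"), tuple(rule(i) for i in range(4)), [(0, 0, 0, 0)]
    )


@dataclass(frozen=True)
class MirrorParams:
    """Coupling strengths for the eight-unit mirror-symmetric universe."""

    base: float = 0.05
    self_delta: float = 0.02
    copy_delta: float = 0.85      # A,B copy the mirror hub G (and E,F copy C)
    or_delta: float = 0.85        # C is a noisy OR of A and B
    drive_delta: float = 0.25     # D accumulates linearly from A, B, C
    feedback_delta: float = 0.05  # weak D feedback onto A and B

    def __post_init__(self) -> None:
        worst = self.base + self.self_delta + max(
            self.copy_delta + self.feedback_delta,
            self.or_delta,
            3 * self.drive_delta,
        )
        if worst > 1.0:
            raise ValueError(f"parameter set overflows probability scale ({worst})")


def mirror_universe(params: MirrorParams | None = None) -> MicroUniverse:
    """Eight-unit mirror-symmetric black-box-style universe (synthetic).

    Two four-unit halves {A,B,C,D} and {E,F,G,H} wired as mirror images:
    the hub of each half (C resp. G) is a noisy OR of its half's input units
    (A,B resp. E,F), the input units copy the opposite half's hub, D (resp.
    H) is driven linearly by its half's units with weak feedback onto the
    input units, and every unit has weak self-persistence.  The numeric
    strengths are free parameters: this is a structural stand-in used for
    property tests only, not a reproduction of any published TPM.
    """
    p = params or MirrorParams()
    labels = ("A", "B", "C", "D", "E", "F", "G", "H")
    A, B, C, D, E, F, G, H = range(8)

    def copy_rule(i: int, hub: int, fb: int) -> AdditiveRuleSpec:
        return AdditiveRuleSpec(
            base=p.base,
            increments=(
                (lambda s, a=i: s[a] == 1, p.self_delta),
                (lambda s, a=hub: s[a] == 1, p.copy_delta),
                (lambda s, a=fb: s[a] == 1, p.feedback_delta),
            ),
        )

    def or_rule(i: int, in1: int, in2: int) -> AdditiveRuleSpec:
        return AdditiveRuleSpec(
            base=p.base,
            increments=(
                (lambda s, a=i: s[a] == 1, p.self_delta),
                (lambda s, a=in1, b=in2: s[a] == 1 or s[b] == 1, p.or_delta),
            ),
        )

    def drive_rule(i: int, ins: tuple[int, int, int]) -> AdditiveRuleSpec:
        return AdditiveRuleSpec(
            base=p.base,
            increments=tuple(
                [(lambda s, a=i: s[a] == 1, p.self_delta)]
                + [(lambda s, a=j: s[a] == 1, p.drive_delta) for j in ins]
            ),
        )

    rules = (
        copy_rule(A, G, D),
        copy_rule(B, G, D),
        or_rule(C, A, B),
        drive_rule(D, (A, B, C)),
        copy_rule(E, C, H),
        copy_rule(F, C, H),
        or_rule(G, E, F),
        drive_rule(H, (E, F, G)),
    )
    return universe_from_rules(labels, rules, [(1,) * 8])


def random_universe(
    n: int, seed: int, noise_floor: float = 0.05, history_length: int = 1
) -> MicroUniverse:
    """Seeded random universe with every probability in [floor, 1 - floor].

    The floor guarantees some indeterminism, so every current state is
    reachable and cause repertoires are well defined.
    """
    if not 1 <= n <= 6:
        raise ValueError("random universes support 1 <= n <= 6 units")
    if not 0.0 < noise_floor <= 0.5:
        raise ValueError("noise_floor must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    sbn = noise_floor + (1 - 2 * noise_floor) * rng.random((2**n, n))
    labels = tuple("ABCDEF"[:n])
    history = tuple(
        tuple(int(b) for b in rng.integers(0, 2, n)) for _ in range(history_length)
    )
    return MicroUniverse(labels, sbn, history)
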