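"""Units across grains: the 5-tuple definition, mappings, composition.

A unit J is defined by its micro constituents U^J, its direct constituents
V^J (micro units or finer-grain units), an update grain tau' counted in
constituent updates, a binary mapping g' from sequences of tau' constituent
states to {0, 1}, and a background apportionment W^J.  Composing the
hierarchy of mappings yields the micro-grain quantities: the micro update
grain tau (the product of the grains down the hierarchy) and a mapping g
from sequences of tau micro states of U^J to the unit's state.

Micro states and constituent states are indexed little-endian throughout; a
sequence of states is iterated earliest-first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, Sequence, Union

import numpy as np

from .errors import GuardError

#: refuse to enumerate mapping tables with more input sequences than this
MAPPING_ENUMERATION_GUARD = 16


@dataclass(frozen=True)
class MappingTable:
    """Complete binary truth table over sequences of constituent states.

    ``bits[k]`` is the output for the k-th input sequence, where a sequence
    (x_1, ..., x_tau') of constituent-state indices (earliest first) has
    rank ``sum_t x_t * n_states**t'`` with the earliest state least
    significant.  Constant tables do not define a unit (the unit's two
    states must both be attainable) and are rejected.
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("mapping outputs must be bits")
        if len(set(self.bits)) < 2:
            raise ValueError("mapping must be non-constant")

    @property
    def n_inputs(self) -> int:
        return len(self.bits)

    def __call__(self, sequence_rank: int) -> int:
        return self.bits[sequence_rank]

    @property
    def truth_table_integer(self) -> int:
        """Canonical integer encoding (bit k = output for input rank k)."""
        return sum(b << k for k, b in enumerate(self.bits))


def sequence_rank(states: Sequence[int], n_states: int) -> int:
    """Rank of a sequence of state indices, earliest state least significant."""
    rank = 0
    for t, s in enumerate(states):
        if not 0 <= s < n_states:
            raise ValueError(f"state index {s} out of range")
        rank += s * n_states**t
    return rank


def enumerate_mappings(k_constituents: int, tau_prime: int,
                       guard: int = MAPPING_ENUMERATION_GUARD
                       ) -> Iterator[MappingTable]:
    """All 2^(2^(tau'*k)) - 2 non-constant mappings, in truth-table order."""
    n_inputs = 2 ** (tau_prime * k_constituents)
    if n_inputs > guard:
        raise GuardError(
            f"{n_inputs} input sequences exceeds the enumeration guard "
            f"({guard}); pass a larger guard to override"
        )
    for code in range(1, 2**n_inputs - 1):
        yield MappingTable(tuple((code >> k) & 1 for k in range(n_inputs)))


IDENTITY = MappingTable((0, 1))
NEGATION = MappingTable((1, 0))


@dataclass(frozen=True)
class UnitDef:
    """A unit at any grain: (U^J, V^J, tau', g', W^J) plus a label.

    ``constituents`` are either micro unit indices (ints) or finer-grain
    :class:`UnitDef` objects; mixing is allowed as long as all constituents
    share the same micro update grain.  ``background`` is the apportionment
    W^J, as micro unit indices; it must contain the constituents'
    apportionments.
    """

    label: str
    constituents: tuple[Union[int, "UnitDef"], ...]
    tau_prime: int = 1
    mapping: MappingTable = IDENTITY
    background: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.tau_prime < 1:
            raise ValueError("update grain must be a positive integer")
        if not self.constituents:
            raise ValueError("a unit needs at least one constituent")
        expected = 2 ** (self.tau_prime * len(self.constituents))
        if self.mapping.n_inputs != expected:
            raise ValueError(
                f"mapping table has {self.mapping.n_inputs} entries; unit with "
                f"{len(self.constituents)} constituents at grain {self.tau_prime} "
                f"needs {expected}"
            )
        micro_sets = [c.micro_constituents if isinstance(c, UnitDef) else
                      frozenset({c}) for c in self.constituents]
        combined: set[int] = set()
        for ms in micro_sets:
            if combined & ms:
                raise ValueError("constituents' micro constituents must be disjoint")
            combined |= ms
        grains = {c.tau for c in self.constituents if isinstance(c, UnitDef)}
        grains |= {1 for c in self.constituents if not isinstance(c, UnitDef)}
        if len(grains) != 1:
            raise ValueError(
                "constituents with unequal micro update grains are unsupported"
            )
        for c in self.constituents:
            if isinstance(c, UnitDef) and not c.background <= self.background:
                raise ValueError(
                    f"background of constituent {c.label} is not contained "
                    f"in the unit's apportionment"
                )
        if self.background & combined:
            raise ValueError("background apportionment overlaps micro constituents")

    # -- derived micro-grain quantities -----------------------------------

    @property
    def micro_constituents(self) -> frozenset:
        out: set[int] = set()
        for c in self.constituents:
            out |= c.micro_constituents if isinstance(c, UnitDef) else {c}
        return frozenset(out)

    @property
    def constituent_tau(self) -> int:
        c = self.constituents[0]
        return c.tau if isinstance(c, UnitDef) else 1

    @property
    def tau(self) -> int:
        """Micro update grain: tau' multiplied down the hierarchy."""
        return self.tau_prime * self.constituent_tau

    @property
    def is_micro(self) -> bool:
        return (
            len(self.constituents) == 1
            and not isinstance(self.constituents[0], UnitDef)
            and self.tau_prime == 1
            and self.mapping == IDENTITY
        )

    # -- evaluation --------------------------------------------------------

    def state_from_micro_sequence(self, sequence: Sequence[Sequence[int]]) -> int:
        """g_J applied to the trailing tau micro states of U^J.

        ``sequence`` holds tau full micro states of the universe (earliest
        first); each is indexed by absolute micro unit index.
        """
        if len(sequence) != self.tau:
            raise ValueError(
                f"unit {self.label} needs exactly {self.tau} micro states, "
                f"got {len(sequence)}"
            )
        ctau = self.constituent_tau
        constituent_states = []
        for t in range(self.tau_prime):
            window = sequence[t * ctau:(t + 1) * ctau]
            bits = []
            for c in self.constituents:
                if isinstance(c, UnitDef):
                    bits.append(c.state_from_micro_sequence(window))
                else:
                    bits.append(int(window[-1][c]))
            idx = sum(b << k for k, b in enumerate(bits))
            constituent_states.append(idx)
        rank = sequence_rank(constituent_states, 2 ** len(self.constituents))
        return self.mapping(rank)


def micro_unit(index: int, label: str | None = None) -> UnitDef:
    """A micro unit wrapped in the general 5-tuple form."""
    return UnitDef(label=label if label is not None else str(index),
                   constituents=(index,))


def compose_micro_mapping(unit: UnitDef, micro_order: Sequence[int] | None = None
                          ) -> dict[tuple[int, ...], int]:
    """Flatten the hierarchy: g_J over sequences of tau states of U^J.

    Returns a table keyed by tuples of ``tau`` local state indices of U^J
    (earliest first, little-endian over ``micro_order``, which defaults to
    the sorted micro constituents).
    """
    micro = tuple(sorted(unit.micro_constituents)) if micro_order is None \
        else tuple(micro_order)
    k = len(micro)
    table: dict[tuple[int, ...], int] = {}
    n_abs = max(micro) + 1
    for seq in product(range(2**k), repeat=unit.tau):
        full_states = []
        for local_idx in seq:
            state = [0] * n_abs
            for pos, abs_idx in enumerate(micro):
                state[abs_idx] = (local_idx >> pos) & 1
            full_states.append(state)
        table[seq] = unit.state_from_micro_sequence(full_states)
    return table


def unit_state(unit: UnitDef, micro_history: Sequence[Sequence[int]]) -> int:
    """The unit's current state from the trailing tau micro states."""
    if len(micro_history) < unit.tau:
        raise ValueError(
            f"unit {unit.label} (micro update grain {unit.tau}) requires a "
            f"history of at least {unit.tau} micro states; got {len(micro_history)}"
        )
    return unit.state_from_micro_sequence(micro_history[-unit.tau:])


def mapping_is_constant_on(unit: UnitDef) -> bool:
    """True if the composed micro-grain mapping cannot attain both states."""
    outputs = set(compose_micro_mapping(unit).values())
    return len(outputs) < 2
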