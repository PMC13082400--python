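"""Admissible units, candidate systems across grains, and complexes.

A candidate macro unit must be *maximally irreducible within*: the system
of its constituents must have phi_s > 0 and strictly greater phi_s than
every other valid system over subsets of its micro constituents (with
backgrounds drawn from non-overlapping subsets of its apportionment and
update grains no coarser than its own).  Candidate systems are built
recursively: micro units give candidate systems, maximally-irreducible
candidate systems become constituents of new units (one mapping per
admissible truth table), new units give new candidate systems, and so on
until no new units appear or the depth cap is reached.

Complexes are identified recursively by repeatedly taking the candidate
with maximal phi_s and discarding every candidate that overlaps its micro
constituents, so reported complexes never share a micro unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .background import micro_cause_effect_tpms
from .errors import GuardError
from .macro import MacroSystem, macro_cause_effect_tpms
from .phi import PhiResult, phi_s
from .tpm import MicroUniverse
from .units import UnitDef, enumerate_mappings, micro_unit, compose_micro_mapping

#: absolute tolerance for the strict inequalities of admissibility/exclusion
STRICT_ATOL = 1e-10


@dataclass(frozen=True)
class SearchConstraints:
    """Enumeration guards for the doubly exponential search space."""

    max_micro_units: int = 6
    max_tau: int = 1
    max_depth: int = 1
    max_unit_constituents: int = 4
    mapping_guard: int = 16


@dataclass
class CandidateSystem:
    """A valid system of non-overlapping units, with its phi_s."""

    units: tuple[UnitDef, ...]
    state: tuple[int, ...]
    phi: float
    result: PhiResult
    depth: int

    @property
    def micro_constituents(self) -> frozenset:
        out: set[int] = set()
        for u in self.units:
            out |= u.micro_constituents
        return frozenset(out)

    @property
    def claimed_micro(self) -> frozenset:
        out: set[int] = set()
        for u in self.units:
            out |= u.micro_constituents | u.background
        return frozenset(out)

    @property
    def tau(self) -> int:
        return self.units[0].tau

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(u.label for u in self.units)


@dataclass
class ComplexReport:
    """Ranked candidates and the non-overlapping complexes among them."""

    candidates: list[CandidateSystem]
    complexes: list[CandidateSystem]
    ties_flagged: list[tuple[tuple[str, ...], tuple[str, ...]]]
    truncated: bool = False


def evaluate_system(universe: MicroUniverse, units: tuple[UnitDef, ...]
                    ) -> CandidateSystem:
    """phi_s of a system of units (micro shortcut when no macroing)."""
    depth = max(_unit_depth(u) for u in units)
    if all(u.is_micro for u in units):
        idx = tuple(sorted(next(iter(u.micro_constituents)) for u in units))
        tpms = micro_cause_effect_tpms(universe, idx)
        state = tuple(universe.current_state[i] for i in idx)
    else:
        system = MacroSystem(universe, units)
        tpms = macro_cause_effect_tpms(system)
        state = system.current_macro_state()
    result = phi_s(tpms)
    return CandidateSystem(units=units, state=state, phi=result.phi,
                           result=result, depth=depth)


def _unit_depth(unit: UnitDef) -> int:
    if unit.is_micro:
        return 0
    sub = [(_unit_depth(c) if isinstance(c, UnitDef) else 0)
           for c in unit.constituents]
    return 1 + max(sub)


@lru_cache(maxsize=None)
def _unit_key(unit: UnitDef):
    table = compose_micro_mapping(unit)
    return (unit.micro_constituents, unit.tau,
            tuple(sorted(table.items())), unit.background)


def is_maximally_irreducible_within(
    candidate: CandidateSystem,
    pool: list[CandidateSystem],
) -> tuple[bool, CandidateSystem | None]:
    """Check phi_s > 0 and strict maximality among systems within U^J.

    ``pool`` must contain every valid competitor system whose micro
    constituents are a subset of the candidate's (at grains up to the
    candidate's).  Returns the verdict and a witness competitor on failure.
    """
    if candidate.phi <= STRICT_ATOL:
        return False, None
    u_j = candidate.micro_constituents
    for other in pool:
        if other is candidate:
            continue
        if not other.micro_constituents <= u_j:
            continue
        if other.tau > candidate.tau:
            continue
        if other.units == candidate.units:
            continue
        if other.phi >= candidate.phi - STRICT_ATOL:
            return False, other
    return True, None


def _systems_from_units(units: list[UnitDef]):
    """All non-overlapping unit combinations with a common update grain.

    Depth-first with overlap pruning: the valid combinations are sparse
    because units claiming a shared micro unit can never co-occur.
    """
    claims = [u.micro_constituents | u.background for u in units]
    taus = [u.tau for u in units]
    n = len(units)

    def extend(start: int, chosen: tuple[int, ...], claimed: frozenset, tau: int):
        for i in range(start, n):
            if taus[i] != tau or (claims[i] & claimed):
                continue
            combo = chosen + (i,)
            yield tuple(units[j] for j in combo)
            yield from extend(i + 1, combo, claimed | claims[i], tau)

    for tau in sorted(set(taus)):
        yield from extend(0, (), frozenset(), tau)


def candidate_systems(
    universe: MicroUniverse,
    constraints: SearchConstraints = SearchConstraints(),
    restrict_micro: frozenset | None = None,
) -> list[CandidateSystem]:
    """Recursive enumeration of valid candidate systems across grains.

    Starts from the micro units (optionally restricted to a subset of
    micro indices), evaluates all systems they form, promotes maximally
    irreducible candidates to constituents of new units (all non-constant
    mappings, update grains up to the cap), and repeats until convergence
    or the depth cap.
    """
    if universe.n > constraints.max_micro_units:
        raise GuardError(
            f"universe has {universe.n} micro units, above the search guard "
            f"({constraints.max_micro_units})"
        )
    micro_set = (frozenset(range(universe.n)) if restrict_micro is None
                 else frozenset(restrict_micro))
    units: list[UnitDef] = [
        micro_unit(i, universe.unit_labels[i]) for i in sorted(micro_set)
    ]
    seen_units = {_unit_key(u) for u in units}
    evaluated: dict[tuple, CandidateSystem] = {}

    def evaluate_all() -> None:
        for combo in _systems_from_units(units):
            key = tuple(_unit_key(u) for u in combo)
            if key not in evaluated:
                evaluated[key] = evaluate_system(universe, combo)

    evaluate_all()
    for depth in range(1, constraints.max_depth + 1):
        new_units: list[UnitDef] = []
        pool = list(evaluated.values())
        for cand in pool:
            if cand.depth != depth - 1:
                continue
            if len(cand.units) > constraints.max_unit_constituents:
                continue
            if len(cand.units) == 1 and cand.units[0].is_micro \
                    and constraints.max_tau <= 1:
                continue  # a single micro unit at tau=1 is already a unit
            verdict, _ = is_maximally_irreducible_within(cand, pool)
            if not verdict:
                continue
            constituents = tuple(
                next(iter(u.micro_constituents)) if u.is_micro else u
                for u in cand.units
            )
            base_tau = cand.tau
            for tau_prime in range(1, constraints.max_tau + 1):
                if base_tau * tau_prime > constraints.max_tau:
                    continue
                n_inputs = 2 ** (tau_prime * len(constituents))
                if n_inputs > constraints.mapping_guard:
                    continue
                for g in enumerate_mappings(len(constituents), tau_prime,
                                            guard=constraints.mapping_guard):
                    label = "|".join(u.label for u in cand.units) + \
                        f"/t{tau_prime}g{g.truth_table_integer}"
                    unit = UnitDef(label, constituents, tau_prime, g)
                    key = _unit_key(unit)
                    if key not in seen_units:
                        seen_units.add(key)
                        new_units.append(unit)
        if not new_units:
            break
        units.extend(new_units)
        evaluate_all()
    return list(evaluated.values())


def apportion_background(
    universe: MicroUniverse,
    units: tuple[UnitDef, ...],
    background_pool: frozenset,
) -> tuple[tuple[UnitDef, ...], CandidateSystem]:
    """Exhaustive search over background apportionments, maximizing phi_s.

    Each background micro unit is assigned to exactly one unit or left
    unapportioned; nested apportionments (a constituent's background must
    stay inside its parent's) are preserved by construction since search
    units carry empty constituent apportionments.  Ties keep the first
    assignment in canonical order (all-unapportioned first).
    """
    pool = tuple(sorted(background_pool))
    k = len(units)
    best: tuple[tuple[UnitDef, ...], CandidateSystem] | None = None
    for code in range((k + 1) ** len(pool)):
        assignment: list[set[int]] = [set() for _ in range(k)]
        c = code
        for unit_idx in pool:
            owner = c % (k + 1)
            c //= k + 1
            if owner > 0:
                assignment[owner - 1].add(unit_idx)
        apportioned = tuple(
            UnitDef(u.label, u.constituents, u.tau_prime, u.mapping,
                    frozenset(assignment[i]))
            for i, u in enumerate(units)
        )
        cand = evaluate_system(universe, apportioned)
        if best is None or cand.phi > best[1].phi + STRICT_ATOL:
            best = (apportioned, cand)
    assert best is not None
    return best


def _rank_key(cand: CandidateSystem):
    return (-cand.phi, -len(cand.micro_constituents), cand.labels)


def find_complexes(
    universe: MicroUniverse,
    constraints: SearchConstraints = SearchConstraints(),
) -> ComplexReport:
    """Identify non-overlapping complexes (first-maximal, second, ...).

    A complex must have strictly greater phi_s than every other candidate
    system overlapping its micro constituents; exact ties are broken
    canonically (larger micro-constituent set, then label order) and
    flagged in the report.
    """
    candidates = candidate_systems(universe, constraints)
    ranked = sorted(candidates, key=_rank_key)
    complexes: list[CandidateSystem] = []
    ties: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    remaining = ranked
    while remaining:
        top = remaining[0]
        if top.phi <= STRICT_ATOL:
            break
        for other in remaining[1:]:
            if top.micro_constituents & other.micro_constituents and \
                    abs(top.phi - other.phi) <= STRICT_ATOL:
                ties.append((top.labels, other.labels))
        complexes.append(top)
        remaining = [
            c for c in remaining
            if not (c.micro_constituents & top.micro_constituents)
        ]
    return ComplexReport(candidates=ranked, complexes=complexes,
                         ties_flagged=ties)
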