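"""Recompute every published example quantity from the printed rules.

Each row regenerates one phi_s value end to end: build the universe from
its parametric rules, condition or run the macro construction, and compute
phi_s.  ``expected`` carries the published three-decimal value for the
pass/fail column of the report; the computed numbers come from the
pipeline alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .background import micro_cause_effect_tpms
from .examples import example1_universe, example2_universe, fig2_universe
from .macro import MacroSystem, macro_cause_effect_tpms
from .phi import phi_s
from .units import MappingTable, UnitDef, enumerate_mappings

#: published values are printed to three decimals
PRINTED_TOL = 5e-4

AND_MAPPING = MappingTable((0, 0, 0, 1))


def _micro_phi(universe, system) -> float:
    return phi_s(micro_cause_effect_tpms(universe, system)).phi


def example1_micro_pair() -> float:
    """phi_s of {A,B} in (0,0) of the two-unit example universe."""
    return _micro_phi(example1_universe(), (0, 1))


def example1_micro_single() -> float:
    """phi_s of {A} with B as background."""
    return _micro_phi(example1_universe(), (0,))


def example1_macro_best() -> float:
    """Max phi_s over the 14 one-step mappings of a single macro unit."""
    universe = example1_universe()
    best = 0.0
    for g in enumerate_mappings(2, 1):
        unit = UnitDef("alpha", (0, 1), 1, g)
        result = phi_s(macro_cause_effect_tpms(MacroSystem(universe, (unit,))))
        best = max(best, result.phi)
    return best


def example2_micro_pair() -> float:
    """phi_s of the horizontal pair {A,B} (background {C,D})."""
    return _micro_phi(example2_universe(), (0, 1))


def example2_micro_single() -> float:
    """phi_s of {A} (background {B,C,D})."""
    return _micro_phi(example2_universe(), (0,))


def example2_micro_full() -> float:
    """phi_s of the full micro system {A,B,C,D}."""
    return _micro_phi(example2_universe(), (0, 1, 2, 3))


def example2_macro_pair() -> float:
    """phi_s of {alpha, beta} with alpha = AND(A,B), beta = AND(C,D)."""
    universe = example2_universe()
    units = (UnitDef("alpha", (0, 1), 1, AND_MAPPING),
             UnitDef("beta", (2, 3), 1, AND_MAPPING))
    return phi_s(macro_cause_effect_tpms(MacroSystem(universe, units))).phi


def fig2a_single() -> float:
    """phi_s of one unit of the vertical-delta-0 grid."""
    return _micro_phi(fig2_universe(0.0), (0,))


def fig2a_vertical_pair() -> float:
    """phi_s of a vertical pair with no connection between its units."""
    return _micro_phi(fig2_universe(0.0), (0, 2))


def fig2b_vertical_pair() -> float:
    """phi_s of a vertical pair under the 0.01 vertical increment."""
    return _micro_phi(fig2_universe(0.01), (0, 2))


@dataclass(frozen=True)
class ExampleRow:
    name: str
    description: str
    expected: float
    compute: callable


ROWS: tuple[ExampleRow, ...] = (
    ExampleRow("example1_micro_pair", "two-unit example, micro system {A,B}",
               0.005, example1_micro_pair),
    ExampleRow("example1_micro_single", "two-unit example, single unit {A}",
               0.0, example1_micro_single),
    ExampleRow("example1_macro_best", "two-unit example, best one-unit macro",
               0.788, example1_macro_best),
    ExampleRow("example2_micro_pair", "grid example, horizontal pair {A,B}",
               0.044, example2_micro_pair),
    ExampleRow("example2_micro_single", "grid example, single unit {A}",
               0.004, example2_micro_single),
    ExampleRow("example2_micro_full", "grid example, full micro system",
               0.020, example2_micro_full),
    ExampleRow("example2_macro_pair", "grid example, AND/AND macro pair",
               1.004, example2_macro_pair),
    ExampleRow("fig2a_single", "uncoupled-verticals grid, single unit",
               0.024, fig2a_single),
    ExampleRow("fig2a_vertical_pair", "uncoupled-verticals grid, vertical pair",
               0.0, fig2a_vertical_pair),
    ExampleRow("fig2b_vertical_pair", "weak-verticals grid, vertical pair",
               0.005, fig2b_vertical_pair),
)


def reproduce_examples(tolerance: float = PRINTED_TOL) -> list[dict]:
    """Recompute every example value; report computed vs published."""
    report = []
    for row in ROWS:
        value = float(row.compute())
        report.append({
            "name": row.name,
            "description": row.description,
            "computed": value,
            "published": row.expected,
            "pass": abs(value - row.expected) <= tolerance,
        })
    return report
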