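"""Readers and writers for TPMs, unit definitions, and reports.

Two universe formats are supported:

* JSON: ``{"units": [...], "tpm": [[...], ...], "state": [...]}`` where
  ``tpm`` is the state-by-node matrix (2**n rows, n columns of
  p(u'_i = 1 | u)) and ``state`` is either a single micro state or a list
  of micro states (earliest first, last = current);
* TSV: a header line with unit labels, then the 2**n state-by-node rows.

Rows are ordered by the little-endian state index (the first listed unit
varies fastest); the TSV writer records this convention in a comment
header.  State-by-state matrices can be exported for inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .tpm import MicroUniverse, expand_to_state_by_state
from .units import MappingTable, UnitDef


def read_universe(path: str | Path) -> MicroUniverse:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_universe_json(path)
    return _read_universe_tsv(path)


def _validate_entries(rows: list[list[float]], labels: list[str]) -> np.ndarray:
    n = len(labels)
    if len(rows) != 2**n:
        raise ValidationError(
            f"expected {2**n} rows for {n} units, found {len(rows)}"
        )
    arr = np.empty((2**n, n))
    for r, row in enumerate(rows):
        if len(row) != n:
            raise ValidationError(f"row {r} has {len(row)} entries, expected {n}")
        for c, value in enumerate(row):
            v = float(value)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"probability {value!r} at row {r}, column {labels[c]!r} "
                    "is outside [0, 1]"
                )
            arr[r, c] = v
    return arr


def _read_universe_json(path: Path) -> MicroUniverse:
    with open(path) as fh:
        data = json.load(fh)
    for key in ("units", "tpm"):
        if key not in data:
            raise ValidationError(f"universe JSON is missing the {key!r} field")
    labels = [str(l) for l in data["units"]]
    sbn = _validate_entries(data["tpm"], labels)
    history = data.get("history")
    if history is None:
        state = data.get("state")
        history = [state] if state is not None else []
    try:
        return MicroUniverse(tuple(labels), sbn, tuple(map(tuple, history)))
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


def _read_universe_tsv(path: Path) -> MicroUniverse:
    labels: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if labels is None:
                labels = fields
            else:
                rows.append([float(f) for f in fields])
    if labels is None:
        raise ValidationError(f"{path} contains no data")
    sbn = _validate_entries(rows, labels)
    try:
        return MicroUniverse(tuple(labels), sbn, ())
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


_CONVENTION = ("# state-by-node TPM; rows ordered by little-endian state index "
               "(first unit varies fastest); entries are p(unit'=1 | row state)")


def write_universe_tsv(universe: MicroUniverse, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_CONVENTION + "\n")
        fh.write("\t".join(universe.unit_labels) + "\n")
        for row in universe.sbn_tpm:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def write_universe_json(universe: MicroUniverse, path: str | Path) -> None:
    data = {
        "units": list(universe.unit_labels),
        "tpm": universe.sbn_tpm.tolist(),
        "history": [list(s) for s in universe.current_history],
        "convention": "little-endian rows; first unit varies fastest",
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


def write_state_by_state_tsv(matrix: np.ndarray, path: str | Path,
                             labels: tuple[str, ...] | None = None) -> None:
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        fh.write("# state-by-state matrix; little-endian state order"
                 + (f"; units: {','.join(labels)}" if labels else "") + "\n")
        for row in matrix:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


# -- unit definitions --------------------------------------------------------


def unit_to_dict(unit: UnitDef, labels: tuple[str, ...]) -> dict:
    return {
        "label": unit.label,
        "constituents": [
            unit_to_dict(c, labels) if isinstance(c, UnitDef) else labels[c]
            for c in unit.constituents
        ],
        "micro_constituents": [labels[i] for i in sorted(unit.micro_constituents)],
        "tau_prime": unit.tau_prime,
        "mapping": list(unit.mapping.bits),
        "background": [labels[i] for i in sorted(unit.background)],
    }


def unit_from_dict(data: dict, labels: tuple[str, ...]) -> UnitDef:
    index = {l: i for i, l in enumerate(labels)}
    try:
        constituents = tuple(
            unit_from_dict(c, labels) if isinstance(c, dict) else index[c]
            for c in data["constituents"]
        )
        return UnitDef(
            label=str(data["label"]),
            constituents=constituents,
            tau_prime=int(data.get("tau_prime", 1)),
            mapping=MappingTable(tuple(int(b) for b in data["mapping"])),
            background=frozenset(index[l] for l in data.get("background", [])),
        )
    except KeyError as exc:
        raise ValidationError(f"unit definition refers to unknown label {exc}") from exc
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


def read_units(path: str | Path, labels: tuple[str, ...]) -> tuple[UnitDef, ...]:
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    return tuple(unit_from_dict(d, labels) for d in data)
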