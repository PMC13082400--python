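"""Micro causal models: state-by-node TPMs, state indexing, conditioning.

A universe is a set of n binary units whose next state depends only on the
current universe state (a complete causal network: no instantaneous causation,
so the units update conditionally independently).  The canonical in-memory
representation is the *state-by-node* TPM: a (2**n, n) array whose entry
``(u, i)`` is ``p(u'_i = 1 | u)``, with rows indexed by the little-endian
state index (first listed unit varies fastest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: absolute tolerance for row-stochasticity checks (inputs are exact decimals)
STOCHASTIC_ATOL = 1e-12


def state_index(state: Sequence[int]) -> int:
    """Little-endian index of a binary state: the first unit varies fastest."""
    idx = 0
    for k, bit in enumerate(state):
        if bit not in (0, 1):
            raise ValueError(f"state entries must be 0 or 1, got {bit!r}")
        idx |= int(bit) << k
    return idx


def index_state(idx: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`state_index` for an ``n``-unit state."""
    if not 0 <= idx < 2**n:
        raise ValueError(f"index {idx} out of range for {n} units")
    return tuple((idx >> k) & 1 for k in range(n))


def all_states(n: int) -> np.ndarray:
    """(2**n, n) array of binary states in little-endian index order."""
    idx = np.arange(2**n)
    return (idx[:, None] >> np.arange(n)[None, :]) & 1


@dataclass
class MicroUniverse:
    """A complete binary causal network plus its current (trailing) state.

    Parameters
    ----------
    unit_labels:
        Ordered unit identifiers.
    sbn_tpm:
        State-by-node TPM, shape ``(2**n, n)``; entry ``(u, i)`` is the
        interventional probability ``p(u'_i = 1 | do(u))``.
    current_history:
        Sequence of >= 1 micro states; the last entry is the current state
        ``u_0``.  Longer histories are only needed when units with micro
        update grain tau > 1 are analyzed (a unit's macro state looks back
        tau micro updates from the current instant).
    """

    unit_labels: tuple[str, ...]
    sbn_tpm: np.ndarray
    current_history: tuple[tuple[int, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        self.unit_labels = tuple(str(l) for l in self.unit_labels)
        n = len(self.unit_labels)
        if len(set(self.unit_labels)) != n:
            raise ValueError("unit labels must be unique")
        self.sbn_tpm = np.asarray(self.sbn_tpm, dtype=float)
        if self.sbn_tpm.shape != (2**n, n):
            raise ValueError(
                f"sbn_tpm must have shape {(2**n, n)} for {n} units, "
                f"got {self.sbn_tpm.shape}"
            )
        if np.any(self.sbn_tpm < 0) or np.any(self.sbn_tpm > 1):
            bad = np.argwhere((self.sbn_tpm < 0) | (self.sbn_tpm > 1))[0]
            raise ValueError(
                f"sbn_tpm entry at row {bad[0]}, column {bad[1]} is outside [0, 1]"
            )
        self.current_history = tuple(
            tuple(int(b) for b in state) for state in self.current_history
        )
        for state in self.current_history:
            if len(state) != n or any(b not in (0, 1) for b in state):
                raise ValueError(f"invalid state {state} for {n} binary units")

    # -- basic descriptors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.unit_labels)

    @property
    def n_states(self) -> int:
        return 2**self.n

    @property
    def current_state(self) -> tuple[int, ...]:
        if not self.current_history:
            raise ValueError("universe has no current state")
        return self.current_history[-1]

    def require_history(self, length: int) -> None:
        if len(self.current_history) < length:
            raise ValueError(
                f"analysis requires a history of at least {length} micro states; "
                f"only {len(self.current_history)} provided"
            )

    def unit_indices(self, labels: Sequence[str]) -> tuple[int, ...]:
        try:
            return tuple(self.unit_labels.index(str(l)) for l in labels)
        except ValueError as exc:
            raise KeyError(f"unknown unit label in {labels!r}") from exc

    # -- conversions -------------------------------------------------------

    def state_by_state(self) -> np.ndarray:
        """Expand to the (2**n, 2**n) state-by-state TPM (product form)."""
        return expand_to_state_by_state(self.sbn_tpm)

    def with_history(self, history: Sequence[Sequence[int]]) -> "MicroUniverse":
        return MicroUniverse(self.unit_labels, self.sbn_tpm, tuple(history))


def expand_to_state_by_state(sbn_tpm: np.ndarray) -> np.ndarray:
    """p(u'|u) = prod_i p(u'_i|u); rows sum to 1 by construction."""
    sbn_tpm = np.asarray(sbn_tpm, dtype=float)
    n = sbn_tpm.shape[1]
    states = all_states(n)
    tpm = np.ones((2**n, 2**n))
    for i in range(n):
        p1 = sbn_tpm[:, i][:, None]
        bit = states[:, i][None, :]
        tpm *= np.where(bit == 1, p1, 1.0 - p1)
    return tpm


def sbn_from_state_by_state(tpm: np.ndarray) -> np.ndarray:
    """Per-unit marginals of a state-by-state TPM (exact under product form)."""
    tpm = np.asarray(tpm, dtype=float)
    n_states = tpm.shape[0]
    n = n_states.bit_length() - 1
    if 2**n != n_states or tpm.shape != (n_states, n_states):
        raise ValueError("state-by-state TPM must be square with 2**n rows")
    row_sums = tpm.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > STOCHASTIC_ATOL):
        bad = int(np.argmax(np.abs(row_sums - 1.0)))
        raise ValueError(f"row {bad} sums to {row_sums[bad]!r}, not 1")
    states = all_states(n)
    return tpm @ states.astype(float)


def condition_rows(
    sbn_tpm: np.ndarray,
    fixed_units: Sequence[int],
    fixed_state: Sequence[int],
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Average the state-by-node TPM over rows consistent with a partial state.

    Rows whose state agrees with ``fixed_state`` on ``fixed_units`` are kept
    and the remaining units are averaged out, uniformly unless ``weights``
    (one weight per universe state) are given.  Returns the ``(n,)`` vector
    of conditional per-unit activation probabilities.  Fixing every unit
    recovers the corresponding row unchanged.
    """
    sbn_tpm = np.asarray(sbn_tpm, dtype=float)
    n = sbn_tpm.shape[1]
    fixed_units = tuple(int(i) for i in fixed_units)
    if len(set(fixed_units)) != len(fixed_units):
        raise ValueError("fixed units must be distinct")
    if len(fixed_state) != len(fixed_units):
        raise ValueError("fixed_state length must match fixed_units")
    states = all_states(n)
    mask = np.ones(2**n, dtype=bool)
    for unit, bit in zip(fixed_units, fixed_state):
        if bit not in (0, 1):
            raise ValueError(f"fixed state bit must be 0 or 1, got {bit!r}")
        mask &= states[:, unit] == bit
    if weights is None:
        w = mask.astype(float)
    else:
        w = np.asarray(weights, dtype=float) * mask
    total = w.sum()
    if total <= 0:
        raise ValueError("no rows consistent with the requested conditioning")
    return w @ sbn_tpm / total


def marginalize_inputs(sbn_column: np.ndarray, n: int, noised: Sequence[int]) -> np.ndarray:
    """Uniformly average one unit's input column over a set of input units.

    ``sbn_column`` has one entry per universe state; the result no longer
    depends on the state of the units in ``noised``.
    """
    col = np.asarray(sbn_column, dtype=float)
    noised = sorted(set(int(i) for i in noised))
    if not noised:
        return col.copy()
    states = all_states(n)
    out = np.zeros_like(col)
    # group states by their configuration outside `noised`
    keep = [i for i in range(n) if i not in noised]
    key = states[:, keep] @ (1 << np.arange(len(keep))) if keep else np.zeros(2**n, int)
    for k in np.unique(key):
        grp = key == k
        out[grp] = col[grp].mean()
    return out
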