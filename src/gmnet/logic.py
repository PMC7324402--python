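"""Synchronous Boolean networks over gene modules.

A network of ``m`` modules updates all modules simultaneously:

    s_i(j + 1) = f_i(s_1(j), ..., s_m(j))

where each update rule ``f_i`` is an AND/OR/NOT expression over a subset of
modules (its *regulators*).  States are length-``m`` binary vectors; the
bit-string rendering puts module M1 leftmost, so ``000000000111`` with
``m = 12`` means M10-M12 are ON.

Internally the dynamics code packs a state into a Python integer with M1 in
the least-significant bit; :func:`state_to_int` / :func:`int_to_state`
convert between the two views.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DimensionError, InvalidParameterError

Bits = tuple[int, ...]


def as_state(state: Sequence[int] | str) -> Bits:
    """Coerce a sequence of 0/1 or a bit-string (M1 leftmost) to a tuple."""
    if isinstance(state, str):
        return string_to_state(state)
    bits = tuple(int(b) for b in state)
    if any(b not in (0, 1) for b in bits):
        raise InvalidParameterError(f"state must be binary, got {state!r}")
    return bits


def state_to_string(state: Sequence[int]) -> str:
    """Render a state as a bit-string with module M1 leftmost."""
    return "".join(str(int(b)) for b in state)


def string_to_state(s: str) -> Bits:
    if not s or any(c not in "01" for c in s):
        raise InvalidParameterError(f"not a bit-string: {s!r}")
    return tuple(int(c) for c in s)


def state_to_int(state: Sequence[int]) -> int:
    """Pack a state into an integer; M1 occupies the least-significant bit."""
    x = 0
    for i, b in enumerate(state):
        x |= int(b) << i
    return x


def int_to_state(x: int, m: int) -> Bits:
    return tuple((x >> i) & 1 for i in range(m))


@dataclass(frozen=True)
class BooleanFunction:
    """Update rule for one module.

    Parameters
    ----------
    target
        1-based index of the module this rule updates.
    regulators
        Ordered (ascending) 1-based indices of the input modules.
    truth_table
        Output bit for every combination of regulator values.  Entry ``t``
        corresponds to the input in which regulator ``regulators[p]`` has
        value ``(t >> p) & 1`` -- i.e. the first regulator is the
        least-significant bit of the row index.
    """

    target: int
    regulators: tuple[int, ...]
    truth_table: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.truth_table) != 1 << len(self.regulators):
            raise InvalidParameterError(
                f"truth table for M{self.target} has {len(self.truth_table)} "
                f"rows; expected {1 << len(self.regulators)}"
            )
        if any(b not in (0, 1) for b in self.truth_table):
            raise InvalidParameterError("truth table entries must be 0/1")
        if any(r < 1 for r in self.regulators):
            raise InvalidParameterError("regulator indices are 1-based")
        if list(self.regulators) != sorted(set(self.regulators)):
            raise InvalidParameterError("regulators must be sorted and unique")

    @property
    def expression(self) -> str:
        """Minimal AND/OR/NOT text form (``!``, ``&``, ``|`` dialect)."""
        from .rules import expression_from_truth_table

        return expression_from_truth_table(self.regulators, self.truth_table)

    def __call__(self, state: Sequence[int]) -> int:
        return evaluate_rule(self, state)


@dataclass(frozen=True)
class BooleanNetwork:
    """One synchronous update rule per module, M1..Mm."""

    functions: tuple[BooleanFunction, ...]

    def __post_init__(self) -> None:
        m = len(self.functions)
        for i, fn in enumerate(self.functions, start=1):
            if fn.target != i:
                raise InvalidParameterError(
                    f"function {i} targets M{fn.target}; expected M{i}"
                )
            if any(r > m for r in fn.regulators):
                raise InvalidParameterError(
                    f"M{i} references regulator beyond M{m}"
                )

    @property
    def m(self) -> int:
        return len(self.functions)

    def step(self, state: Sequence[int] | str) -> Bits:
        return step(self, state)

    def successor_array(self) -> np.ndarray:
        """Integer-encoded successor of every one of the 2^m states."""
        m = self.m
        n = 1 << m
        states = np.arange(n, dtype=np.int64)
        succ = np.zeros(n, dtype=np.int64)
        for i, fn in enumerate(self.functions):
            idx = np.zeros(n, dtype=np.int64)
            for p, reg in enumerate(fn.regulators):
                idx |= ((states >> (reg - 1)) & 1) << p
            tt = np.asarray(fn.truth_table, dtype=np.int64)
            succ |= tt[idx] << i
        return succ


def evaluate_rule(fn: BooleanFunction, state: Sequence[int] | str) -> int:
    """Value of ``fn`` at ``state`` (any state at least as long as needed)."""
    bits = as_state(state)
    if fn.regulators and max(fn.regulators) > len(bits):
        raise DimensionError(
            f"rule for M{fn.target} reads M{max(fn.regulators)} but the "
            f"state has only {len(bits)} modules"
        )
    idx = 0
    for p, reg in enumerate(fn.regulators):
        idx |= bits[reg - 1] << p
    return fn.truth_table[idx]


def step(net: BooleanNetwork, state: Sequence[int] | str) -> Bits:
    """Synchronous update: every module evaluated on the same input state."""
    bits = as_state(state)
    if len(bits) != net.m:
        raise DimensionError(
            f"state has {len(bits)} modules; network has {net.m}"
        )
    return tuple(evaluate_rule(fn, bits) for fn in net.functions)
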