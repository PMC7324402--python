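"""Boolean network inference from an observed state sequence.

The spatial table is read as synchronous dynamics: column j is the input
state, column j+1 its successor.  For each module the smallest regulator
subset that explains all observed transitions without contradiction is
selected, searching subsets of size 0, 1, 2, ... up to ``max_indegree``
and, within a size, in lexicographic order of regulator indices.  This
deterministic selection matters: many rule sets are typically consistent
with a short sequence, and reproducibility requires a fixed tie-break.

Truth-table rows never observed in the data are filled by a completion
policy: ``"zero"`` (default; unseen input patterns give an inactive
module) or ``"majority"`` (the majority output over observed rows, ties
inactive).

The returned network reproduces every observed transition exactly; this is
a hard postcondition, violated only if no subset within the in-degree
bound is consistent, in which case :class:`UnsatisfiableInferenceError`
names the module and a pair of conflicting transitions.
"""

from __future__ import annotations

from itertools import combinations

from .exceptions import InvalidParameterError, UnsatisfiableInferenceError
from .logic import BooleanFunction, BooleanNetwork
from .modules import BinaryStateTable

__all__ = ["infer_network"]

_COMPLETIONS = ("zero", "majority")


def infer_network(
    table: BinaryStateTable,
    max_indegree: int | None = None,
    completion: str = "zero",
) -> BooleanNetwork:
    if table.n_positions < 2:
        raise InvalidParameterError("need at least 2 columns to infer")
    m = table.m
    if max_indegree is None:
        max_indegree = min(4, m)
    if not 0 <= max_indegree <= m:
        raise InvalidParameterError(
            f"max_indegree must be in 0..{m}, got {max_indegree}"
        )
    if completion not in _COMPLETIONS:
        raise InvalidParameterError(
            f"completion must be one of {_COMPLETIONS}, got {completion!r}"
        )

    cols = table.columns()
    inputs = cols[:-1]
    outputs = cols[1:]

    functions = []
    for i in range(1, m + 1):
        outs = [o[i - 1] for o in outputs]
        fn = _infer_one(i, inputs, outs, m, max_indegree, completion)
        functions.append(fn)
    return BooleanNetwork(functions=tuple(functions))


def _infer_one(target, inputs, outs, m, max_indegree, completion):
    for size in range(max_indegree + 1):
        for regs in combinations(range(1, m + 1), size):
            seen: dict[tuple, int] = {}
            ok = True
            for s, o in zip(inputs, outs):
                key = tuple(s[r - 1] for r in regs)
                prev = seen.get(key)
                if prev is None:
                    seen[key] = o
                elif prev != o:
                    ok = False
                    break
            if ok:
                return _build(target, regs, seen, completion)
    raise UnsatisfiableInferenceError(_conflict_message(target, inputs, outs, m))


def _build(target, regs, seen, completion):
    k = len(regs)
    if completion == "majority":
        ones = sum(seen.values())
        fill = 1 if 2 * ones > len(seen) else 0
    else:
        fill = 0
    tt = []
    for t in range(1 << k):
        key = tuple((t >> p) & 1 for p in range(k))
        tt.append(seen.get(key, fill))
    return BooleanFunction(target=target, regulators=tuple(regs), truth_table=tuple(tt))


def _conflict_message(target, inputs, outs, m):
    # the only way *no* subset (up to the full set) can work is two equal
    # input states with different outputs; report such a pair if present
    for a in range(len(inputs)):
        for b in range(a + 1, len(inputs)):
            if inputs[a] == inputs[b] and outs[a] != outs[b]:
                s = "".join(map(str, inputs[a]))
                return (
                    f"no consistent rule for M{target}: transitions "
                    f"{a}->{a + 1} and {b}->{b + 1} map the same state "
                    f"{s} to different M{target} outputs"
                )
    return (
        f"no consistent rule for M{target} within the in-degree bound; "
        f"raise max_indegree (up to {m})"
    )
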