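"""Exhaustive attractor, basin and trajectory analysis.

With ``m`` modules the synchronous dynamics is a function on ``2^m``
states; every trajectory enters a fixed point or a cycle.  Enumeration is
exact: the full successor map is built (vectorized over all states), the
eventual cycle of every state is found by pointer doubling, and basins are
counted by membership of the eventual state.  At ``m = 12`` this is 4096
states and runs in milliseconds; the hard bound is ``m <= 24``.

Fixed points are the states satisfying S(j+1) = S(j); cycles of length
greater than one are detected and reported too, flagged per attractor.
Basin membership includes the attractor's own states, so a fixed point
with no other predecessors has basin size 1, and basin sizes always sum
to ``2^m``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import CapacityError, DimensionError
from .logic import (
    Bits,
    BooleanNetwork,
    as_state,
    int_to_state,
    state_to_int,
    state_to_string,
)

MAX_EXHAUSTIVE_M = 24


@dataclass(frozen=True)
class Attractor:
    """A fixed point or cycle with its basin."""

    states: tuple[Bits, ...]  # in successor order, starting from the min state
    basin_size: int
    basin_pct: float
    is_fixed_point: bool

    @property
    def bitstrings(self) -> tuple[str, ...]:
        return tuple(state_to_string(s) for s in self.states)

    @property
    def state_set(self) -> frozenset[Bits]:
        return frozenset(self.states)


@dataclass
class AttractorReport:
    m: int
    attractors: list[Attractor]

    @property
    def n_states(self) -> int:
        return 1 << self.m

    @property
    def basin_sizes(self) -> list[int]:
        return [a.basin_size for a in self.attractors]

    def canonical(self) -> frozenset[frozenset[Bits]]:
        """The attractor set as a hashable value (cycles compared as sets)."""
        return frozenset(a.state_set for a in self.attractors)

    def containing(self, state: Sequence[int] | str) -> Attractor | None:
        """The attractor whose cycle contains ``state``, if any."""
        bits = as_state(state)
        for a in self.attractors:
            if bits in a.state_set:
                return a
        return None

    def to_json(self) -> dict:
        return {
            "m": self.m,
            "n_states": self.n_states,
            "attractors": [
                {
                    "states": list(a.bitstrings),
                    "basin_size": a.basin_size,
                    "basin_pct": a.basin_pct,
                    "fixed_point": a.is_fixed_point,
                }
                for a in self.attractors
            ],
        }


def _check_capacity(m: int) -> None:
    if m > MAX_EXHAUSTIVE_M:
        raise CapacityError(
            f"m={m} exceeds the exhaustive bound ({MAX_EXHAUSTIVE_M}); "
            "sample initial states instead of full enumeration"
        )


def _eventual(succ: np.ndarray, m: int) -> np.ndarray:
    """State reached after 2^m steps (guaranteed on the attractor cycle)."""
    t = succ.copy()
    for _ in range(m):
        t = t[t]
    return t


def _attractor_labels(succ: np.ndarray, t: np.ndarray):
    """Label each state's attractor; return (labels, cycles as int lists)."""
    n = succ.shape[0]
    label = np.full(n, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for u in np.unique(t):
        if label[u] >= 0:
            continue
        cyc = [int(u)]
        v = int(succ[u])
        while v != u:
            cyc.append(v)
            v = int(succ[v])
        k = len(cycles)
        for s in cyc:
            label[s] = k
        # canonical rotation: start at the smallest state
        j = cyc.index(min(cyc))
        cycles.append(cyc[j:] + cyc[:j])
    return label[t], cycles, label


def find_attractors(net: BooleanNetwork) -> AttractorReport:
    """All attractors of ``net`` with exact basin sizes."""
    m = net.m
    _check_capacity(m)
    succ = net.successor_array()
    t = _eventual(succ, m)
    basin_label, cycles, _ = _attractor_labels(succ, t)
    counts = np.bincount(basin_label, minlength=len(cycles))
    n = 1 << m
    attractors = [
        Attractor(
            states=tuple(int_to_state(s, m) for s in cyc),
            basin_size=int(counts[k]),
            basin_pct=100.0 * counts[k] / n,
            is_fixed_point=len(cyc) == 1,
        )
        for k, cyc in enumerate(cycles)
    ]
    attractors.sort(key=lambda a: (-a.basin_size, min(state_to_int(s) for s in a.states)))
    return AttractorReport(m=m, attractors=attractors)


@dataclass
class TransitionGraph:
    """Full state-transition graph plus its decomposition into trees.

    ``successors[s]`` is the integer-encoded successor of state ``s``;
    ``attractor_index[s]`` the index (into ``report.attractors``) of the
    attractor state ``s`` eventually reaches; ``depth[s]`` the number of
    steps until the trajectory first enters the attractor cycle (0 for
    states on a cycle).  The per-attractor trees partition the
    non-attractor states.
    """

    m: int
    successors: np.ndarray
    attractor_index: np.ndarray
    depth: np.ndarray
    report: AttractorReport

    def tree_nodes(self, k: int) -> list[int]:
        """Non-attractor states (encoded) in the basin of attractor k."""
        in_basin = np.flatnonzero(self.attractor_index == k)
        return [int(s) for s in in_basin if self.depth[s] > 0]

    def tree(self, k: int):
        """The state-transition tree of attractor k as a networkx DiGraph.

        Nodes are bit-strings; edges point from a state to its successor.
        Attractor states are included as the roots (flagged with the node
        attribute ``attractor=True``).
        """
        import networkx as nx

        g = nx.DiGraph()
        att = self.report.attractors[k]
        for s in att.states:
            g.add_node(state_to_string(s), attractor=True, depth=0)
        for s in self.tree_nodes(k):
            bits = int_to_state(s, self.m)
            nxt = int_to_state(int(self.successors[s]), self.m)
            g.add_node(state_to_string(bits), attractor=False, depth=int(self.depth[s]))
            g.add_edge(state_to_string(bits), state_to_string(nxt))
        return g

    def to_edgelist_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("state\tsuccessor\tattractor_index\tdepth\n")
            for s in range(1 << self.m):
                fh.write(
                    f"{state_to_string(int_to_state(s, self.m))}\t"
                    f"{state_to_string(int_to_state(int(self.successors[s]), self.m))}\t"
                    f"{int(self.attractor_index[s])}\t{int(self.depth[s])}\n"
                )

    def to_json(self) -> dict:
        return {
            "m": self.m,
            "attractors": self.report.to_json()["attractors"],
            "tree_sizes": [
                int((self.attractor_index == k).sum())
                - len(self.report.attractors[k].states)
                for k in range(len(self.report.attractors))
            ],
            "max_depth": int(self.depth.max()),
        }


def transition_graph(net: BooleanNetwork) -> TransitionGraph:
    """Successor map, basin labels and entry depth for every state."""
    m = net.m
    _check_capacity(m)
    succ = net.successor_array()
    t = _eventual(succ, m)
    basin_label, cycles, cycle_label = _attractor_labels(succ, t)
    report = find_attractors(net)

    # map raw cycle index -> index into the sorted report
    by_states = {
        frozenset(state_to_int(s) for s in a.states): k
        for k, a in enumerate(report.attractors)
    }
    remap = np.array(
        [by_states[frozenset(cyc)] for cyc in cycles], dtype=np.int64
    )
    attractor_index = remap[basin_label]

    # depth: BFS over predecessors starting from cycle states
    n = 1 << m
    depth = np.full(n, -1, dtype=np.int64)
    preds: list[list[int]] = [[] for _ in range(n)]
    for s in range(n):
        preds[int(succ[s])].append(s)
    q: deque[int] = deque()
    for s in range(n):
        if cycle_label[s] >= 0:
            depth[s] = 0
            q.append(s)
    while q:
        v = q.popleft()
        for p in preds[v]:
            if depth[p] < 0:
                depth[p] = depth[v] + 1
                q.append(p)
    return TransitionGraph(
        m=m,
        successors=succ,
        attractor_index=attractor_index,
        depth=depth,
        report=report,
    )


def trajectory(net: BooleanNetwork, s0: Sequence[int] | str) -> list[Bits]:
    """States from ``s0`` until the first repeat (attractor entered once).

    A fixed-point initial state yields ``[s0]``; in general the list ends
    with the full attractor cycle traversed exactly once.
    """
    bits = as_state(s0)
    if len(bits) != net.m:
        raise DimensionError(f"state has {len(bits)} modules; network has {net.m}")
    path = []
    seen = set()
    cur = bits
    while cur not in seen:
        seen.add(cur)
        path.append(cur)
        cur = net.step(cur)
    return path


def _trajectory_ints(succ: np.ndarray, s0: int) -> list[int]:
    """Integer-encoded trajectory over a precomputed successor map."""
    path, seen, cur = [], set(), s0
    while cur not in seen:
        seen.add(cur)
        path.append(cur)
        cur = int(succ[cur])
    return path
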