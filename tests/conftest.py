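"""Shared fixtures and the independent brute-force dynamics oracle.

The oracle deliberately avoids the package's vectorized successor-map /
pointer-doubling machinery: it evaluates truth tables state by state with
plain Python and follows trajectories with a dict, so it can certify the
fast implementation on small module counts.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

from gmnet import (
    BinaryStateTable,
    BooleanFunction,
    BooleanNetwork,
    wing_disc_ground_truth,
    wing_disc_state_table,
)

# ---------------------------------------------------------------------------
# oracle


def oracle_step(net: BooleanNetwork, bits: tuple[int, ...]) -> tuple[int, ...]:
    out = []
    for fn in net.functions:
        idx = 0
        for p, r in enumerate(fn.regulators):
            idx += bits[r - 1] * (1 << p)
        out.append(fn.truth_table[idx])
    return tuple(out)


def oracle_basins(net: BooleanNetwork):
    """Map every state to its attractor cycle (frozenset) by plain simulation.

    Returns (basin_of_state, Counter cycle -> basin size).
    """
    basin: dict[tuple, frozenset] = {}
    for s in itertools.product((0, 1), repeat=net.m):
        path, seen = [], {}
        cur = s
        while cur not in seen:
            seen[cur] = len(path)
            path.append(cur)
            cur = oracle_step(net, cur)
        basin[s] = frozenset(path[seen[cur] :])
    return basin, Counter(basin.values())


def network_from_successor(succ: dict[tuple, tuple], m: int) -> BooleanNetwork:
    """Build a network realizing an explicit successor map (test scaffolding)."""
    functions = []
    regs = tuple(range(1, m + 1))
    for i in range(m):
        tt = []
        for t in range(1 << m):
            bits = tuple((t >> p) & 1 for p in range(m))
            tt.append(succ[bits][i])
        functions.append(
            BooleanFunction(target=i + 1, regulators=regs, truth_table=tuple(tt))
        )
    return BooleanNetwork(functions=tuple(functions))


def constant_network(m: int, value: int = 0) -> BooleanNetwork:
    return BooleanNetwork(
        functions=tuple(
            BooleanFunction(target=i, regulators=(), truth_table=(value,))
            for i in range(1, m + 1)
        )
    )


def identity_network(m: int) -> BooleanNetwork:
    return BooleanNetwork(
        functions=tuple(
            BooleanFunction(target=i, regulators=(i,), truth_table=(0, 1))
            for i in range(1, m + 1)
        )
    )


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def wing_table() -> BinaryStateTable:
    return wing_disc_state_table()


@pytest.fixture(scope="session")
def ground_truth():
    """Noisy synthetic study at the default conditions."""
    return wing_disc_ground_truth(seed=0)


@pytest.fixture(scope="session")
def ground_truth_clean():
    """Noise-free synthetic study for exact-recovery checks."""
    return wing_disc_ground_truth(seed=1, sigma=0.0)
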