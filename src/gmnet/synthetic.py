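"""Synthetic ground truth: networks, spatial state tables, expression.

No raw position-resolved RNA-seq is publicly deposited for the wing-disc
study this pipeline re-implements, so every stage is exercised against
generated data with known ground truth.  The generator emulates the
salient structure of that data:

* ~10-15 ordered positions along the A-P axis, two staggered sample sets
  (batches) with a constant per-batch offset;
* modules whose ON regions are contiguous position intervals, member
  genes high inside the interval and decaying geometrically outside it
  (FPKM-like positive values, multiplicative log-normal noise);
* marker genes with fixed deterministic shapes -- an *hh*-like gene
  exclusive to the terminal (posterior) position, a *ci*-like gene ON
  everywhere but the terminal position, a *dpp*-like gene peaking in the
  interior -- so the interleaving order can be validated;
* non-monotone background genes that a morphogen-response screen must
  reject.

The default parameters are fixed study conditions, not tuning knobs; see
``docs/methods.md`` for the rationale behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DimensionError, InvalidParameterError
from .expression import ExpressionMatrix
from .infer import infer_network
from .logic import Bits, BooleanFunction, BooleanNetwork, as_state
from .modules import BinaryStateTable, ModuleAssignment

#: Interleaved axis order of the two staggered sample sets, anterior to
#: posterior; batch A contributes 6 positions, batch B seven, the last
#: (B7) lying in the morphogen source compartment.
WING_DISC_ORDER: list[str] = [
    "A1", "B1", "A2", "B2", "B3", "A3", "B4", "A4", "B5", "A5", "B6", "A6", "B7",
]

_A_POSITIONS = ["A1", "A2", "A3", "A4", "A5", "A6"]
_B_POSITIONS = ["B1", "B2", "B3", "B4", "B5", "B6", "B7"]

#: Contiguous ON interval (start, end; 0-based, inclusive) of each of the
#: 12 modules over the 13 observed positions.  Starts increase strictly,
#: so peak-ordered renumbering is the identity; the terminal column is
#: 000000000111 (the last three modules ON), echoing the physiological
#: posterior-compartment pattern, and the morphogen-readout module M8 is
#: ON just anterior to the source boundary.
WING_DISC_RUNS: dict[int, tuple[int, int]] = {
    1: (0, 2), 2: (1, 3), 3: (2, 4), 4: (3, 5), 5: (4, 6), 6: (5, 7),
    7: (6, 8), 8: (7, 9), 9: (8, 11), 10: (9, 12), 11: (10, 12), 12: (11, 12),
}


@dataclass
class GroundTruth:
    """A fully known pipeline input: network, states, genes, expression."""

    network: BooleanNetwork
    state_table: BinaryStateTable
    assignment: ModuleAssignment
    expression_pair: tuple[ExpressionMatrix, ExpressionMatrix]
    seed: int
    markers: dict[str, str] = field(default_factory=dict)


def make_random_network(
    m: int, max_indegree: int, seed: int
) -> BooleanNetwork:
    """Random Boolean network with in-degrees drawn from 0..max_indegree.

    Same seed, same network (serialized rule text included).  With
    ``max_indegree = 0`` every rule is a constant.
    """
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    if not 0 <= max_indegree <= m:
        raise InvalidParameterError(
            f"max_indegree must be in 0..{m}, got {max_indegree}"
        )
    rng = np.random.default_rng(seed)
    functions = []
    for i in range(1, m + 1):
        k = int(rng.integers(0, max_indegree + 1))
        regs = tuple(sorted(int(r) + 1 for r in rng.choice(m, size=k, replace=False)))
        tt = tuple(int(b) for b in rng.integers(0, 2, size=1 << k))
        functions.append(BooleanFunction(target=i, regulators=regs, truth_table=tt))
    return BooleanNetwork(functions=tuple(functions))


def simulate_state_sequence(
    net: BooleanNetwork, s0: Sequence[int] | str, steps: int
) -> BinaryStateTable:
    """Synchronous simulation for ``steps`` updates; steps+1 columns."""
    bits = as_state(s0)
    if len(bits) != net.m:
        raise DimensionError(
            f"s0 has {len(bits)} modules; network has {net.m}"
        )
    if steps < 0:
        raise InvalidParameterError("steps must be >= 0")
    cols = [bits]
    for _ in range(steps):
        cols.append(net.step(cols[-1]))
    arr = np.array(cols, dtype=int).T
    labels = [f"t{j}" for j in range(steps + 1)]
    return BinaryStateTable(arr, labels, False)


def expression_from_states(
    table: BinaryStateTable,
    genes_per_module: int = 40,
    mu_on: float = 100.0,
    mu_off: float = 1.0,
    sigma: float = 0.2,
    batch_offsets: Sequence[float] = (1.0,),
    seed: int = 0,
    decay: float = 8.0,
    n_background: int = 20,
) -> list[ExpressionMatrix]:
    """Noisy modular expression matrices realizing a binary state table.

    A gene of module i at observed position j takes value ``mu_on`` where
    ``s_i(j) = 1`` and ``mu_off / decay**(d-1)`` at distance ``d`` from
    the module's nearest ON position -- so off-interval profiles fall
    geometrically (monotone, >= ``decay``-fold per interval) and the
    gene binarizes back to exactly its module's interval.  Each value is
    multiplied by log-normal noise ``exp(N(0, sigma^2))`` and by the
    batch's constant offset; one matrix per entry of ``batch_offsets`` is
    returned, covering all observed positions.

    Marker genes (``marker_hh``, ``marker_ci``, ``marker_dpp``) are
    injected with fixed noiseless shapes, and ``n_background`` alternating
    non-monotone genes (``bg_*``) that must fail an MRG screen.
    """
    if not mu_on > mu_off > 0:
        raise InvalidParameterError("need mu_on > mu_off > 0")
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    if decay < 2:
        raise InvalidParameterError("decay must be >= 2")
    rng = np.random.default_rng(seed)
    obs = table.observed()
    P = obs.n_positions
    labels = obs.position_labels

    gene_ids: list[str] = []
    base_rows: list[np.ndarray] = []
    noisy: list[bool] = []
    for i in range(1, table.m + 1):
        row = obs.states[i - 1]
        on = np.flatnonzero(row)
        if on.size:
            d = np.array([0 if row[j] else np.abs(on - j).min() for j in range(P)])
            profile = np.where(row == 1, mu_on, mu_off * decay ** (-(np.maximum(d, 1) - 1.0)))
        else:
            profile = np.full(P, mu_off)
        for g in range(genes_per_module):
            gene_ids.append(f"M{i:02d}_g{g:03d}")
            base_rows.append(profile)
            noisy.append(True)

    # fixed-shape markers (deterministic so ordering checks are exact)
    hh = np.full(P, mu_off)
    hh[-1] = mu_on
    ci = np.full(P, mu_on)
    ci[-1] = mu_off
    centre = P // 2
    dpp = mu_on * decay ** (-np.abs(np.arange(P) - centre).astype(float))
    dpp = np.maximum(dpp, mu_off * 1e-3)
    for name, prof in (("marker_hh", hh), ("marker_ci", ci), ("marker_dpp", dpp)):
        gene_ids.append(name)
        base_rows.append(prof)
        noisy.append(False)

    for k in range(n_background):
        prof = np.where((np.arange(P) + k) % 2 == 0, 3.0 * mu_off, mu_off)
        gene_ids.append(f"bg_{k:03d}")
        base_rows.append(prof.astype(float))
        noisy.append(True)

    base = np.vstack(base_rows)
    matrices = []
    for b, offset in enumerate(batch_offsets):
        if offset <= 0:
            raise InvalidParameterError("batch offsets must be > 0")
        vals = base.copy()
        if sigma > 0:
            factors = np.exp(rng.normal(0.0, sigma, size=base.shape))
            factors[~np.array(noisy)] = 1.0
            vals = vals * factors
        vals *= offset
        df = pd.DataFrame(vals, index=gene_ids, columns=labels)
        matrices.append(ExpressionMatrix(df, batch_label=f"batch{b + 1}"))
    return matrices


def wing_disc_state_table() -> BinaryStateTable:
    """The canonical synthetic 12-module, 13-position spatial table.

    Contiguous ON intervals per :data:`WING_DISC_RUNS`, interleaved A/B
    position labels, and the terminal column duplicated as the stationary
    final state.
    """
    P = len(WING_DISC_ORDER)
    arr = np.zeros((12, P), dtype=int)
    for i, (a, b) in WING_DISC_RUNS.items():
        arr[i - 1, a : b + 1] = 1
    table = BinaryStateTable(arr, list(WING_DISC_ORDER), False)
    return table.with_terminal_duplicate()


def wing_disc_ground_truth(
    seed: int = 0,
    genes_per_module: int = 40,
    sigma: float = 0.2,
    mu_on: float = 100.0,
    mu_off: float = 1.0,
    batch_offsets: Sequence[float] = (1.0, 1.6),
    n_background: int = 20,
) -> GroundTruth:
    """Full synthetic study: table, network, gene modules, two batches.

    The two expression batches are the staggered sample sets: batch A
    holds the A1..A6 columns, batch B the B1..B7 columns, each with its
    own constant offset and independent noise.  The ground-truth network
    is the deterministic inference result on the noiseless table; by the
    inference postcondition its trajectory from the first column
    reproduces the table exactly.
    """
    table = wing_disc_state_table()
    full = expression_from_states(
        table,
        genes_per_module=genes_per_module,
        mu_on=mu_on,
        mu_off=mu_off,
        sigma=sigma,
        batch_offsets=batch_offsets,
        seed=seed,
        n_background=n_background,
    )
    expr_a = full[0].select_positions(_A_POSITIONS, batch_label="A")
    expr_b = full[1].select_positions(_B_POSITIONS, batch_label="B")
    assignment = ModuleAssignment(
        module_of={
            f"M{i:02d}_g{g:03d}": i
            for i in range(1, 13)
            for g in range(genes_per_module)
        },
        m=12,
    )
    network = infer_network(table)
    return GroundTruth(
        network=network,
        state_table=table,
        assignment=assignment,
        expression_pair=(expr_a, expr_b),
        seed=seed,
        markers={"hh": "marker_hh", "ci": "marker_ci", "dpp": "marker_dpp"},
    )
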