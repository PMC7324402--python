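"""Robustness studies on the gene modular network.

Two perturbation designs are implemented.

*Genetic (bit-flip) perturbation.*  A fixed number of cells of the
observed spatial state table are flipped uniformly at random, the network
is re-inferred from the perturbed table and its attractor landscape is
compared with the original's.  Repeated over many replicates this
measures how often small errors in the observed module states change the
asymptotic behaviour of the inferred network.  The duplicated terminal
column never receives its own flips; it is re-synchronized with the
terminal observed column so the "constant beyond the last position"
assumption is preserved.

*Morphogen-production (boundary-shift) scan.*  The ON run of the
morphogen-readout module (M8 by default: Hedgehog-pathway genes) is
widened away from, or shrunk toward, the source-compartment boundary to
emulate increased / decreased morphogen production; each scenario table is
re-inferred and scored by the percentage of all initial states that
converge to the normal attractor.

Trajectory robustness is quantified by *overlap ratios*: for every
initial state converging to the normal attractor (major-path states
excluded), the fraction of its trajectory's states that lie on the major
(physiological) trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .dynamics import (
    AttractorReport,
    find_attractors,
    trajectory,
    _eventual,
    _trajectory_ints,
)
from .exceptions import (
    GMNError,
    InvalidParameterError,
    UnsatisfiableInferenceError,
)
from .infer import infer_network
from .logic import Bits, BooleanNetwork, as_state, state_to_int, state_to_string
from .modules import BinaryStateTable


# ---------------------------------------------------------------------------
# bit-flip perturbation


def perturb_table(
    table: BinaryStateTable,
    n_flips: int = 2,
    rng: np.random.Generator | None = None,
) -> BinaryStateTable:
    """Flip ``n_flips`` distinct uniformly chosen observed cells.

    Flippable cells are the m x (observed positions) entries; the
    duplicated terminal column is excluded from the draw and then reset to
    mirror the terminal observed column.
    """
    if rng is None:
        rng = np.random.default_rng()
    m, p_obs = table.m, table.n_observed
    n_cells = m * p_obs
    if not 0 <= n_flips <= n_cells:
        raise InvalidParameterError(
            f"n_flips must be in 0..{n_cells}, got {n_flips}"
        )
    arr = table.states.copy()
    if n_flips:
        chosen = rng.choice(n_cells, size=n_flips, replace=False)
        rows, cols = np.unravel_index(chosen, (m, p_obs))
        arr[rows, cols] ^= 1
    if table.terminal_duplicated:
        arr[:, -1] = arr[:, -2]
    return BinaryStateTable(arr, list(table.position_labels), table.terminal_duplicated)


@dataclass
class PerturbationResult:
    replicates: int
    n_flips: int
    same_attractor_fraction: float  # percentage of replicates
    mean_basins: dict[str, float]  # original attractor bitstring -> mean size
    overlap_original: np.ndarray
    overlap_perturbed: np.ndarray | None
    comparison: tuple[str, float, float] | None  # (test, statistic, p-value)
    seed: int | None
    records: list[dict]

    def to_json(self) -> dict:
        return {
            "replicates": self.replicates,
            "n_flips": self.n_flips,
            "same_attractor_fraction_pct": self.same_attractor_fraction,
            "mean_basins": self.mean_basins,
            "comparison": (
                None
                if self.comparison is None
                else {
                    "test": self.comparison[0],
                    "statistic": self.comparison[1],
                    "p_value": self.comparison[2],
                }
            ),
            "seed": self.seed,
        }


def compare_distributions(
    d1: Sequence[float], d2: Sequence[float], test: str = "ks"
) -> tuple[str, float, float]:
    """Two-sample comparison of overlap-ratio distributions.

    Default is the two-sample Kolmogorov-Smirnov test; ``test`` may also
    be ``"mannwhitney"``.  Returns ``(test, statistic, p_value)``.
    """
    a = np.asarray(list(d1), dtype=float)
    b = np.asarray(list(d2), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("distributions must be non-empty")
    if test == "ks":
        res = stats.ks_2samp(a, b)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b)
    else:
        raise InvalidParameterError(f"unknown test {test!r}")
    return (test, float(res.statistic), float(res.pvalue))


def overlap_distribution(
    net: BooleanNetwork,
    major_path: Sequence[Sequence[int] | str],
    target_attractor: Sequence[int] | str | Iterable,
) -> np.ndarray:
    """Overlap ratio of every other trajectory with the major trajectory.

    For each initial state whose trajectory reaches ``target_attractor``
    -- excluding initial states lying on the major path itself -- the
    ratio is |trajectory states on the major path| / |trajectory states|.
    """
    if not len(major_path):
        raise InvalidParameterError("major path must be non-empty")
    att_states = _attractor_state_ints(net, target_attractor)
    succ = net.successor_array()
    # verify the target is actually an attractor cycle of net
    for s in att_states:
        if int(succ[s]) not in att_states:
            raise InvalidParameterError(
                "target is not an attractor of the network"
            )
    major = {state_to_int(as_state(s)) for s in major_path}
    t = _eventual(succ, net.m)
    ratios = []
    for s0 in range(1 << net.m):
        if int(t[s0]) not in att_states or s0 in major:
            continue
        path = _trajectory_ints(succ, s0)
        ratios.append(sum(1 for s in path if s in major) / len(path))
    return np.asarray(ratios, dtype=float)


def _attractor_state_ints(net, target) -> set[int]:
    if isinstance(target, str) or (
        isinstance(target, Sequence) and all(isinstance(b, (int, np.integer)) for b in target)
    ):
        states = [as_state(target)]
    else:
        states = [as_state(s) for s in target]
    for s in states:
        if len(s) != net.m:
            raise InvalidParameterError("target state has the wrong length")
    return {state_to_int(s) for s in states}


def perturbation_study(
    table: BinaryStateTable,
    reps: int = 1000,
    n_flips: int = 2,
    max_indegree: int | None = None,
    completion: str = "zero",
    seed: int | None = None,
    test: str = "ks",
) -> PerturbationResult:
    """Bit-flip / re-infer / re-enumerate robustness study.

    Per replicate the observed table is perturbed, a network re-inferred
    and its attractors computed.  Reported are: the percentage of
    replicates whose attractor set equals the original's exactly (cycles
    compared as state sets); the mean basin size of each original
    attractor over the matching replicates; and a distribution comparison
    of trajectory overlap ratios between the original network and the
    first matching perturbed one.  A replicate whose inference fails is
    recorded as non-matching, not fatal.  Fully reproducible from ``seed``.
    """
    if reps < 1:
        raise InvalidParameterError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    base_net = infer_network(table, max_indegree, completion)
    base_report = find_attractors(base_net)
    base_canon = base_report.canonical()
    key_of = {a.state_set: state_to_string(a.states[0]) for a in base_report.attractors}

    major = trajectory(base_net, table.column(0))
    normal = base_report.containing(major[-1])
    overlap_orig = overlap_distribution(base_net, major, normal.states)

    basin_acc: dict[str, list[int]] = {k: [] for k in key_of.values()}
    records: list[dict] = []
    matches = 0
    overlap_pert = None
    for r in range(reps):
        pt = perturb_table(table, n_flips, rng)
        rec: dict = {"replicate": r, "matched": False, "reason": ""}
        try:
            net = infer_network(pt, max_indegree, completion)
        except UnsatisfiableInferenceError as e:
            rec["reason"] = f"inference failed: {e}"
            records.append(rec)
            continue
        report = find_attractors(net)
        if report.canonical() == base_canon:
            matches += 1
            rec["matched"] = True
            for a in report.attractors:
                basin_acc[key_of[a.state_set]].append(a.basin_size)
            if overlap_pert is None:
                p_major = trajectory(net, pt.column(0))
                overlap_pert = overlap_distribution(net, p_major, normal.states)
        else:
            rec["reason"] = "different attractor set"
        records.append(rec)

    mean_basins = {
        k: (float(np.mean(v)) if v else float("nan")) for k, v in basin_acc.items()
    }
    comparison = None
    if overlap_pert is not None and overlap_pert.size and overlap_orig.size:
        comparison = compare_distributions(overlap_orig, overlap_pert, test)
    return PerturbationResult(
        replicates=reps,
        n_flips=n_flips,
        same_attractor_fraction=100.0 * matches / reps,
        mean_basins=mean_basins,
        overlap_original=overlap_orig,
        overlap_perturbed=overlap_pert,
        comparison=comparison,
        seed=seed,
        records=records,
    )


# ---------------------------------------------------------------------------
# morphogen-production scan


@dataclass(frozen=True)
class ScanScenario:
    delta: int
    module_row: str  # ON/OFF pattern over observed positions
    pct_normal: float


@dataclass
class MorphogenScanResult:
    module_index: int
    normal_attractor: tuple[str, ...]
    scenarios: list[ScanScenario]

    @property
    def physiological(self) -> ScanScenario:
        return next(s for s in self.scenarios if s.delta == 0)

    def to_json(self) -> dict:
        return {
            "module_index": self.module_index,
            "normal_attractor": list(self.normal_attractor),
            "scenarios": [
                {"delta": s.delta, "module_row": s.module_row, "pct_normal": s.pct_normal}
                for s in self.scenarios
            ],
        }


def _on_run(row: np.ndarray, module_index: int) -> tuple[int, int]:
    on = np.flatnonzero(row)
    if on.size == 0:
        raise InvalidParameterError(
            f"module M{module_index} has no ON position; supply an explicit row"
        )
    a, b = int(on[0]), int(on[-1])
    if b - a + 1 != on.size:
        raise InvalidParameterError(
            f"module M{module_index} ON region is not contiguous; "
            "override the row explicitly"
        )
    return a, b


def morphogen_scan(
    table: BinaryStateTable,
    module_index: int = 8,
    shifts: Sequence[int] = (-4, -3, -2, -1, 0, 1, 2, 3, 4),
    max_indegree: int | None = None,
    completion: str = "zero",
    mode: str = "reinfer",
) -> MorphogenScanResult:
    """Attractor scan under shifted morphogen-readout boundaries.

    The physiological ON run ``[a, b]`` of module ``module_index`` (over
    the observed positions, the source compartment at the high-index end)
    is modified per shift delta: production increase (delta > 0) widens
    the run away from the source boundary (``a -> a - delta``, clamped at
    the first position); production decrease (delta < 0) switches off the
    ``|delta|`` run positions closest to the boundary (``b -> b - |delta|``),
    down to an all-OFF row (with a warning).  Each scenario table is
    re-built (terminal column re-duplicated) and scored by the percentage
    of all ``2^m`` initial states converging to the normal attractor of
    the unmodified analysis; delta = 0 reproduces the baseline exactly.

    ``mode="reinfer"`` (default) re-infers the network per scenario.
    ``mode="fixed"`` keeps the physiological network and instead restricts
    the initial states to those whose module bit agrees with the modified
    row at the first position, scoring the percentage of that restricted
    set converging to the normal attractor.
    """
    if not 1 <= module_index <= table.m:
        raise InvalidParameterError(f"module_index out of 1..{table.m}")
    if mode not in ("reinfer", "fixed"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    base_row = table.states[module_index - 1, : table.n_observed].copy()
    a, b = _on_run(base_row, module_index)

    base_net = infer_network(table, max_indegree, completion)
    base_report = find_attractors(base_net)
    major = trajectory(base_net, table.column(0))
    normal = base_report.containing(major[-1])
    normal_ints = {state_to_int(s) for s in normal.states}

    scenarios = []
    for delta in shifts:
        if delta >= 0:
            new_a, new_b = max(0, a - delta), b
        else:
            new_a, new_b = a, b + delta  # delta < 0 retracts the boundary edge
        row = np.zeros_like(base_row)
        if new_b >= new_a:
            row[new_a : new_b + 1] = 1
        else:
            warnings.warn(
                f"delta={delta} empties the ON run of M{module_index}; "
                "row is all-OFF",
                stacklevel=2,
            )
        mod_table = table.replace_row(module_index, row)
        if mode == "reinfer":
            try:
                net = infer_network(mod_table, max_indegree, completion)
            except UnsatisfiableInferenceError:
                scenarios.append(
                    ScanScenario(delta, "".join(map(str, row)), float("nan"))
                )
                continue
            t = _eventual(net.successor_array(), net.m)
            pct = 100.0 * np.isin(t, list(normal_ints)).mean()
        else:
            t = _eventual(base_net.successor_array(), base_net.m)
            sel = np.flatnonzero(
                ((np.arange(1 << base_net.m) >> (module_index - 1)) & 1) == row[0]
            )
            pct = 100.0 * np.isin(t[sel], list(normal_ints)).mean()
        scenarios.append(ScanScenario(delta, "".join(map(str, row)), float(pct)))

    return MorphogenScanResult(
        module_index=module_index,
        normal_attractor=tuple(state_to_string(s) for s in normal.states),
        scenarios=scenarios,
    )
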