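"""Model/Results facade over the gene-modular-network pipeline.

:class:`GMNModel` holds the observed data (a binary spatial state table,
possibly built from raw expression via :meth:`GMNModel.from_expression`)
together with the inference options; :meth:`GMNModel.fit` infers the
synchronous Boolean network and returns a :class:`GMNResults` carrying the
network, the full attractor/basin report, the state-transition graph and
the major (physiological) trajectory, with robustness studies and
plotting as methods of the results object.

Example
-------
>>> from gmnet import GMNModel, wing_disc_ground_truth
>>> gt = wing_disc_ground_truth(seed=0)
>>> res = GMNModel(gt.state_table).fit()
>>> len(res.attractors.attractors), res.attractors.n_states
(...)
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dynamics import (
    AttractorReport,
    TransitionGraph,
    find_attractors,
    trajectory,
    transition_graph,
)
from .exceptions import InvalidParameterError
from .expression import ExpressionMatrix
from .infer import infer_network
from .logic import Bits, BooleanNetwork, state_to_string
from .modules import (
    BinaryStateTable,
    ModuleAssignment,
    binarize_genes,
    cluster_genes,
    module_states,
)
from .robustness import (
    MorphogenScanResult,
    PerturbationResult,
    morphogen_scan,
    overlap_distribution,
    perturbation_study,
)
from .rules import parse_rules, serialize_rules
from .screening import ScreenResult, common_mrgs, integrate_samples, screen_mrgs


class GMNModel:
    """A gene modular network to be inferred from spatial state data.

    Parameters
    ----------
    state_table
        Binary module-state table (modules x ordered positions); if its
        terminal column is not already duplicated it is duplicated here,
        encoding stationarity inside the morphogen source compartment.
    max_indegree, completion
        Inference options (see :func:`gmnet.infer.infer_network`).
    reverse
        Analyze the posterior-to-anterior reading of the axis (the table
        is reversed before inference).  Default is anterior-to-posterior.
    """

    def __init__(
        self,
        state_table: BinaryStateTable,
        *,
        max_indegree: int | None = None,
        completion: str = "zero",
        reverse: bool = False,
        network: BooleanNetwork | None = None,
    ) -> None:
        if reverse and state_table is not None:
            obs = state_table.observed()
            state_table = BinaryStateTable(
                obs.states[:, ::-1].copy(), obs.position_labels[::-1], False
            ).with_terminal_duplicate()
        if state_table is not None and not state_table.terminal_duplicated:
            state_table = state_table.with_terminal_duplicate()
        self.state_table = state_table
        self.max_indegree = max_indegree
        self.completion = completion
        self.network = network
        # populated by from_expression
        self.assignment: ModuleAssignment | None = None
        self.screen_result: ScreenResult | None = None
        self.integrated: ExpressionMatrix | None = None

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_expression(
        cls,
        expr_a: ExpressionMatrix,
        expr_b: ExpressionMatrix,
        *,
        order: list,
        m: int = 12,
        genes: Sequence[str] | None = None,
        screen: bool = True,
        window_intervals: int = 4,
        fold: float = 2.0,
        distance: str = "correlation",
        linkage: str = "average",
        pseudocount: float = 1.0,
        markers: dict[str, str] | None = None,
        max_indegree: int | None = None,
        completion: str = "zero",
    ) -> "GMNModel":
        """Build the model from two raw expression batches.

        When ``genes`` is given the screen is bypassed and exactly those
        genes are used; otherwise both batches are screened for MRGs and
        their intersection is taken (``screen=False`` with no gene list
        uses all genes common to the two batches).
        """
        if genes is not None:
            gene_set = set(genes)
            screen_result = None
        elif screen:
            sa = screen_mrgs(expr_a, window_intervals, fold)
            sb = screen_mrgs(expr_b, window_intervals, fold)
            screen_result = common_mrgs(sa, sb)
            gene_set = screen_result.common
        else:
            screen_result = None
            gene_set = set(expr_a.gene_ids) & set(expr_b.gene_ids)
        if len(gene_set) < m:
            raise InvalidParameterError(
                f"only {len(gene_set)} genes available for {m} modules"
            )
        integrated = integrate_samples(
            expr_a, expr_b, order, gene_set, pseudocount=pseudocount, markers=markers
        )
        assignment = cluster_genes(integrated, m=m, distance=distance, linkage=linkage)
        table = module_states(
            binarize_genes(integrated), assignment, duplicate_terminal=True
        )
        model = cls(table, max_indegree=max_indegree, completion=completion)
        model.assignment = assignment
        model.screen_result = screen_result
        model.integrated = integrated
        return model

    @classmethod
    def from_rules(cls, text: str) -> "GMNModel":
        """Model with a fixed published/known rule set (no inference)."""
        return cls(None, network=parse_rules(text))

    @classmethod
    def from_rules_file(cls, path: str | Path) -> "GMNModel":
        return cls.from_rules(Path(path).read_text())

    # -- fitting -------------------------------------------------------------
    def fit(self) -> "GMNResults":
        """Infer the Boolean network (unless fixed) and enumerate dynamics."""
        if self.network is not None:
            net = self.network
        else:
            net = infer_network(self.state_table, self.max_indegree, self.completion)
        return GMNResults(model=self, network=net)


class GMNResults:
    """Fitted gene modular network: rules, attractors, trajectories."""

    def __init__(self, model: GMNModel, network: BooleanNetwork) -> None:
        self.model = model
        self.network = network
        self.attractors: AttractorReport = find_attractors(network)
        self._transition: TransitionGraph | None = None
        self.major_trajectory: list[Bits] | None = None
        self.normal_attractor = None
        if model.state_table is not None:
            self.major_trajectory = trajectory(network, model.state_table.column(0))
            self.normal_attractor = self.attractors.containing(
                self.major_trajectory[-1]
            )

    # -- dynamics ------------------------------------------------------------
    @property
    def transition(self) -> TransitionGraph:
        if self._transition is None:
            self._transition = transition_graph(self.network)
        return self._transition

    def trajectory(self, s0: Sequence[int] | str) -> list[Bits]:
        return trajectory(self.network, s0)

    def rules_text(self) -> str:
        return serialize_rules(self.network)

    # -- robustness ----------------------------------------------------------
    def perturbation_study(
        self,
        reps: int = 1000,
        n_flips: int = 2,
        seed: int | None = None,
        test: str = "ks",
    ) -> PerturbationResult:
        self._require_table("perturbation_study")
        return perturbation_study(
            self.model.state_table,
            reps=reps,
            n_flips=n_flips,
            max_indegree=self.model.max_indegree,
            completion=self.model.completion,
            seed=seed,
            test=test,
        )

    def morphogen_scan(
        self,
        module_index: int = 8,
        shifts: Sequence[int] = (-4, -3, -2, -1, 0, 1, 2, 3, 4),
        mode: str = "reinfer",
    ) -> MorphogenScanResult:
        self._require_table("morphogen_scan")
        return morphogen_scan(
            self.model.state_table,
            module_index=module_index,
            shifts=shifts,
            max_indegree=self.model.max_indegree,
            completion=self.model.completion,
            mode=mode,
        )

    def overlap_distribution(self) -> np.ndarray:
        if self.major_trajectory is None or self.normal_attractor is None:
            raise InvalidParameterError(
                "overlap distribution needs a state table (major trajectory)"
            )
        return overlap_distribution(
            self.network, self.major_trajectory, self.normal_attractor.states
        )

    def _require_table(self, what: str) -> None:
        if self.model.state_table is None:
            raise InvalidParameterError(
                f"{what} needs the observed state table; the model was "
                "built from rules only"
            )

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        """Human-readable account of the fitted network and its dynamics."""
        net = self.network
        lines = [
            "Gene Modular Network (synchronous Boolean model)",
            "=" * 48,
            f"modules:            {net.m}",
            f"state space:        {1 << net.m} states",
            f"attractors:         {len(self.attractors.attractors)}",
        ]
        if self.model.state_table is not None:
            lines.append(
                f"observed positions: {self.model.state_table.n_observed} "
                f"(+ duplicated terminal)"
            )
        lines.append("")
        lines.append("Update rules")
        lines.append("-" * 48)
        for fn in net.functions:
            lines.append(f"  M{fn.target} <- {fn.expression}")
        lines.append("")
        lines.append("Attractors (basin sizes sum to the state space)")
        lines.append("-" * 48)
        lines.append(f"  {'states':<30}{'basin':>8}{'%':>8}  type")
        for a in self.attractors.attractors:
            states = ",".join(a.bitstrings)
            kind = "fixed point" if a.is_fixed_point else f"cycle({len(a.states)})"
            lines.append(
                f"  {states:<30}{a.basin_size:>8}{a.basin_pct:>8.2f}  {kind}"
            )
        if self.major_trajectory is not None:
            lines.append("")
            lines.append(
                f"major trajectory:   {len(self.major_trajectory)} states, "
                f"{state_to_string(self.major_trajectory[0])} -> "
                f"{state_to_string(self.major_trajectory[-1])}"
            )
        return "\n".join(lines)

    def to_json(self) -> dict:
        out = {
            "m": self.network.m,
            "rules": {
                f"M{fn.target}": fn.expression for fn in self.network.functions
            },
            "attractors": self.attractors.to_json()["attractors"],
        }
        if self.major_trajectory is not None:
            out["major_trajectory"] = [
                state_to_string(s) for s in self.major_trajectory
            ]
        return out

    # -- plotting ------------------------------------------------------------
    def plot_basins(self, ax=None):
        """Bar chart of basin percentages per attractor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        labels = [",".join(a.bitstrings) for a in self.attractors.attractors]
        pcts = [a.basin_pct for a in self.attractors.attractors]
        ax.bar(range(len(pcts)), pcts, color="#4477aa")
        ax.set_xticks(range(len(pcts)))
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
        ax.set_ylabel("% of initial states")
        ax.set_title("Basins of attraction")
        return ax

    def plot_overlap(self, other: np.ndarray | None = None, ax=None):
        """Histogram of trajectory overlap ratios (optionally vs another)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        bins = np.linspace(0, 1, 21)
        ax.hist(
            self.overlap_distribution(), bins=bins, density=True,
            histtype="step", color="crimson", label="original",
        )
        if other is not None:
            ax.hist(
                np.asarray(other), bins=bins, density=True,
                histtype="step", color="seagreen", label="perturbed",
            )
        ax.set_xlabel("overlap ratio with major trajectory")
        ax.set_ylabel("density")
        ax.legend(frameon=False)
        return ax
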