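"""Gene modules and binary spatial module states.

This stage turns the integrated expression matrix into the object the
Boolean analysis runs on:

1. hierarchical clustering of the genes into ``m`` modules
   (:func:`cluster_genes`);
2. per-gene binarization against the gene's across-position mean
   (:func:`binarize_genes`);
3. strict-majority voting inside each module to obtain the binary module
   state per position (:func:`module_states`), optionally appending a
   duplicate of the terminal position to encode that the pattern is
   constant inside the source compartment of the morphogen.

Conventions (deliberately literal and therefore testable): a gene is ON at
a position iff its value *strictly* exceeds its own mean; a module is ON
iff *strictly more than half* of its genes are ON; ties count as OFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .exceptions import InvalidParameterError
from .expression import ExpressionMatrix
from .logic import Bits, state_to_string


@dataclass
class ModuleAssignment:
    """Partition of genes into modules 1..m."""

    module_of: dict[str, int]
    m: int

    def __post_init__(self) -> None:
        seen = set(self.module_of.values())
        bad = [i for i in self.module_of.values() if not 1 <= i <= self.m]
        if bad:
            raise InvalidParameterError(f"module indices out of 1..{self.m}")
        empty = [i for i in range(1, self.m + 1) if i not in seen]
        if empty:
            raise InvalidParameterError(f"empty modules: {empty}")

    def genes_in(self, i: int) -> list[str]:
        return [g for g, mi in self.module_of.items() if mi == i]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.module_of)


@dataclass
class BinaryStateTable:
    """m x P binary matrix of module states across ordered positions.

    ``terminal_duplicated`` marks that the last column is a copy of the
    second-to-last, appended as the stationary final state; the duplicate
    takes part in network inference (it pins the terminal state as a fixed
    point of the observed dynamics) but is excluded from perturbation and
    expression modelling, which act on the observed columns only.
    """

    states: np.ndarray
    position_labels: list[str]
    terminal_duplicated: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.states, dtype=int)
        if arr.ndim != 2:
            raise InvalidParameterError("states must be a 2-D matrix")
        if not np.isin(arr, (0, 1)).all():
            raise InvalidParameterError("state entries must be 0/1")
        if len(self.position_labels) != arr.shape[1]:
            raise InvalidParameterError(
                f"{len(self.position_labels)} labels for {arr.shape[1]} columns"
            )
        if self.terminal_duplicated:
            if arr.shape[1] < 2 or not (arr[:, -1] == arr[:, -2]).all():
                raise InvalidParameterError(
                    "terminal_duplicated set but last two columns differ"
                )
        self.states = arr
        self.position_labels = [str(p) for p in self.position_labels]

    @property
    def m(self) -> int:
        return self.states.shape[0]

    @property
    def n_positions(self) -> int:
        return self.states.shape[1]

    @property
    def n_observed(self) -> int:
        """Number of measured positions (excludes the duplicated terminal)."""
        return self.n_positions - 1 if self.terminal_duplicated else self.n_positions

    def column(self, j: int) -> Bits:
        return tuple(int(b) for b in self.states[:, j])

    def bitstring(self, j: int) -> str:
        return state_to_string(self.column(j))

    def columns(self) -> list[Bits]:
        return [self.column(j) for j in range(self.n_positions)]

    def observed(self) -> "BinaryStateTable":
        """The table restricted to measured positions."""
        if not self.terminal_duplicated:
            return self
        return BinaryStateTable(
            self.states[:, :-1].copy(), self.position_labels[:-1], False
        )

    def with_terminal_duplicate(self) -> "BinaryStateTable":
        if self.terminal_duplicated:
            return self
        arr = np.column_stack([self.states, self.states[:, -1]])
        labels = self.position_labels + [self.position_labels[-1] + "*"]
        return BinaryStateTable(arr, labels, True)

    def replace_row(self, module_index: int, observed_row: Sequence[int]) -> "BinaryStateTable":
        """Return a copy with module ``module_index`` (1-based) replaced.

        ``observed_row`` covers the observed columns; the duplicated
        terminal column, if present, is re-synchronized.
        """
        row = np.asarray(observed_row, dtype=int)
        if row.shape != (self.n_observed,):
            raise InvalidParameterError(
                f"row must have {self.n_observed} observed entries"
            )
        arr = self.states.copy()
        arr[module_index - 1, : self.n_observed] = row
        if self.terminal_duplicated:
            arr[:, -1] = arr[:, -2]
        return BinaryStateTable(arr, list(self.position_labels), self.terminal_duplicated)

    # -- IO ------------------------------------------------------------------
    def to_tsv(self, path: str | Path, comment: str | None = None) -> None:
        df = pd.DataFrame(
            self.states,
            index=[f"M{i}" for i in range(1, self.m + 1)],
            columns=self.position_labels,
        )
        with Path(path).open("w") as fh:
            if comment:
                for line in comment.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index_label="module")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinaryStateTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        labels = [str(c) for c in df.columns]
        dup = (
            len(labels) >= 2
            and labels[-1].endswith("*")
            and labels[-1][:-1] == labels[-2]
            and (df.iloc[:, -1] == df.iloc[:, -2]).all()
        )
        return cls(df.to_numpy(dtype=int), labels, bool(dup))

    def to_bitstrings(self) -> dict[str, str]:
        """Compact per-position bit-strings (M1 leftmost), for JSON reports."""
        return {lab: self.bitstring(j) for j, lab in enumerate(self.position_labels)}


# ---------------------------------------------------------------------------
# operations


def cluster_genes(
    expr: ExpressionMatrix,
    m: int = 12,
    distance: str = "correlation",
    linkage: str = "average",
) -> ModuleAssignment:
    """Hierarchically cluster per-gene standardized profiles into m modules.

    Profiles are z-scored per gene, pairwise distances computed with the
    given metric (default 1 - Pearson correlation), the dendrogram built
    with the given linkage (default average/UPGMA) and cut into ``m``
    groups.  Modules are renumbered along the axis so labels are
    reproducible: by the first position at which the cluster's mean
    profile exceeds its across-position mean (the ON-region start --
    robust when the profile plateaus), ties broken by the peak position,
    then by the original cluster label.  Earliest = M1.
    """
    if m > expr.n_genes:
        raise InvalidParameterError(
            f"m={m} exceeds the number of genes ({expr.n_genes})"
        )
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    X = expr.values.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant genes -> all-zero profile
    Z = (X - mu) / sd
    with np.errstate(invalid="ignore", divide="ignore"):
        D = pdist(Z, metric=distance)
    D = np.nan_to_num(D, nan=1.0)  # constant rows have undefined correlation
    link = hierarchy.linkage(D, method=linkage)
    labels = hierarchy.fcluster(link, t=m, criterion="maxclust")

    # renumber clusters along the axis, earliest first
    order = []
    for lab in np.unique(labels):
        mp = X[labels == lab].mean(axis=0)
        above = np.flatnonzero(mp > mp.mean())
        start = int(above[0]) if above.size else int(np.argmax(mp))
        order.append((start, int(np.argmax(mp)), int(lab)))
    remap = {old: new for new, (_, _, old) in enumerate(sorted(order), start=1)}
    module_of = {
        g: remap[int(lab)] for g, lab in zip(expr.gene_ids, labels)
    }
    return ModuleAssignment(module_of=module_of, m=m)


def binarize_genes(expr: ExpressionMatrix) -> pd.DataFrame:
    """1 iff the value strictly exceeds the gene's across-position mean."""
    df = expr.values
    return df.gt(df.mean(axis=1), axis=0).astype(int)


def module_states(
    bin_matrix: pd.DataFrame,
    assignment: ModuleAssignment,
    duplicate_terminal: bool = True,
) -> BinaryStateTable:
    """Strict-majority vote of member genes per module per position.

    A module is ON at a position iff strictly more than half of its member
    genes are ON there (exact ties are OFF).  Genes in ``bin_matrix`` not
    covered by the assignment are ignored; an assigned gene missing from
    the matrix is an error.
    """
    missing = [g for g in assignment.gene_ids if g not in bin_matrix.index]
    if missing:
        raise InvalidParameterError(
            f"assigned genes missing from binary matrix: {missing[:5]}"
        )
    P = bin_matrix.shape[1]
    states = np.zeros((assignment.m, P), dtype=int)
    for i in range(1, assignment.m + 1):
        genes = assignment.genes_in(i)
        if not genes:
            raise InvalidParameterError(f"module M{i} is empty")
        sub = bin_matrix.loc[genes].to_numpy()
        states[i - 1] = (sub.sum(axis=0) * 2 > len(genes)).astype(int)
    table = BinaryStateTable(
        states, [str(c) for c in bin_matrix.columns], False
    )
    return table.with_terminal_duplicate() if duplicate_terminal else table
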