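"""Morphogen-responsive gene (MRG) screening and sample-set integration.

A gene responding directly to a diffusing morphogen should change
monotonically with distance from the source.  The screen keeps a gene if
somewhere along the axis it shows a run of ``window_intervals``
consecutive position-to-position intervals that all change in the same
direction, each by at least ``fold`` (computed on values + eps to guard
zeros).  With ``fold = 1`` the criterion degrades to plain (non-strict)
monotonicity over the window.

Two independently sectioned sample sets rarely hit identical positions;
their staggered positions are integrated into one refined axis after a
per-gene batch-offset removal on the log scale.  The interleaving order
is user-supplied (in the original design it was fixed by the known
profiles of the *hh*, *ci* and *dpp* markers); the integration step can
check marker shapes and warn when they do not look as expected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .expression import ExpressionMatrix

__all__ = ["screen_mrgs", "common_mrgs", "integrate_samples", "ScreenResult"]


def screen_mrgs(
    expr: ExpressionMatrix,
    window_intervals: int = 4,
    fold: float = 2.0,
    eps: float | None = None,
) -> set[str]:
    """Genes with a direction-consistent >= ``fold`` run of intervals.

    ``eps`` defaults to 1e-6 times the smallest positive value in the
    matrix.  Deterministic; invariant under a global positive scaling of
    a gene's profile (fold changes are ratios).
    """
    if window_intervals < 1:
        raise InvalidParameterError("window_intervals must be >= 1")
    if fold < 1:
        raise InvalidParameterError("fold must be >= 1")
    n_intervals = expr.n_positions - 1
    if window_intervals > n_intervals:
        raise InvalidParameterError(
            f"window_intervals={window_intervals} exceeds the "
            f"{n_intervals} intervals available"
        )
    V = expr.values.to_numpy(dtype=float)
    if eps is None:
        pos = V[V > 0]
        eps = 1e-6 * float(pos.min()) if pos.size else 1e-6
    if eps <= 0:
        raise InvalidParameterError("eps must be > 0")
    W = V + eps
    # the pseudo-count slightly deflates true ratios, so allow a tiny
    # relative tolerance: an exact fold-change must count as passing
    slack = 1.0 - 1e-5
    up = W[:, 1:] >= fold * W[:, :-1] * slack
    down = W[:, :-1] >= fold * W[:, 1:] * slack
    passing = _has_run(up, window_intervals) | _has_run(down, window_intervals)
    return {g for g, ok in zip(expr.gene_ids, passing) if ok}


def _has_run(mask: np.ndarray, w: int) -> np.ndarray:
    """Row-wise: does any window of w consecutive True exist?"""
    windows = np.lib.stride_tricks.sliding_window_view(mask, w, axis=1)
    return windows.all(axis=2).any(axis=1)


@dataclass
class ScreenResult:
    """Intersection of two per-sample-set MRG screens."""

    common: set[str]
    coverage: dict[str, float | None]  # percentage of each set that is common

    def to_json(self) -> dict:
        return {
            "n_common": len(self.common),
            "coverage_pct": self.coverage,
            "common": sorted(self.common),
        }


def common_mrgs(set_a: set[str], set_b: set[str]) -> ScreenResult:
    """Common MRGs plus per-set coverage (100 * |common| / |set|, 2 dp)."""
    common = set(set_a) & set(set_b)
    coverage: dict[str, float | None] = {}
    for name, s in (("A", set_a), ("B", set_b)):
        if not s:
            warnings.warn(
                f"sample set {name} passed no genes; coverage undefined",
                stacklevel=2,
            )
            coverage[name] = None
        else:
            coverage[name] = round(100.0 * len(common) / len(s), 2)
    return ScreenResult(common=common, coverage=coverage)


def integrate_samples(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    order: list,
    genes: set[str] | list[str],
    pseudocount: float = 1.0,
    markers: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Batch-adjust two sample sets and interleave them into one axis.

    ``order`` lists the output columns in axis order; each entry is either
    a ``(batch, position)`` pair with batch ``"A"``/``"B"`` (or the
    matrices' own batch labels) or a bare position label occurring in
    exactly one of the two matrices.

    The batch adjustment removes, per gene, each batch's mean deviation on
    ``log2(value + pseudocount)`` and back-transforms, so after adjustment
    the gene's per-batch log-means agree and its grand log-mean is
    preserved.  This is a plain two-group offset removal, not a reimplementation
    of any particular batch-correction package.

    ``markers`` may map roles ``"hh"`` / ``"ci"`` / ``"dpp"`` to gene IDs;
    the integrated profiles are then checked (source-exclusive terminal
    peak, source-excluded, interior peak respectively) and deviations are
    warned about, since the interleaving order was chosen from exactly
    these shapes.
    """
    genes = sorted(set(genes))
    for expr in (expr_a, expr_b):
        missing = [g for g in genes if g not in expr.values.index]
        if missing:
            raise InvalidParameterError(
                f"genes missing from batch {expr.batch_label or '?'}: "
                f"{missing[:10]}"
            )
    if pseudocount < 0:
        raise InvalidParameterError("pseudocount must be >= 0")

    A = expr_a.values.loc[genes]
    B = expr_b.values.loc[genes]
    la = np.log2(A.to_numpy(dtype=float) + pseudocount)
    lb = np.log2(B.to_numpy(dtype=float) + pseudocount)
    grand = (la.sum(axis=1) + lb.sum(axis=1)) / (la.shape[1] + lb.shape[1])
    la_adj = la - la.mean(axis=1, keepdims=True) + grand[:, None]
    lb_adj = lb - lb.mean(axis=1, keepdims=True) + grand[:, None]
    A_adj = pd.DataFrame(
        np.maximum(np.exp2(la_adj) - pseudocount, 0.0), index=genes, columns=A.columns
    )
    B_adj = pd.DataFrame(
        np.maximum(np.exp2(lb_adj) - pseudocount, 0.0), index=genes, columns=B.columns
    )

    batches = {"A": (expr_a, A_adj), "B": (expr_b, B_adj)}
    if expr_a.batch_label:
        batches[expr_a.batch_label] = batches["A"]
    if expr_b.batch_label:
        batches[expr_b.batch_label] = batches["B"]

    cols, labels = [], []
    for entry in order:
        if isinstance(entry, (tuple, list)):
            batch, pos = str(entry[0]), str(entry[1])
            if batch not in batches:
                raise InvalidParameterError(f"unknown batch {batch!r} in order")
            _, adj = batches[batch]
            if pos not in adj.columns:
                raise InvalidParameterError(
                    f"position {pos!r} not in batch {batch!r}"
                )
            cols.append(adj[pos])
            labels.append(pos)
        else:
            pos = str(entry)
            in_a, in_b = pos in A_adj.columns, pos in B_adj.columns
            if in_a == in_b:
                raise InvalidParameterError(
                    f"position {pos!r} must occur in exactly one batch; "
                    "use (batch, position) pairs"
                )
            adj = A_adj if in_a else B_adj
            cols.append(adj[pos])
            labels.append(pos)
    out = pd.concat(cols, axis=1)
    out.columns = labels
    integrated = ExpressionMatrix(out, batch_label="integrated")
    if markers:
        _check_markers(integrated, markers)
    return integrated


def _check_markers(expr: ExpressionMatrix, markers: dict[str, str]) -> None:
    df = expr.values
    last = df.shape[1] - 1
    for role, gene in markers.items():
        if gene not in df.index:
            warnings.warn(f"marker {role}={gene!r} not in matrix", stacklevel=3)
            continue
        v = df.loc[gene].to_numpy(dtype=float)
        above = v > v.mean()
        if role == "hh" and not (above[last] and not above[:last].any()):
            warnings.warn(
                f"hh-like marker {gene!r} is not exclusive to the terminal "
                "position; check the interleaving order",
                stacklevel=3,
            )
        elif role == "ci" and above[last]:
            warnings.warn(
                f"ci-like marker {gene!r} is active at the terminal position",
                stacklevel=3,
            )
        elif role == "dpp" and int(np.argmax(v)) in (0, last):
            warnings.warn(
                f"dpp-like marker {gene!r} does not peak in the interior",
                stacklevel=3,
            )
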