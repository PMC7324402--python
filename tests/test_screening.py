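"""MRG screening, set intersection/coverage, and sample integration."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gmnet import (
    ExpressionMatrix,
    InvalidParameterError,
    common_mrgs,
    integrate_samples,
    screen_mrgs,
)


def _expr(rows: dict[str, list[float]], batch="A") -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"p{j}" for j in range(df.shape[1])]
    return ExpressionMatrix(df, batch)


@pytest.mark.parametrize(
    "profile,window,expected",
    [
        ([32, 16, 8, 4, 2, 1], 4, True),   # exact 2-fold drop everywhere
        ([5, 5, 5, 5, 5, 5], 4, False),    # no change at all
        ([1, 2, 4, 8, 4, 2], 4, False),    # rises 3, falls 2: no 4-run
        ([1, 2, 4, 8, 4, 2], 3, True),     # but a 3-interval run exists
    ],
)
def test_monotone_window_criterion(profile, window, expected):
    expr = _expr({"g": profile})
    passed = "g" in screen_mrgs(expr, window_intervals=window, fold=2)
    assert passed is expected


def test_window_exceeding_intervals_rejected():
    with pytest.raises(InvalidParameterError):
        screen_mrgs(_expr({"g": [1, 2, 4]}), window_intervals=4)


def test_fold_one_degrades_to_monotonicity():
    expr = _expr({"flat_then_up": [1, 1, 2, 3, 4, 5], "wiggle": [1, 3, 2, 4, 3, 5]})
    got = screen_mrgs(expr, window_intervals=4, fold=1)
    assert got == {"flat_then_up"}


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    profile=st.lists(st.floats(0.5, 1e4), min_size=6, max_size=10),
    scale=st.floats(0.01, 100.0),
)
def test_screen_invariant_under_positive_scaling(profile, scale):
    """Fold changes are ratios, so a global gain leaves the screen unchanged."""
    a = _expr({"g": profile})
    b = _expr({"g": [v * scale for v in profile]})
    eps = 1e-9
    assert ("g" in screen_mrgs(a, 3, 2, eps=eps)) == (
        "g" in screen_mrgs(b, 3, 2, eps=eps * scale)
    )


# ---------------------------------------------------------------------------
# common MRGs


def test_coverage_from_printed_set_sizes():
    """4217 shared genes cover 93.21% / 78.15% of sets of 4524 / 5396."""
    shared = {f"c{i}" for i in range(4217)}
    set_a = shared | {f"a{i}" for i in range(4524 - 4217)}
    set_b = shared | {f"b{i}" for i in range(5396 - 4217)}
    res = common_mrgs(set_a, set_b)
    assert len(res.common) == 4217
    assert res.coverage == {"A": 93.21, "B": 78.15}


def test_coverage_identical_sets_and_symmetry():
    s = {"x", "y"}
    res = common_mrgs(s, s)
    assert res.coverage == {"A": 100.0, "B": 100.0}
    r1 = common_mrgs({"x"}, {"x", "y"})
    r2 = common_mrgs({"x", "y"}, {"x"})
    assert r1.common == r2.common
    assert r1.coverage["A"] == r2.coverage["B"]


def test_empty_set_coverage_missing_with_warning():
    with pytest.warns(UserWarning, match="coverage undefined"):
        res = common_mrgs(set(), {"x"})
    assert res.coverage["A"] is None
    assert res.coverage["B"] == 0.0


# ---------------------------------------------------------------------------
# integration


def test_pure_offset_batches_become_identical():
    """With a pure multiplicative offset, log-scale centring removes it.

    Checked on the pure log transform (pseudocount 0), where a 2x gain is
    exactly an additive log offset.
    """
    rows = {"g1": [1.0, 4.0, 2.0], "g2": [8.0, 2.0, 4.0]}
    a = _expr(rows, "A")
    b = _expr({g: [2 * v for v in vals] for g, vals in rows.items()}, "B")
    out = integrate_samples(
        a, b,
        order=[("A", "p0"), ("B", "p0"), ("A", "p1"), ("B", "p1"),
               ("A", "p2"), ("B", "p2")],
        genes={"g1", "g2"},
        pseudocount=0.0,
    )
    av = out.values.iloc[:, [0, 2, 4]].to_numpy()
    bv = out.values.iloc[:, [1, 3, 5]].to_numpy()
    np.testing.assert_allclose(av, bv, rtol=1e-12)


def test_interleaving_thirteen_columns():
    """6 A-positions and 7 B-positions interleave into 13 ordered columns."""
    a = ExpressionMatrix(
        pd.DataFrame(
            np.arange(12.0).reshape(2, 6) + 1,
            index=["g1", "g2"],
            columns=[f"A{i}" for i in range(1, 7)],
        ),
        "A",
    )
    b = ExpressionMatrix(
        pd.DataFrame(
            np.arange(14.0).reshape(2, 7) + 1,
            index=["g1", "g2"],
            columns=[f"B{i}" for i in range(1, 8)],
        ),
        "B",
    )
    order = ["A1", "B1", "A2", "B2", "B3", "A3", "B4", "A4", "B5", "A5",
             "B6", "A6", "B7"]
    out = integrate_samples(a, b, order, {"g1", "g2"})
    assert out.position_labels == order
    assert out.n_positions == 13


def test_same_batch_twice_is_identity_on_log_scale():
    rows = {"g1": [1.0, 2.0, 3.0], "g2": [5.0, 1.0, 2.0]}
    a = _expr(rows, "A")
    b = _expr(rows, "B")
    out = integrate_samples(
        a, b, order=[("A", "p0"), ("A", "p1"), ("A", "p2")],
        genes={"g1", "g2"}, pseudocount=0.0,
    )
    np.testing.assert_allclose(
        out.values.loc[["g1", "g2"]].to_numpy(),
        np.array([rows["g1"], rows["g2"]]),
        rtol=1e-12,
    )


def test_grand_log_mean_preserved():
    rng = np.random.default_rng(0)
    rows_a = {f"g{i}": rng.uniform(1, 50, 5).tolist() for i in range(4)}
    rows_b = {f"g{i}": rng.uniform(1, 50, 6).tolist() for i in range(4)}
    a, b = _expr(rows_a, "A"), _expr(rows_b, "B")
    order = [("A", f"p{j}") for j in range(5)] + [("B", f"p{j}") for j in range(6)]
    out = integrate_samples(a, b, order, set(rows_a), pseudocount=0.0)
    for g in rows_a:
        before = np.log2(np.concatenate([rows_a[g], rows_b[g]])).mean()
        after = np.log2(out.values.loc[g].to_numpy()).mean()
        assert after == pytest.approx(before, rel=1e-12)


def test_missing_gene_names_offenders():
    a = _expr({"g1": [1, 2], "g2": [1, 2]})
    b = _expr({"g1": [1, 2]}, "B")
    with pytest.raises(InvalidParameterError, match="g2"):
        integrate_samples(a, b, [("A", "p0"), ("B", "p1")], {"g1", "g2"})


def test_marker_shape_warnings():
    # hh-like marker that is NOT terminal-exclusive triggers a warning
    a = _expr({"hh": [9.0, 1.0, 1.0], "x": [1, 2, 3]}, "A")
    b = _expr({"hh": [9.0, 1.0, 1.0], "x": [1, 2, 3]}, "B")
    order = [("A", "p0"), ("B", "p1"), ("A", "p2")]
    with pytest.warns(UserWarning, match="hh-like"):
        integrate_samples(a, b, order, {"hh", "x"}, markers={"hh": "hh"})
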