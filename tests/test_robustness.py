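"""Bit-flip perturbation studies, overlap ratios, morphogen scans."""

import numpy as np
import pytest

from gmnet import (
    BinaryStateTable,
    InvalidParameterError,
    compare_distributions,
    find_attractors,
    morphogen_scan,
    overlap_distribution,
    perturb_table,
    perturbation_study,
    trajectory,
)
from conftest import constant_network, network_from_successor


# ---------------------------------------------------------------------------
# perturb_table


def test_zero_flips_is_identity(wing_table):
    rng = np.random.default_rng(0)
    out = perturb_table(wing_table, 0, rng)
    assert (out.states == wing_table.states).all()


def test_two_flips_have_hamming_distance_two_and_synced_terminal(wing_table):
    rng = np.random.default_rng(1)
    for _ in range(25):
        out = perturb_table(wing_table, 2, rng)
        obs = wing_table.n_observed
        diff = (out.states[:, :obs] != wing_table.states[:, :obs]).sum()
        assert diff == 2
        assert (out.states[:, -1] == out.states[:, -2]).all()


def test_full_flip_is_bitwise_complement():
    table = BinaryStateTable(np.array([[0, 1], [1, 0]]), ["a", "b"], False)
    out = perturb_table(table, 4, np.random.default_rng(0))
    assert (out.states == 1 - table.states).all()


def test_too_many_flips_rejected(wing_table):
    with pytest.raises(InvalidParameterError):
        perturb_table(wing_table, 12 * 13 + 1, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# perturbation study


def test_null_perturbation_always_matches(wing_table):
    res = perturbation_study(wing_table, reps=5, n_flips=0, seed=0)
    assert res.same_attractor_fraction == 100.0
    assert res.comparison[0] == "ks"
    assert res.comparison[1] == 0.0


def test_study_is_reproducible_from_seed(wing_table):
    r1 = perturbation_study(wing_table, reps=30, n_flips=2, seed=11)
    r2 = perturbation_study(wing_table, reps=30, n_flips=2, seed=11)
    assert r1.same_attractor_fraction == r2.same_attractor_fraction
    assert r1.mean_basins == r2.mean_basins
    assert r1.records == r2.records
    np.testing.assert_array_equal(r1.overlap_original, r2.overlap_original)


def test_two_seeds_agree_within_binomial_error(wing_table):
    n = 120
    p1 = perturbation_study(wing_table, reps=n, n_flips=2, seed=1)
    p2 = perturbation_study(wing_table, reps=n, n_flips=2, seed=2)
    f1, f2 = p1.same_attractor_fraction / 100, p2.same_attractor_fraction / 100
    pbar = (f1 + f2) / 2
    se = np.sqrt(2 * pbar * (1 - pbar) / n)
    assert abs(f1 - f2) <= 3.5 * se + 1e-9


def test_agreement_declines_with_flip_count_on_average(wing_table):
    means = []
    for n_flips in (0, 2, 10):
        fracs = [
            perturbation_study(wing_table, reps=25, n_flips=n_flips, seed=s)
            .same_attractor_fraction
            for s in range(3)
        ]
        means.append(np.mean(fracs))
    assert means[0] >= means[1] >= means[2] - 5.0  # small stochastic slack


# ---------------------------------------------------------------------------
# overlap ratios


def _chain_network():
    """m=3 dynamics: 111 -> 011 -> 001 -> 000 (fixed); everything else
    funnels into the chain at specified points."""
    succ = {}
    bits = lambda s: tuple(int(c) for c in s)
    chain = ["111", "110", "100", "000"]  # M1-leftmost renderings
    for a, b in zip(chain, chain[1:]):
        succ[bits(a)] = bits(b)
    succ[bits("000")] = bits("000")
    succ[bits("101")] = bits("110")  # one step off, joins at chain[1]
    succ[bits("011")] = bits("000")  # shares only the attractor
    succ[bits("001")] = bits("000")
    succ[bits("010")] = bits("000")
    return network_from_successor(succ, 3), [bits(s) for s in chain]


def test_overlap_ratio_one_step_off_the_path():
    net, chain = _chain_network()
    d = overlap_distribution(net, chain, (0, 0, 0))
    # trajectory from 101: [101, 110, 100, 000] -> 3 of 4 states on path
    traj = trajectory(net, (1, 0, 1))
    assert len(traj) == 4
    assert (len(traj) - 1) / len(traj) in d.tolist()


def test_overlap_excludes_major_path_states():
    net, chain = _chain_network()
    d = overlap_distribution(net, chain, (0, 0, 0))
    # 8 states - 4 on the path = 4 off-path initial states
    assert d.size == 4


def test_overlap_ratio_attractor_only():
    net, chain = _chain_network()
    d = overlap_distribution(net, chain, (0, 0, 0))
    # trajectory from 011 is [011, 000]: shares only the attractor state
    assert 0.5 in d.tolist()


def test_overlap_requires_true_attractor():
    net, chain = _chain_network()
    with pytest.raises(InvalidParameterError, match="not an attractor"):
        overlap_distribution(net, chain, (1, 1, 1))


# ---------------------------------------------------------------------------
# distribution comparison


def test_identical_distributions_have_zero_statistic():
    d = [0.1, 0.5, 0.9]
    assert compare_distributions(d, d)[1] == 0.0


def test_disjoint_supports_have_statistic_one():
    assert compare_distributions([0.0, 0.1], [0.8, 0.9])[1] == 1.0


def test_ks_statistic_equals_brute_force_ecdf_gap():
    d1, d2 = [0.0, 0.0, 1.0, 1.0], [0.0, 1.0]

    def ecdf_gap(a, b):
        xs = sorted(set(a) | set(b))
        gap = 0.0
        for x in xs:
            fa = sum(v <= x for v in a) / len(a)
            fb = sum(v <= x for v in b) / len(b)
            gap = max(gap, abs(fa - fb))
        return gap

    _, stat, _ = compare_distributions(d1, d2)
    assert stat == pytest.approx(ecdf_gap(d1, d2))


def test_empty_distribution_rejected():
    with pytest.raises(InvalidParameterError):
        compare_distributions([], [0.1])


def test_mannwhitney_alternative_available():
    name, stat, p = compare_distributions([0.1, 0.2], [0.3, 0.4], test="mannwhitney")
    assert name == "mannwhitney" and 0 <= p <= 1


# ---------------------------------------------------------------------------
# morphogen scan


def test_delta_zero_reproduces_baseline_basin_pct(wing_table):
    res = morphogen_scan(wing_table, module_index=8, shifts=[0])
    from gmnet import infer_network

    report = find_attractors(infer_network(wing_table))
    normal = report.containing(trajectory(infer_network(wing_table), wing_table.column(0))[-1])
    assert res.physiological.pct_normal == pytest.approx(normal.basin_pct)


def test_increase_widens_away_from_boundary_decrease_retracts(wing_table):
    res = morphogen_scan(wing_table, module_index=8, shifts=[-1, 0, 1])
    rows = {s.delta: s.module_row for s in res.scenarios}
    assert rows[0] == "0000000111000"  # physiological run at positions 7-9
    assert rows[1] == "0000001111000"  # widened one position anteriorly
    assert rows[-1] == "0000000110000"  # boundary-proximal position switched off


def test_severe_shrink_can_abolish_the_normal_attractor():
    """If the normal attractor requires the module ON upstream, an all-OFF
    row removes it entirely."""
    # M1 constant ON drives M2 ON; normal attractor is (1,1)
    arr = np.array([[1, 1, 1], [0, 1, 1]])
    table = BinaryStateTable(arr, ["p0", "p1", "p2"], False).with_terminal_duplicate()
    with pytest.warns(UserWarning, match="all-OFF"):
        res = morphogen_scan(table, module_index=1, shifts=[-3, 0])
    by_delta = {s.delta: s.pct_normal for s in res.scenarios}
    assert by_delta[0] == 100.0
    assert by_delta[-3] == 0.0


def test_non_contiguous_run_rejected():
    arr = np.array([[1, 0, 1], [0, 1, 1]])
    table = BinaryStateTable(arr, ["p0", "p1", "p2"], False).with_terminal_duplicate()
    with pytest.raises(InvalidParameterError, match="contiguous"):
        morphogen_scan(table, module_index=1, shifts=[0])


def test_fixed_network_mode_runs(wing_table):
    res = morphogen_scan(wing_table, module_index=8, shifts=[-1, 0, 1], mode="fixed")
    assert all(0.0 <= s.pct_normal <= 100.0 for s in res.scenarios)
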