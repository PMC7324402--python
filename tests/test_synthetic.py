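"""Synthetic ground-truth generation and its recovery guarantees."""

import numpy as np
import pytest

from gmnet import (
    DimensionError,
    InvalidParameterError,
    ModuleAssignment,
    binarize_genes,
    expression_from_states,
    infer_network,
    make_random_network,
    module_states,
    parse_rules,
    serialize_rules,
    simulate_state_sequence,
    wing_disc_ground_truth,
    wing_disc_state_table,
)


# ---------------------------------------------------------------------------
# random networks


def test_zero_indegree_networks_are_constant():
    net = make_random_network(3, 0, seed=1)
    assert all(fn.regulators == () for fn in net.functions)
    assert all(fn.truth_table in ((0,), (1,)) for fn in net.functions)


def test_same_seed_same_serialized_rules():
    a = serialize_rules(make_random_network(12, 3, seed=7))
    b = serialize_rules(make_random_network(12, 3, seed=7))
    assert a == b


def test_max_indegree_above_m_rejected():
    with pytest.raises(InvalidParameterError):
        make_random_network(2, 3, seed=0)


def test_stored_truth_tables_match_expression_evaluation():
    import itertools

    net = make_random_network(2, 2, seed=5)
    rendered = parse_rules(serialize_rules(net))
    for bits in itertools.product((0, 1), repeat=2):
        assert net.step(bits) == rendered.step(bits)


# ---------------------------------------------------------------------------
# simulation


def test_constant_zero_simulation():
    from conftest import constant_network

    table = simulate_state_sequence(constant_network(3, 0), (1, 1, 1), steps=2)
    assert [table.column(j) for j in range(3)] == [
        (1, 1, 1), (0, 0, 0), (0, 0, 0)
    ]


def test_identity_simulation_is_constant_in_time():
    from conftest import identity_network

    table = simulate_state_sequence(identity_network(4), (1, 0, 1, 0), steps=3)
    assert all(table.column(j) == (1, 0, 1, 0) for j in range(4))


def test_two_module_constant_network_simulation():
    net = parse_rules("M1, 0\nM2, 1\n")
    table = simulate_state_sequence(net, (1, 0), steps=2)
    assert [table.column(j) for j in range(3)] == [(1, 0), (0, 1), (0, 1)]


def test_simulation_dimension_mismatch():
    net = parse_rules("M1, 0\nM2, 1\n")
    with pytest.raises(DimensionError):
        simulate_state_sequence(net, (1, 0, 1), steps=1)


# ---------------------------------------------------------------------------
# expression generation


def test_noiseless_on_positions_equal_mu_on(wing_table):
    mats = expression_from_states(wing_table, genes_per_module=3, sigma=0.0,
                                  batch_offsets=[1.0], seed=0)
    (mat,) = mats
    obs = wing_table.observed()
    for i in range(1, 13):
        row = mat.values.loc[f"M{i:02d}_g000"].to_numpy()
        on = obs.states[i - 1] == 1
        np.testing.assert_allclose(row[on], 100.0)
        assert (row[~on] < 100.0).all()


def test_batch_offsets_scale_exactly(wing_table):
    m1, m2 = expression_from_states(
        wing_table, genes_per_module=2, sigma=0.0, batch_offsets=[1.0, 2.0], seed=0
    )
    np.testing.assert_allclose(
        m2.values.to_numpy(), 2.0 * m1.values.to_numpy(), rtol=1e-12
    )


def test_all_values_strictly_positive(wing_table):
    mats = expression_from_states(wing_table, genes_per_module=2, sigma=0.5,
                                  batch_offsets=[1.0, 1.6], seed=3)
    for mat in mats:
        assert (mat.values.to_numpy() > 0).all()


def test_mu_ordering_enforced(wing_table):
    with pytest.raises(InvalidParameterError):
        expression_from_states(wing_table, mu_on=1.0, mu_off=2.0)


def test_noiseless_round_trip_recovers_table_exactly(wing_table):
    mats = expression_from_states(wing_table, genes_per_module=5, sigma=0.0,
                                  batch_offsets=[1.0], seed=0)
    assign = ModuleAssignment(
        {f"M{i:02d}_g{g:03d}": i for i in range(1, 13) for g in range(5)}, 12
    )
    rec = module_states(binarize_genes(mats[0]), assign, duplicate_terminal=True)
    assert (rec.states == wing_table.states).all()


def test_noisy_round_trip_error_free_on_most_replicates(wing_table):
    """At sigma = 0.1 * log(mu_on/mu_off), >= 95% of replicates recover
    the module-state table with zero errors."""
    sigma = 0.1 * np.log(100.0 / 1.0)
    assign = ModuleAssignment(
        {f"M{i:02d}_g{g:03d}": i for i in range(1, 13) for g in range(40)}, 12
    )
    ok = 0
    n_reps = 20
    for seed in range(n_reps):
        mats = expression_from_states(wing_table, genes_per_module=40,
                                      sigma=sigma, batch_offsets=[1.0], seed=seed)
        rec = module_states(binarize_genes(mats[0]), assign)
        ok += int((rec.states == wing_table.states).all())
    assert ok >= 0.95 * n_reps


# ---------------------------------------------------------------------------
# full ground truth


def test_ground_truth_network_reproduces_its_table(ground_truth):
    gt = ground_truth
    steps = gt.state_table.n_positions - 1
    sim = simulate_state_sequence(gt.network, gt.state_table.column(0), steps)
    assert (sim.states == gt.state_table.states).all()


def test_ground_truth_modules_nonempty_and_disjoint(ground_truth):
    gt = ground_truth
    seen: dict[str, int] = {}
    for i in range(1, 13):
        genes = gt.assignment.genes_in(i)
        assert genes
        for g in genes:
            assert g not in seen
            seen[g] = i


def test_ground_truth_batches_are_staggered(ground_truth):
    ea, eb = ground_truth.expression_pair
    assert ea.position_labels == ["A1", "A2", "A3", "A4", "A5", "A6"]
    assert eb.position_labels == ["B1", "B2", "B3", "B4", "B5", "B6", "B7"]
    assert ea.batch_label == "A" and eb.batch_label == "B"


def test_markers_validate_under_the_canonical_order(ground_truth_clean):
    """With the correct interleaving the marker shapes raise no warnings;
    a scrambled order breaks the hh-like terminal exclusivity."""
    import warnings as _warnings

    from gmnet import WING_DISC_ORDER, integrate_samples

    gt = ground_truth_clean
    genes = set(gt.assignment.gene_ids) | set(gt.markers.values())
    with _warnings.catch_warnings():
        _warnings.simplefilter("error")
        integrate_samples(
            *gt.expression_pair, WING_DISC_ORDER, genes, markers=gt.markers
        )
    scrambled = ["B7"] + WING_DISC_ORDER[:-1]
    with pytest.warns(UserWarning, match="hh-like"):
        integrate_samples(
            *gt.expression_pair, scrambled, genes, markers=gt.markers
        )


def test_inference_on_simulated_sequence_is_self_consistent():
    """Inferred dynamics always reproduces its own training sequence."""
    net = make_random_network(6, 3, seed=9)
    table = simulate_state_sequence(net, (1, 0, 1, 0, 1, 0), steps=8)
    inferred = infer_network(table)
    sim = simulate_state_sequence(inferred, (1, 0, 1, 0, 1, 0), steps=8)
    assert (sim.states == table.states).all()
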