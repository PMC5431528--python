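"""Migration graphs: count tables, covariance, NJ trees, stopping rule, consensus."""

import numpy as np
import pytest

from ancestra import synthgen
from ancestra._tree import parse_newick
from ancestra.migration import (
    AlleleCountTable,
    MigrationGraphModel,
    ancestry_allele_counts,
    bootstrap_trees,
    consensus_tree,
    fit_tree,
    frequency_covariance,
    replicate_runs,
    stopping_rule,
)


def _counts_from_model(K=4, m=3000, drift=0.08, N=200, seed=1):
    model = synthgen.simulate_frequency_tree(K, m, drift=drift, seed=seed)
    rng = np.random.default_rng(seed + 1000)
    alt = rng.binomial(N, model.ancestral_freqs)
    return (
        AlleleCountTable(model.ancestry_labels, np.full(K, N), alt, N - alt),
        model,
    )


def test_allele_count_table_validation():
    with pytest.raises(ValueError):
        AlleleCountTable(["a"], [10], [[4]], [[5]])  # alt + ref != N
    tab = AlleleCountTable(["a", "b"], [10, 20], [[4], [10]], [[6], [10]])
    np.testing.assert_allclose(tab.frequencies(), [[0.4], [0.5]])


def test_count_table_write_roundtrip(tmp_path):
    tab = AlleleCountTable(["a", "b"], [10, 20], [[4, 0], [10, 20]], [[6, 10], [10, 0]])
    p = tmp_path / "tm.txt.gz"
    tab.write(p)
    import gzip

    lines = gzip.open(p, "rt").read().strip().split("\n")
    assert lines[0] == "a b"
    assert lines[1] == "6,4 10,10"


def test_ancestry_allele_counts_conserves_totals():
    rng = np.random.default_rng(2)
    Q = rng.dirichlet(np.ones(3), size=50)
    F = rng.uniform(0.05, 0.95, size=(3, 40))
    tab = ancestry_allele_counts(Q, F)
    np.testing.assert_array_equal(tab.N, np.round(2 * Q.sum(axis=0)))
    assert np.all(tab.alt + tab.ref == tab.N[:, None])
    # recovered frequencies close to F up to rounding
    assert np.abs(tab.frequencies() - F).max() < 0.5 / tab.N.min() + 1e-9


def test_frequency_covariance_noise_correction():
    # two independent populations at the same depth: off-diagonal negative
    # (centering), diagonal reflects drift variance not sampling noise
    tab, model = _counts_from_model(K=3, m=20000, drift=0.05, N=400, seed=3)
    W, se = frequency_covariance(tab)
    assert W.shape == (3, 3) and np.allclose(W, W.T)
    assert np.all(se > 0)
    # sampling-noise correction: W from N=40 should match W from N=400
    tab2, _ = _counts_from_model(K=3, m=20000, drift=0.05, N=40, seed=3)
    W2, _ = frequency_covariance(tab2)
    assert np.abs(W2 - W).max() < 0.01


def test_fit_tree_four_leaf_oracle():
    # additive distances with (a,b | c,d) split
    labels = ["a", "b", "c", "d"]
    # covariance whose implied distances are additive on ((a,b),(c,d))
    W = np.array(
        [
            [0.30, 0.20, 0.0, 0.0],
            [0.20, 0.32, 0.0, 0.0],
            [0.0, 0.0, 0.28, 0.18],
            [0.0, 0.0, 0.18, 0.26],
        ]
    )
    tree = fit_tree(W, labels, root_label="a")
    bip = {tuple(sorted(b)) for b in tree.bipartitions()}
    assert ("a", "b") in bip or ("c", "d") in bip
    assert sorted(tree.leaf_names()) == labels
    # root is on a's pendant edge: 'a' is a child of the root
    assert "a" in [c.name for c in tree.children]


def test_fit_tree_recovers_simulated_topology():
    tab, model = _counts_from_model(K=5, m=10000, drift=0.08, N=300, seed=4)
    W, _ = frequency_covariance(tab)
    tree = fit_tree(W, tab.labels, root_label="A1")
    true_bip = {b for b in model.tree.bipartitions() if 1 < len(b) < 4}
    got_bip = {b for b in tree.bipartitions() if 1 < len(b) < 4}
    assert true_bip == got_bip


def test_stopping_rule_cases():
    assert stopping_rule([-120.4, -35.2, 2.1, 5.7]) == 1
    assert stopping_rule([-10.0, -5.0, -1.0]) == 2
    with pytest.warns(UserWarning):
        assert stopping_rule([3.0, 5.0]) == 0
    assert stopping_rule([-1.0, 4.0]) == 0
    with pytest.raises(ValueError):
        stopping_rule([])


def test_graph_fit_plain_tree(small_graph_inputs):
    model, truth_model = small_graph_inputs
    res = model.fit(m_events=0, root_label="A1", order_seed=0)
    assert res.m_events == 0 and res.migration_edges == []
    assert sorted(res.tree.leaf_names()) == sorted(model.labels)
    assert np.isfinite(res.loglik)
    assert "Migration graph fit" in res.summary()


def test_graph_fit_recovers_planted_edge(small_graph_inputs_migrated):
    model, (src, tgt, w) = small_graph_inputs_migrated
    res = model.fit(m_events=1, root_label="A1", order_seed=0)
    assert len(res.migration_edges) == 1
    s_clade, t_clade, w_hat = res.migration_edges[0]
    assert tgt in t_clade
    assert abs(w_hat - w) < 0.15


def test_fit_range_stopping(small_graph_inputs_migrated):
    model, _ = small_graph_inputs_migrated
    results, chosen = model.fit_range(m_max=1, root_label="A1", n_orders=3, seed=5)
    assert len(results) == 2
    lls = [r["best"].loglik for r in results]
    assert chosen in (0, 1)
    if lls[0] <= 0 < lls[1]:
        assert chosen == 0


def test_replicate_runs_outcomes(small_graph_inputs):
    model, _ = small_graph_inputs
    summary = replicate_runs(model, 0, root_label="A1", n_orders=5, seed=6)
    assert summary["runs"] == 5
    assert sum(summary["outcome_percentages"].values()) == pytest.approx(100.0)
    assert summary["best"] is not None


def test_bootstrap_consensus(small_graph_inputs):
    model, truth_model = small_graph_inputs
    trees = bootstrap_trees(model.counts, "A1", n_boot=15, seed=7)
    cons = consensus_tree(trees)
    assert sorted(cons.tree.leaf_names()) == sorted(model.labels)
    for clade, pct in cons.support.items():
        assert 50.0 < pct <= 100.0


def test_consensus_tree_hand_instance():
    t1 = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    t2 = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    t3 = parse_newick("((a:1,c:1):1,(b:1,d:1):1);")
    cons = consensus_tree([t1, t2, t3])
    assert cons.support == {("a", "b"): pytest.approx(200 / 3), ("c", "d"): pytest.approx(200 / 3)}
    with pytest.raises(ValueError):
        consensus_tree([t1])


def test_migration_results_write(tmp_path, small_graph_inputs):
    model, _ = small_graph_inputs
    res = model.fit(m_events=0, root_label="A1", order_seed=1)
    res.write(tmp_path / "graph")
    assert (tmp_path / "graph.nwk").read_text().strip().endswith(";")
    assert "source_clade" in (tmp_path / "graph.migrations.tsv").read_text()


@pytest.fixture(scope="module")
def small_graph_inputs():
    tab, model = _counts_from_model(K=4, m=4000, drift=0.08, N=250, seed=8)
    return MigrationGraphModel(tab), model


@pytest.fixture(scope="module")
def small_graph_inputs_migrated():
    model = synthgen.simulate_frequency_tree(4, 6000, drift=0.08, seed=9)
    planted = synthgen.plant_migration(model, "A2", "A4", 0.3)
    rng = np.random.default_rng(10)
    N = 300
    alt = rng.binomial(N, planted.ancestral_freqs)
    tab = AlleleCountTable(planted.ancestry_labels, np.full(4, N), alt, N - alt)
    return MigrationGraphModel(tab), ("A2", "A4", 0.3)
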