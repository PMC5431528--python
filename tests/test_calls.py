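"""Ancestry calling: intervals, zeroing, sample averaging, mixed stats."""

import numpy as np
import pandas as pd
import pytest

from ancestra import calls
from ancestra.admixture import BootstrapEnsemble
from ancestra.calls import (
    designate_exemplars,
    individual_intervals,
    mixed_ancestry_stats,
    sample_average_ancestry,
    zero_and_renormalize,
)


class _FakeModel:
    def __init__(self, ids):
        self.individual_ids = ids


class _FakeRef:
    def __init__(self, ids):
        self.model = _FakeModel(ids)


def _ens(reps, ids=None):
    reps = np.asarray(reps, float)
    ids = ids or [f"i{j + 1}" for j in range(reps.shape[1])]
    return BootstrapEnsemble(reps, _FakeRef(ids))


def test_individual_intervals_hand_values():
    # two replicates {0.4, 0.6}: mean 0.5, sd (ddof=1) = 0.1414..,
    # CI = 0.5 +/- 1.96 * 0.1414 = [0.2228, 0.7772]
    reps = np.array([[[0.4, 0.6]], [[0.6, 0.4]]])
    means, ses, cis = individual_intervals(_ens(reps))
    assert means[0, 0] == pytest.approx(0.5)
    assert ses[0, 0] == pytest.approx(np.sqrt(0.02), abs=1e-12)
    assert cis[0, 0, 0] == pytest.approx(0.5 - 1.959963984540054 * np.sqrt(0.02), abs=1e-9)
    assert cis[0, 0, 1] == pytest.approx(0.5 + 1.959963984540054 * np.sqrt(0.02), abs=1e-9)


def test_intervals_truncated_to_unit():
    reps = np.array([[[0.98, 0.02]], [[0.92, 0.08]]])
    _, _, cis = individual_intervals(_ens(reps))
    assert np.all(cis >= 0) and np.all(cis <= 1)
    assert cis[0, 0, 1] == 1.0
    assert cis[0, 1, 0] == 0.0


def test_zero_and_renormalize_hand_values():
    means = np.array([[0.6, 0.3, 0.1]])
    cis = np.array([[[0.4, 0.8], [0.1, 0.5], [0.0, 0.25]]])
    out, degen = zero_and_renormalize(means, cis)
    np.testing.assert_allclose(out, [[2 / 3, 1 / 3, 0.0]])
    assert not degen[0]
    assert out.sum() == pytest.approx(1.0)


def test_zero_and_renormalize_degenerate_row():
    means = np.array([[0.5, 0.5]])
    cis = np.zeros((1, 2, 2))
    with pytest.warns(UserWarning, match="zeroed everywhere"):
        out, degen = zero_and_renormalize(means, cis)
    np.testing.assert_allclose(out, means)
    assert degen[0]


def test_zeroing_keeps_rows_normalized(small_ensemble):
    means, _, cis = individual_intervals(small_ensemble)
    out, _ = zero_and_renormalize(means, cis)
    np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(out >= 0)


def test_sample_average_weights_and_se():
    # two individuals in one sample, equal SEs: weighted mean = plain mean
    reps = np.array(
        [[[0.2, 0.8], [0.4, 0.6]], [[0.3, 0.7], [0.5, 0.5]]]
    )  # B=2, n=2, K=2
    ens = _ens(reps, ids=["a", "b"])
    props, se = sample_average_ancestry(ens, {"a": "S", "b": "S"})
    assert props.loc["S", "comp1"] == pytest.approx(0.35)
    assert props.loc["S", "comp2"] == pytest.approx(0.65)
    assert (se.values > 0).all()


def test_sample_average_zero_variance_falls_back_to_mean():
    reps = np.array([[[0.2, 0.8], [0.4, 0.6]], [[0.2, 0.8], [0.4, 0.6]]])
    ens = _ens(reps, ids=["a", "b"])
    props, se = sample_average_ancestry(ens, {"a": "S", "b": "S"})
    assert props.loc["S", "comp1"] == pytest.approx(0.3)
    assert se.loc["S", "comp1"] == 0.0


def test_sample_average_requires_complete_map(small_ensemble):
    with pytest.raises(KeyError):
        sample_average_ancestry(small_ensemble, {"nobody": "S"})


def test_designate_exemplars_ties_break_lexicographically():
    props = pd.DataFrame(
        [[0.9, 0.1], [0.9, 0.1], [0.2, 0.8]],
        index=["S_b", "S_a", "S_c"],
        columns=["comp1", "comp2"],
    )
    ex = designate_exemplars(props)
    assert ex == {"comp1": "S_a", "comp2": "S_c"}


def test_call_ancestry_end_to_end(small_truth, small_ensemble):
    _, truth = small_truth
    called = calls.call_ancestry(small_ensemble, truth.sample_map)
    assert np.allclose(called.individual_props.values.sum(axis=1), 1.0)
    assert np.allclose(called.sample_props.values.sum(axis=1), 1.0)
    assert list(called.sample_props.index) == ["S1", "S2", "S3"]
    # anchored design: each sample's dominant called component is unique
    dom = called.sample_props.values.argmax(axis=1)
    assert len(set(dom)) == 3


def test_mixed_ancestry_stats_counts(small_truth, small_ensemble):
    _, truth = small_truth
    called = calls.call_ancestry(small_ensemble, truth.sample_map)
    stats = mixed_ancestry_stats(called)
    assert 0.0 <= stats["pct_mixed_individuals"] <= 100.0
    lo, hi = stats["individual_count_interval"]
    assert 1 <= lo <= stats["median_ancestries_per_individual"] <= hi <= 3
    assert stats["individual_counts"].shape == (60,)


def test_called_write(tmp_path, small_truth, small_ensemble):
    _, truth = small_truth
    called = calls.call_ancestry(small_ensemble, truth.sample_map)
    called.write(tmp_path / "called")
    assert (tmp_path / "called.individuals.tsv").exists()
    assert (tmp_path / "called.samples.tsv").exists()
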