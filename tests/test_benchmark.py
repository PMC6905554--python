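"""Benchmark construction: differential expression against hand-computed
oracles, threshold labeling with strict boundaries, outlier screening,
min-max scaling, splitting, and positives-only cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ocgene as og


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def test_de_toy_gene_matches_hand_computation(toy_expression):
    """Disease (8,9,10) vs healthy (2,3,4): logFC = 6; Welch t = 6/sqrt(2/3)
    with 4 degrees of freedom (equal variances, equal n)."""
    de = og.differential_expression(toy_expression)
    assert de.loc["gA", "log_fc"] == pytest.approx(6.0)
    t_hand = 6.0 / np.sqrt(2.0 / 3.0)
    p_hand = 2.0 * stats.t.sf(t_hand, df=4)
    assert de.loc["gA", "p_raw"] == pytest.approx(p_hand, rel=1e-10)
    # flat gene: null case
    assert de.loc["gB", "log_fc"] == 0.0
    assert de.loc["gB", "p_raw"] == 1.0
    assert (de["p_adj"] >= de["p_raw"] - 1e-15).all()


def test_de_requires_two_samples_per_condition(toy_expression):
    values = toy_expression.values[["d1", "h1", "h2"]]
    cond = toy_expression.condition[["d1", "h1", "h2"]]
    with pytest.raises(og.BenchmarkError, match="2 samples"):
        og.differential_expression(og.ExpressionMatrix(values=values, condition=cond))


def test_bh_adjustment_matches_hand_stepup():
    """The adjusted p-values of the pipeline equal the hand-computed
    Benjamini-Hochberg step-up of its own raw p-values; e.g. raw
    (0.01, 0.02, 0.03, 0.04) with m=4 all adjust to 0.04."""

    def bh_hand(p):
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    np.testing.assert_allclose(
        bh_hand([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    rng = np.random.default_rng(3)
    vals = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(40, 8)),
        index=[f"g{i}" for i in range(40)],
        columns=[f"s{i}" for i in range(8)],
    )
    vals.iloc[:5, :4] += 2.0  # a few shifted genes for a p-value spread
    cond = pd.Series(["disease"] * 4 + ["healthy"] * 4, index=vals.columns)
    de = og.differential_expression(og.ExpressionMatrix(values=vals, condition=cond))
    np.testing.assert_allclose(de["p_adj"], bh_hand(de["p_raw"]), atol=1e-12)


def test_duplicate_gene_ids_rejected(toy_expression):
    vals = toy_expression.values.copy()
    vals.index = ["gA", "gA"]
    with pytest.raises(og.BenchmarkError, match="duplicate"):
        og.ExpressionMatrix(values=vals, condition=toy_expression.condition)


# ---------------------------------------------------------------------------
# positive/unlabeled labeling
# ---------------------------------------------------------------------------


def test_select_positive_unlabeled_strict_boundaries():
    de = pd.DataFrame(
        {
            "log_fc": [1.5, -1.2, 1.0, 0.2, 2.0],
            "p_raw": [0.001] * 5,
            "p_adj": [0.01, 0.03, 0.01, 0.01, 0.05],
        },
        index=list("abcde"),
    )
    feats = pd.DataFrame(np.zeros((5, 3)), index=list("abcde"))
    bench = og.select_positive_unlabeled(de, feats)
    # a: |1.5|>1 & 0.01<0.05 -> positive; b: negative branch; c: logFC == 1
    # excluded; d: small logFC; e: p_adj == 0.05 excluded
    assert bench.positives == ["a", "b"]
    assert bench.unlabeled == ["c", "d", "e"]
    assert set(bench.positives) | set(bench.unlabeled) == set(de.index)


def test_select_unlabeled_cap_keeps_least_differential():
    de = pd.DataFrame(
        {
            "log_fc": [3.0, 0.1, -0.5, 0.9, 0.3],
            "p_raw": [0.001] * 5,
            "p_adj": [0.001] * 5,
        },
        index=list("abcde"),
    )
    feats = pd.DataFrame(np.zeros((5, 2)), index=list("abcde"))
    bench = og.select_positive_unlabeled(de, feats, unlabeled_cap=2)
    assert bench.positives == ["a"]
    assert bench.unlabeled == ["b", "e"]  # smallest |log_fc|, input order


def test_benchmark_disjointness_enforced():
    feats = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"])
    with pytest.raises(og.BenchmarkError, match="overlap"):
        og.PUBenchmark(positives=["a"], unlabeled=["a", "b"], features=feats)


# ---------------------------------------------------------------------------
# outlier removal
# ---------------------------------------------------------------------------


def test_remove_outliers_drops_planted_extreme():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(50, 4)), index=[f"g{i}" for i in range(50)])
    X.iloc[7, 2] = 500.0  # far beyond any plausible MAD scale
    reduced, removed = og.remove_outliers(X, z_threshold=4.0)
    assert removed == ["g7"]
    assert len(reduced) == 49


def test_remove_outliers_retains_homogeneous_gaussian():
    keep = []
    for seed in range(10):
        X = pd.DataFrame(np.random.default_rng(seed).normal(size=(200, 5)))
        reduced, _ = og.remove_outliers(X, z_threshold=4.0)
        keep.append(len(reduced) / 200)
    assert np.mean(keep) >= 0.97


def test_remove_outliers_degenerate_scale_guard():
    X = pd.DataFrame(np.ones((5, 3)))
    reduced, removed = og.remove_outliers(X)
    assert removed == [] and len(reduced) == 5
    with pytest.raises(og.BenchmarkError, match="3 rows"):
        og.remove_outliers(X.iloc[:2])


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


def test_minmax_scale_examples():
    train = pd.DataFrame({"f1": [2.0, 4.0, 6.0], "f2": [5.0, 5.0, 5.0],
                          "f3": [0.0, 1.0, 0.5]})
    scaled, params = og.minmax_scale(train)
    np.testing.assert_allclose(scaled["f1"], [0.0, 0.5, 1.0])
    np.testing.assert_allclose(scaled["f2"], [0.0, 0.0, 0.0])  # constant -> 0
    np.testing.assert_allclose(scaled["f3"], [0.0, 1.0, 0.5])  # already [0,1]


def test_minmax_scale_test_set_uses_train_params_and_clips():
    train = pd.DataFrame({"f": [0.0, 10.0]})
    test = pd.DataFrame({"f": [-5.0, 5.0, 20.0]})
    train_s, test_s, params = og.minmax_scale(train, test)
    np.testing.assert_allclose(test_s["f"], [0.0, 0.5, 1.0])


def test_scaling_idempotent_on_train():
    train = pd.DataFrame(np.random.default_rng(1).normal(size=(20, 3)))
    scaled, params = og.minmax_scale(train)
    again = og.apply_scale(og.ScaleParams(x_min=scaled.min(), x_max=scaled.max()), scaled)
    pd.testing.assert_frame_equal(scaled, again)


# ---------------------------------------------------------------------------
# split and cross-validation
# ---------------------------------------------------------------------------


def _dummy_benchmark(n_pos=100, n_unl=50, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n_pos)] + [f"u{i}" for i in range(n_unl)]
    feats = pd.DataFrame(rng.normal(size=(n_pos + n_unl, 4)), index=ids)
    return og.PUBenchmark(
        positives=ids[:n_pos], unlabeled=ids[n_pos:], features=feats
    )


def test_split_sizes_and_pools():
    bench = _dummy_benchmark(n_pos=1000, n_unl=100)
    train, test, unl = og.split_train_test(bench, og.SplitSpec(train_fraction=0.7, seed=3))
    assert len(train) == 700 and len(test) == 300
    assert not set(train) & set(test)
    assert unl == bench.unlabeled  # unlabeled never enters training


def test_split_determinism_and_seed_sensitivity():
    bench = _dummy_benchmark()
    s1 = og.split_train_test(bench, og.SplitSpec(seed=5))
    s2 = og.split_train_test(bench, og.SplitSpec(seed=5))
    assert s1 == s2
    diff = [og.split_train_test(bench, og.SplitSpec(seed=s))[0] != s1[0]
            for s in range(6, 12)]
    assert all(diff)


def test_split_requires_two_positives():
    bench = _dummy_benchmark(n_pos=2, n_unl=5)
    og.split_train_test(bench, og.SplitSpec(seed=0))  # boundary works
    one = og.PUBenchmark(positives=bench.positives[:1], unlabeled=bench.unlabeled,
                         features=bench.features)
    with pytest.raises(og.BenchmarkError, match="2 positives"):
        og.split_train_test(one, og.SplitSpec())


def test_split_spec_validation():
    with pytest.raises(og.BenchmarkError):
        og.SplitSpec(train_fraction=1.0)
    with pytest.raises(og.BenchmarkError):
        og.SplitSpec(cv_folds=1)


def test_cross_validation_partition_and_loo():
    rng = np.random.default_rng(2)
    feats = pd.DataFrame(rng.normal(loc=5.0, size=(20, 3)))
    # partition property: every index lands in exactly one validation fold
    n = len(feats)
    order = np.random.default_rng(4).permutation(n)
    folds = np.array_split(order, 5)
    assert sorted(np.concatenate(folds).tolist()) == list(range(n))
    recalls, mean, sd = og.cross_validate(feats, folds=20, seed=4)  # leave-one-out
    assert len(recalls) == 20
    assert set(np.round(recalls, 6)) <= {0.0, 1.0}
    with pytest.raises(og.BenchmarkError, match="folds"):
        og.cross_validate(feats, folds=21)


def test_cross_validation_clean_data_recall():
    """On a tight clean cluster, mean CV recall approaches 1 - nu."""
    rng = np.random.default_rng(6)
    feats = pd.DataFrame(rng.normal(loc=3.0, scale=0.1, size=(60, 4)))
    _, mean, _ = og.cross_validate(feats, nu=0.1, folds=10, seed=1)
    assert mean >= 1.0 - 0.1 - 0.1


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------


def test_expression_roundtrip(tmp_path, toy_expression):
    og.write_expression(toy_expression, tmp_path / "m.csv", tmp_path / "c.csv")
    back = og.read_expression(tmp_path / "m.csv", tmp_path / "c.csv")
    pd.testing.assert_frame_equal(back.values, toy_expression.values)
    assert back.disease_samples == toy_expression.disease_samples


def test_supplementary_layout_roundtrip(tmp_path):
    bench = _dummy_benchmark(n_pos=8, n_unl=12)
    og.write_benchmark_supplementary(bench, tmp_path / "pos.csv", tmp_path / "full.csv")
    back = og.read_benchmark_supplementary(tmp_path / "pos.csv", tmp_path / "full.csv")
    assert back.positives == bench.positives
    assert back.unlabeled == bench.unlabeled
    np.testing.assert_allclose(back.features.to_numpy(), bench.features.to_numpy())


def test_missing_condition_map_is_explicit(tmp_path, toy_expression):
    og.write_expression(toy_expression, tmp_path / "m.csv", tmp_path / "c.csv")
    with pytest.raises(og.BenchmarkError, match="condition"):
        og.read_expression(tmp_path / "m.csv", None)
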