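"""SAM differential expression, signature construction and scoring."""

import numpy as np
import pandas as pd
import pytest

from radgen.signature import (SAM, GeneSignature, build_signature,
                              crosstab_signature_vs_cluster, printed_percent,
                              score_signature)
from radgen.synthetic import ExpressionSpec, generate_expression


def _null_matrix(n_genes=300, n1=12, n2=12, seed=0):
    labels = ["1"] * n1 + ["2b"] * n2
    mat, _ = generate_expression(
        ExpressionSpec(n_genes=n_genes, n_up=0, n_down=0, effect_size=0.0,
                       seed=seed), labels)
    return mat, np.array(labels)


# ---------------------------------------------------------------------------
# two-class SAM
# ---------------------------------------------------------------------------

def test_two_class_antisymmetry_under_label_swap():
    mat, labels = _null_matrix(seed=1)
    a = SAM(mat, labels, groups=("1", "2b")).fit(50, seed=0)
    b = SAM(mat, labels, groups=("2b", "1")).fit(50, seed=0)
    np.testing.assert_allclose(a.d, -b.d, atol=1e-12)


def test_two_class_sign_convention():
    mat, labels = _null_matrix(seed=2)
    g = mat.index[0]
    mat.loc[g, labels == "2b"] += 10.0  # higher in the aggressive group
    res = SAM(mat, labels, groups=("1", "2b")).fit(50, seed=0)
    assert res.d[list(res.gene_ids).index(g)] > 0


def test_null_calls_near_zero():
    mat, labels = _null_matrix(n_genes=500, seed=3)
    res = SAM(mat, labels, groups=("1", "2b")).fit(100, seed=0)
    info = res.select_delta(0.05)
    assert info["n_called"] <= 5  # <= 1% of genes


def test_strong_effect_called():
    labels = ["1"] * 15 + ["2b"] * 15
    spec = ExpressionSpec(n_genes=400, n_up=3, n_down=8, effect_size=3.0, seed=4)
    mat, truth = generate_expression(spec, labels)
    res = SAM(mat, labels, groups=("1", "2b")).fit(100, seed=0)
    info = res.select_delta(0.05)
    assert set(truth["up"]) <= set(info["up"])
    assert set(truth["down"]) <= set(info["down"])


def test_calls_monotone_in_delta():
    mat, labels = _null_matrix(seed=5)
    res = SAM(mat, labels, groups=("1", "2b")).fit(50, seed=0)
    n_prev = None
    for delta in (0.01, 0.1, 0.5, 1.0, 2.0):
        n = res.call_genes(delta)["n_called"]
        if n_prev is not None:
            assert n <= n_prev
        n_prev = n


def test_sam_input_validation():
    mat, labels = _null_matrix()
    with pytest.raises(ValueError):
        SAM(mat, labels[:-1])
    with pytest.raises(ValueError):
        SAM(mat, ["1"] * mat.shape[1])  # single group
    bad = mat.copy()
    bad.iloc[0, 0] = np.nan
    with pytest.raises(ValueError):
        SAM(bad, labels)


def test_sam_deterministic_given_seed():
    mat, labels = _null_matrix(seed=6)
    a = SAM(mat, labels, groups=("1", "2b")).fit(50, seed=9)
    b = SAM(mat, labels, groups=("1", "2b")).fit(50, seed=9)
    np.testing.assert_array_equal(a.perm_sorted, b.perm_sorted)
    assert a.s0 == b.s0


# ---------------------------------------------------------------------------
# multiclass SAM
# ---------------------------------------------------------------------------

def test_multiclass_positive_statistic_and_detection():
    labels = ["1"] * 12 + ["2a"] * 12 + ["2b"] * 12
    spec = ExpressionSpec(n_genes=300, n_up=3, n_down=8, effect_size=3.0, seed=7)
    mat, truth = generate_expression(spec, labels)
    res = SAM(mat, labels).fit(100, seed=0)
    assert (res.d >= 0).all()
    info = res.select_delta(0.05)
    called = set(info["up"]) | set(info["down"])
    assert set(truth["up"]) | set(truth["down"]) <= called


def test_multiclass_needs_two_samples_per_group():
    mat, labels = _null_matrix(n1=10, n2=10)
    labels = labels.copy()
    labels[0] = "2a"  # singleton group
    with pytest.raises(ValueError):
        SAM(mat, labels)


# ---------------------------------------------------------------------------
# signature construction
# ---------------------------------------------------------------------------

def test_build_signature_intersection_and_direction():
    labels = ["1"] * 15 + ["2a"] * 12 + ["2b"] * 15
    spec = ExpressionSpec(n_genes=400, n_up=3, n_down=8, effect_size=3.0, seed=8)
    mat, truth = generate_expression(spec, labels)
    sub = [l in ("1", "2b") for l in labels]
    res2 = SAM(mat.loc[:, sub], np.array(labels)[sub], groups=("1", "2b")).fit(100, seed=0)
    res3 = SAM(mat, labels).fit(100, seed=1)
    sig = build_signature(res2, res3, 0.05)
    assert set(truth["up"]) <= set(sig.up)
    assert set(truth["down"]) <= set(sig.down)
    assert not (set(sig.up) & set(sig.down))
    # ordered by decreasing |d| of the two-class run
    gid = list(res2.gene_ids)
    d = np.abs(np.asarray(res2.d))
    for genes in (sig.up, sig.down):
        mags = [d[gid.index(g)] for g in genes]
        assert all(a >= b for a, b in zip(mags, mags[1:]))


def test_build_signature_disjoint_flagged_empty():
    mat, labels = _null_matrix(n_genes=200, seed=9)
    res = SAM(mat, labels, groups=("1", "2b")).fit(50, seed=0)
    res_b = SAM(mat, list(labels[::-1]), groups=("1", "2b")).fit(50, seed=1)
    with pytest.warns(UserWarning):
        sig = build_signature(res, res_b, 1e-9)
    assert sig.empty
    assert sig.up == [] and sig.down == []


def test_genes_called_only_in_one_run_excluded():
    labels = ["1"] * 15 + ["2a"] * 12 + ["2b"] * 15
    spec = ExpressionSpec(n_genes=400, n_up=3, n_down=8, effect_size=3.0, seed=10)
    mat, truth = generate_expression(spec, labels)
    # shift one extra gene only within group 2a: multiclass sees it,
    # the 1-vs-2b two-class run does not
    extra = [g for g in mat.index if g not in truth["up"] + truth["down"]][0]
    mat.loc[extra, np.array(labels) == "2a"] += 8.0
    sub = [l in ("1", "2b") for l in labels]
    res2 = SAM(mat.loc[:, sub], np.array(labels)[sub], groups=("1", "2b")).fit(100, seed=0)
    res3 = SAM(mat, labels).fit(100, seed=1)
    called3 = res3.select_delta(0.05)
    assert extra in set(called3["up"]) | set(called3["down"])
    sig = build_signature(res2, res3, 0.05)
    assert extra not in set(sig.up) | set(sig.down)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _toy_signature():
    up = [f"u{i}" for i in range(3)]
    down = [f"d{i}" for i in range(8)]
    return GeneSignature(up=up, down=down)


def test_score_all_plus_one_z_is_minus_five():
    sig = _toy_signature()
    rng = np.random.default_rng(0)
    base = rng.normal(0, 1, (11, 40))
    mat = pd.DataFrame(base, index=sig.up + sig.down,
                       columns=[f"s{i}" for i in range(40)])
    # engineer sample 0 to sit exactly +1 cohort-SD above the cohort mean of
    # every gene: solve z0(x0) = 1 per gene (z0 is monotone increasing in x0)
    from scipy.optimize import brentq

    for g in mat.index:
        x = mat.loc[g].to_numpy().copy()

        def z0(x0):
            x[0] = x0
            return (x0 - x.mean()) / x.std() - 1.0

        x[0] = brentq(z0, -100.0, 100.0, xtol=1e-14)
        mat.loc[g] = x
    scores = score_signature(mat, sig)
    assert scores.scores.iloc[0] == pytest.approx(3 - 8, abs=1e-8)


def test_score_antisymmetry_under_negation():
    sig = _toy_signature()
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(rng.normal(0, 1, (11, 30)), index=sig.up + sig.down,
                       columns=[f"s{i}" for i in range(30)])
    a = score_signature(mat, sig)
    b = score_signature(-mat, sig)
    np.testing.assert_allclose(a.scores.to_numpy(), -b.scores.to_numpy(), atol=1e-10)


def test_score_invariance_gene_order_and_extra_genes():
    sig = _toy_signature()
    rng = np.random.default_rng(2)
    mat = pd.DataFrame(rng.normal(0, 1, (11, 20)), index=sig.up + sig.down,
                       columns=[f"s{i}" for i in range(20)])
    a = score_signature(mat, sig)
    shuffled = mat.sample(frac=1.0, random_state=3)
    extra = pd.DataFrame(rng.normal(5, 2, (6, 20)),
                         index=[f"x{i}" for i in range(6)], columns=mat.columns)
    b = score_signature(pd.concat([extra, shuffled]), sig)
    np.testing.assert_allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-12)
    pd.testing.assert_series_equal(a.classes, b.classes)


def test_score_classes_straddle_mean():
    sig = _toy_signature()
    rng = np.random.default_rng(3)
    mat = pd.DataFrame(rng.normal(0, 1, (11, 25)), index=sig.up + sig.down,
                       columns=[f"s{i}" for i in range(25)])
    s = score_signature(mat, sig)
    assert (s.classes == "high").sum() > 0 and (s.classes == "low").sum() > 0
    assert ((s.scores > s.cutoff) == (s.classes == "high")).all()
    assert s.cutoff == pytest.approx(s.scores.mean())


def test_score_missing_genes_dropped_with_warning():
    sig = _toy_signature()
    rng = np.random.default_rng(4)
    mat = pd.DataFrame(rng.normal(0, 1, (10, 15)),
                       index=sig.up + sig.down[:-1],  # one down-gene missing
                       columns=[f"s{i}" for i in range(15)])
    with pytest.warns(UserWarning):
        s = score_signature(mat, sig)
    assert s.dropped_genes == [sig.down[-1]]


def test_score_all_genes_missing_errors():
    sig = _toy_signature()
    mat = pd.DataFrame(np.zeros((3, 5)), index=["a", "b", "c"],
                       columns=[f"s{i}" for i in range(5)])
    with pytest.raises(ValueError):
        score_signature(mat, sig)


# ---------------------------------------------------------------------------
# printed percentages + crosstab
# ---------------------------------------------------------------------------

def test_printed_percent_reproduces_paper_values():
    assert printed_percent(16, 19) == 84
    assert printed_percent(11, 32) == 34
    assert printed_percent(48, 97) == 49
    assert printed_percent(12, 135) == 9


def test_crosstab_counts_and_percentages():
    ids = [f"s{i}" for i in range(51)]
    classes = pd.Series(["low"] * 16 + ["high"] * 3 + ["low"] * 11 + ["high"] * 21,
                        index=ids)
    clusters = pd.Series(["1"] * 19 + ["2a"] * 16 + ["2b"] * 16, index=ids)
    out = crosstab_signature_vs_cluster(classes, clusters)
    assert out["table"].loc["low", "1"] == 16
    assert out["table"].loc["high", "1"] == 3
    assert out["table"].loc["low", "2a/b"] == 11
    assert out["table"].loc["high", "2a/b"] == 21
    assert out["cluster1_low_pct"] == 84
    assert out["cluster2_low_pct"] == 34


def test_crosstab_unmatched_ids_error():
    classes = pd.Series(["low", "high"], index=["a", "b"])
    clusters = pd.Series(["1", "2a", "2b"], index=["a", "b", "c"])
    with pytest.raises(ValueError, match="c"):
        crosstab_signature_vs_cluster(classes, clusters)
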