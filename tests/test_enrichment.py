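"""ssGSEA scoring, unity normalization, purity and preranked GSEA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tmescorer import (
    EnrichmentMatrix,
    GeneSetCollection,
    estimate_purity,
    generate_cohort,
    CohortConfig,
    preranked_gsea,
    score_to_gene_ranking,
    ssgsea_matrix,
    ssgsea_score,
    unity_normalize,
    wilcoxon_rank_sum,
)


def naive_ssgsea(values, gene_ids, gene_set, alpha=0.25):
    """Deliberately plain loop re-implementation used as the oracle."""
    n = len(gene_ids)
    # average ranks, largest value -> rank n
    order_stats = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order_stats[j + 1]] == values[order_stats[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order_stats[k]] = avg
        i = j + 1
    walk = sorted(range(n), key=lambda i: (-ranks[i], i))  # decreasing rank, stable
    in_set = [gene_ids[i] in set(gene_set) for i in walk]
    m = sum(in_set)
    denom_in = sum(ranks[i] ** alpha for i in walk if gene_ids[i] in set(gene_set))
    cum_in = cum_out = 0.0
    total = 0.0
    for pos, i in enumerate(walk):
        if in_set[pos]:
            cum_in += ranks[i] ** alpha / denom_in
        else:
            cum_out += 1.0 / (n - m)
        total += cum_in - cum_out
    return total


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


def test_worked_four_gene_example_top_and_bottom():
    col = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("ABCD"))
    assert ssgsea_score(col, ["A"]) == pytest.approx(2.0)
    assert ssgsea_score(col, ["D"]) == pytest.approx(-2.0)


def test_score_errors_on_degenerate_sets():
    col = pd.Series([4.0, 3.0, 2.0], index=list("ABC"))
    with pytest.raises(ValueError):
        ssgsea_score(col, ["ZZZ"])
    with pytest.raises(ValueError):
        ssgsea_score(col, ["A", "B", "C"])


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_monotone_transform_invariance(seed):
    r = np.random.default_rng(seed)
    vals = r.gamma(2, 10, size=30)
    col = pd.Series(vals, index=[f"G{i}" for i in range(30)])
    gene_set = list(col.index[r.choice(30, size=6, replace=False)])
    base = ssgsea_score(col, gene_set)
    for f in (lambda x: 3 * x + 7, np.log1p, lambda x: x**3):
        assert ssgsea_score(pd.Series(f(vals), index=col.index), gene_set) == pytest.approx(base, abs=1e-12)


def test_matrix_agrees_with_naive_oracle(random_expression):
    m = random_expression(n_genes=100, n_samples=20, seed=77)
    r = np.random.default_rng(42)
    sets = GeneSetCollection(
        {f"set{k}": list(np.array(m.gene_ids)[r.choice(100, size=r.integers(3, 15), replace=False)])
         for k in range(5)}
    )
    scored = ssgsea_matrix(m, sets)
    for name in sets.names:
        for sample in m.sample_ids[::4]:
            expected = naive_ssgsea(m.values[sample].tolist(), m.gene_ids, sets[name])
            assert scored.scores.loc[name, sample] == pytest.approx(expected, abs=1e-9)


def test_matrix_columns_are_independent(random_expression):
    m = random_expression(n_genes=40, n_samples=8, seed=3)
    sets = GeneSetCollection({"s": m.gene_ids[:5]})
    full = ssgsea_matrix(m, sets)
    shuffled = m.subset_samples(m.sample_ids[::-1])
    flipped = ssgsea_matrix(shuffled, sets)
    np.testing.assert_allclose(
        flipped.scores.values[:, ::-1], full.scores.values, atol=1e-12
    )


def test_ties_rank_average_matches_oracle():
    vals = [5.0, 5.0, 2.0, 2.0, 2.0, 1.0]
    ids = [f"G{i}" for i in range(6)]
    col = pd.Series(vals, index=ids)
    for gene_set in (["G0"], ["G2", "G4"], ["G5", "G1"]):
        assert ssgsea_score(col, gene_set) == pytest.approx(
            naive_ssgsea(vals, ids, gene_set), abs=1e-12
        )


# ---------------------------------------------------------------------------
# unity normalization
# ---------------------------------------------------------------------------


def test_unity_normalize_examples_and_idempotence(caplog):
    e = EnrichmentMatrix(pd.DataFrame([[2.0, 4.0, 6.0], [5.0, 5.0, 5.0]],
                                      index=["a", "const"], columns=["s1", "s2", "s3"]))
    with caplog.at_level("WARNING"):
        out = unity_normalize(e)
    assert out.normalized
    assert out.scores.loc["a"].tolist() == [0.0, 0.5, 1.0]
    assert out.scores.loc["const"].tolist() == [0.0, 0.0, 0.0]
    assert any("constant" in r.message for r in caplog.records)
    twice = unity_normalize(out)
    pd.testing.assert_frame_equal(twice.scores, out.scores)


def test_unity_normalize_rows_span_unit_interval(random_expression):
    m = random_expression(n_genes=60, n_samples=10, seed=9)
    sets = GeneSetCollection({"x": m.gene_ids[:6], "y": m.gene_ids[6:16]})
    out = unity_normalize(ssgsea_matrix(m, sets))
    np.testing.assert_allclose(out.scores.min(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.scores.max(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------


def test_estimate_purity_cosine_behaviour(random_expression):
    m = random_expression(n_genes=80, n_samples=12, seed=5)
    out = estimate_purity(m, m.gene_ids[:8], m.gene_ids[8:20])
    assert out["estimate_score"].equals(out["stromal_score"] + out["immune_score"])
    assert ((out["purity"] >= 0) & (out["purity"] <= 1)).all()
    # cos is decreasing where its argument stays inside (0, pi)
    c0, c1 = 0.5, 1e-4
    ordered = out.sort_values("estimate_score")
    args = c0 + c1 * ordered["estimate_score"]
    if ((args > 0) & (args < np.pi)).all():
        pur = np.cos(args)
        assert (np.diff(pur) <= 1e-12).all()


def test_estimate_purity_lower_in_high_infiltration_group(small_cohort):
    cfg, expr, clinical, sets, truth = small_cohort
    # build stromal/immune surrogates from planted signatures of one group
    adverse_sets = [n for n, g in truth.cell_type_group.items() if g == truth.adverse_group]
    stromal = truth.signature_genes[adverse_sets[0]]
    immune = truth.signature_genes[adverse_sets[1]]
    out = estimate_purity(expr, stromal, immune)
    high = truth.group_label == truth.adverse_group
    assert out.loc[high[high].index, "purity"].mean() < out.loc[high[~high].index, "purity"].mean()


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


def test_top_ranked_set_with_zero_weight_reaches_es_one():
    stats_ = pd.Series(np.arange(20, 0, -1, dtype=float), index=[f"G{i}" for i in range(20)])
    res = preranked_gsea(stats_, ["G0", "G1", "G2"], weight=0.0, n_perm=10, seed=0)
    assert res.es == pytest.approx(1.0)
    assert set(res.leading_edge) == {"G0", "G1", "G2"}


def test_exhaustive_null_on_tiny_list():
    """p from random-membership permutations equals exact enumeration over C(6,2)."""
    stats_ = pd.Series([3.0, 2.0, 1.5, 1.0, 0.5, 0.2], index=list("ABCDEF"))
    gene_set = ["A", "B"]

    def es_for(members):
        member = np.array([g in members for g in stats_.index])
        w = np.abs(stats_.to_numpy())
        inc = np.where(member, w / w[member].sum(), -1.0 / (~member).sum())
        run = np.cumsum(inc)
        return run[np.argmax(np.abs(run))]

    observed = es_for(set(gene_set))
    null = [es_for(set(c)) for c in itertools.combinations(stats_.index, 2)]
    same = [x for x in null if (x >= 0) == (observed >= 0)]
    exact = sum(abs(x) >= abs(observed) for x in same) / len(same)
    res = preranked_gsea(stats_, gene_set, weight=1.0, n_perm=4000, seed=1)
    assert res.es == pytest.approx(observed, abs=1e-12)
    # +1-smoothed permutation estimate converges to the exact tail fraction
    assert res.p_perm == pytest.approx(exact, abs=0.03)


def test_null_permutation_p_is_uniform():
    r = np.random.default_rng(11)
    n_reps = 120
    ps = []
    for rep in range(n_reps):
        stats_ = pd.Series(r.normal(size=120), index=[f"G{i}" for i in range(120)])
        gene_set = list(stats_.index[r.choice(120, size=10, replace=False)])
        ps.append(preranked_gsea(stats_, gene_set, n_perm=200, seed=rep).p_perm)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_gene_ranking_from_score(random_expression):
    m = random_expression(n_genes=50, n_samples=15, seed=33)
    r = np.random.default_rng(2)
    score = pd.Series(r.normal(size=15), index=m.sample_ids)
    logx = m.log2()
    # plant perfect (anti-)correlates
    logx.loc["G0000"] = score.to_numpy() + 10.0
    logx.loc["G0001"] = 10.0 - score.to_numpy()
    m2 = type(m)(np.exp2(logx) - 1, "TPM")
    ranking = score_to_gene_ranking(m2, score)
    assert ranking["G0000"] == pytest.approx(1.0, abs=1e-9)
    assert ranking["G0001"] == pytest.approx(-1.0, abs=1e-9)
    # direct covariance/sd oracle
    for g in m.gene_ids[2:12]:
        x = logx.loc[g].to_numpy()
        expected = np.cov(x, score)[0, 1] / (np.std(x, ddof=1) * np.std(score, ddof=1))
        assert ranking[g] == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError, match="constant"):
        score_to_gene_ranking(m2, pd.Series(1.0, index=m.sample_ids))
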