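"""Signature derivation: gene filters, A/B split, TMEscore, maxstat cutpoint."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank
from sklearn.metrics import adjusted_rand_score

from tmescorer import (
    ClinicalTable,
    CohortConfig,
    SignatureModel,
    compute_tmescore,
    dichotomize,
    generate_cohort,
    maxstat_cutpoint,
    prognostic_filter,
    rf_importance_filter,
    split_signature_sets,
)


def _clinical(time, event, index=None):
    idx = index if index is not None else [f"S{i}" for i in range(len(time))]
    return ClinicalTable(pd.DataFrame({"os_time": time, "os_event": event},
                                      index=pd.Index(idx, name="sample_id")))


# ---------------------------------------------------------------------------
# random-forest filter
# ---------------------------------------------------------------------------


def test_rf_keeps_perfect_separator_and_drops_constant(rng):
    n = 60
    groups = np.repeat([0, 1], n // 2)
    x = pd.DataFrame(rng.normal(5, 1, size=(20, n)),
                     index=[f"G{i}" for i in range(20)],
                     columns=[f"S{i}" for i in range(n)])
    x.iloc[0] = np.where(groups == 1, 10.0, 0.0)  # perfect separator
    x.iloc[1] = 4.0  # zero variance
    kept = rf_importance_filter(x, groups, n_trees=200, seed=0)
    assert "G0" in kept
    assert "G1" not in kept


def test_rf_planted_feature_recovery(rng):
    n, ninf, nnoise = 150, 30, 300
    groups = rng.integers(0, 2, n)
    x = rng.normal(3, 1, size=(ninf + nnoise, n))
    x[:ninf, groups == 1] += 2.0
    df = pd.DataFrame(x, index=[f"G{i}" for i in range(ninf + nnoise)],
                      columns=[f"S{i}" for i in range(n)])
    kept = set(rf_importance_filter(df, groups, n_trees=500, seed=1))
    informative = set(df.index[:ninf])
    noise = set(df.index[ninf:])
    assert len(kept & informative) / ninf >= 0.9
    assert 1 - len(kept & noise) / nnoise >= 0.8


def test_rf_top_n_rule_and_validation(rng):
    n = 40
    groups = np.repeat([0, 1], n // 2)
    x = pd.DataFrame(rng.normal(size=(15, n)), index=[f"G{i}" for i in range(15)],
                     columns=[f"S{i}" for i in range(n)])
    x.iloc[0, groups == 1] += 4.0
    kept = rf_importance_filter(x, groups, n_trees=100, seed=0, rule="top_n", top_n=5)
    assert len(kept) == 5 and "G0" in kept
    with pytest.raises(ValueError):
        rf_importance_filter(x, np.zeros(n), n_trees=10)
    with pytest.raises(ValueError):
        rf_importance_filter(x, groups, rule="top_n")


# ---------------------------------------------------------------------------
# prognostic filter
# ---------------------------------------------------------------------------


def test_prognostic_filter_keeps_hazard_linked_gene(rng):
    """A gene whose (log2) expression drives the hazard at beta=1 is retained."""
    n = 200
    x = rng.normal(0, 1, size=n)
    t = rng.exponential(1 / (0.05 * np.exp(1.0 * x)))  # true log-hazard 1 per unit
    cols = [f"S{i}" for i in range(n)]
    df = pd.DataFrame(
        np.vstack([x + 5.0, rng.normal(5, 1, size=(4, n))]),  # log2-scale frame
        index=["hazard_gene", "n1", "n2", "n3", "n4"],
        columns=cols,
    )
    kept = prognostic_filter(df, _clinical(t, np.ones(n, int), index=cols))
    assert "hazard_gene" in kept


def test_prognostic_filter_alpha_zero_is_empty(rng):
    n = 80
    df = pd.DataFrame(rng.gamma(2, 20, size=(5, n)),
                      index=[f"G{i}" for i in range(5)],
                      columns=[f"S{i}" for i in range(n)])
    clin = _clinical(rng.exponential(10, n), np.ones(n, int), index=df.columns)
    assert prognostic_filter(df, clin, alpha=0.0) == []


def test_prognostic_filter_requires_events(rng):
    n = 20
    df = pd.DataFrame(rng.gamma(2, 20, size=(3, n)), columns=[f"S{i}" for i in range(n)])
    with pytest.raises(ValueError, match="event"):
        prognostic_filter(df, _clinical(np.ones(n), np.zeros(n, int), index=df.columns))


def test_prognostic_filter_type_one_calibration():
    """A gene independent of survival is retained about 5% of the time."""
    hits = 0
    n_sims = 200
    r = np.random.default_rng(31)
    for _ in range(n_sims):
        n = 60
        x = pd.DataFrame(r.normal(5, 1, size=(1, n)), index=["g"],
                         columns=[f"S{i}" for i in range(n)])
        clin = _clinical(r.exponential(10, n), np.ones(n, int), index=x.columns)
        hits += len(prognostic_filter(x, clin)) > 0
    # 3-sigma binomial band around 0.05
    assert abs(hits / n_sims - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sims)


# ---------------------------------------------------------------------------
# A/B split
# ---------------------------------------------------------------------------


def _anti_correlated_cohort(rng, n=120, per_block=8):
    """Two gene blocks, one up in the short-survival half of the samples."""
    half = n // 2
    groups = np.repeat([1, 2], half)  # sample group 1 = poor prognosis
    genes_a = [f"A{i}" for i in range(per_block)]
    genes_b = [f"B{i}" for i in range(per_block)]
    x = pd.DataFrame(rng.normal(5, 0.5, size=(2 * per_block, n)),
                     index=genes_a + genes_b, columns=[f"S{i}" for i in range(n)])
    x.loc[genes_a, x.columns[groups == 1]] += 3.0
    x.loc[genes_b, x.columns[groups == 2]] += 3.0
    lam = np.where(groups == 1, 0.2, 0.05)
    t = rng.exponential(1 / lam)
    clin = _clinical(t, np.ones(n, int), index=x.columns)
    sample_groups = pd.Series(groups, index=x.columns)
    return x, clin, sample_groups, genes_a, genes_b


def test_split_recovers_planted_blocks_and_orientation(rng):
    x, clin, sample_groups, genes_a, genes_b = _anti_correlated_cohort(rng)
    from tmescorer import consensus_cluster

    cons = consensus_cluster(x, k=2, reps=50, p_item=0.8,
                             base="hclust_wardD2_euclidean", seed=0)
    gene_clusters = cons.labels_series()
    planted = pd.Series([1] * len(genes_a) + [2] * len(genes_b), index=genes_a + genes_b)
    assert adjusted_rand_score(planted, gene_clusters) == 1.0
    set_a, set_b, note = split_signature_sets(x, gene_clusters, sample_groups, clin)
    # block enriched in the short-survival group becomes set A
    assert set(set_a) == set(genes_a)
    assert set(set_b) == set(genes_b)
    assert "poorer-prognosis" in note


def test_split_validates_cluster_counts(rng):
    x, clin, sample_groups, genes_a, genes_b = _anti_correlated_cohort(rng, n=40, per_block=3)
    bad = pd.Series(1, index=genes_a + genes_b)  # a single cluster
    with pytest.raises(ValueError, match="2 gene clusters"):
        split_signature_sets(x, bad, sample_groups, clin)


# ---------------------------------------------------------------------------
# TMEscore
# ---------------------------------------------------------------------------


def test_tmescore_identities(random_expression):
    m = random_expression(n_genes=60, n_samples=12, seed=4)
    set_a = m.gene_ids[:6]
    set_b = m.gene_ids[6:14]
    same = compute_tmescore(m, set_a, set_a)
    np.testing.assert_allclose(same["tmescore"], 0.0, atol=1e-12)
    fwd = compute_tmescore(m, set_a, set_b)
    rev = compute_tmescore(m, set_b, set_a)
    np.testing.assert_allclose(fwd["tmescore"], -rev["tmescore"], atol=1e-12)


def test_tmescore_worked_single_sample_example():
    import pandas as pd
    from tmescorer import ExpressionMatrix

    m = ExpressionMatrix(pd.DataFrame({"S1": [4.0, 3.0, 2.0, 1.0]}, index=list("ABCD")), "TPM")
    out = compute_tmescore(m, set_a=["D"], set_b=["A"])
    assert out.loc["S1", "tmescore_b"] == pytest.approx(2.0)
    assert out.loc["S1", "tmescore_a"] == pytest.approx(-2.0)
    assert out.loc["S1", "tmescore"] == pytest.approx(4.0)


def test_tmescore_monotone_transform_invariance(random_expression):
    m = random_expression(n_genes=40, n_samples=8, seed=6)
    set_a, set_b = m.gene_ids[:5], m.gene_ids[5:12]
    base = compute_tmescore(m, set_a, set_b)["tmescore"]
    squared = type(m)(m.values**2, "TPM")
    np.testing.assert_allclose(
        compute_tmescore(squared, set_a, set_b)["tmescore"], base, atol=1e-12
    )


# ---------------------------------------------------------------------------
# maxstat
# ---------------------------------------------------------------------------


def brute_force_maxstat(score, time, event, min_prop=0.1):
    """Exhaustive scan using lifelines' log-rank as the independent statistic."""
    import math

    score = np.asarray(score, float)
    n = len(score)
    min_n = math.ceil(min_prop * n)
    distinct = np.unique(score)
    best = (None, -np.inf)
    for cut in (distinct[:-1] + distinct[1:]) / 2.0:
        high = score > cut
        if high.sum() < min_n or (~high).sum() < min_n:
            continue
        res = ll_logrank(time[high], time[~high], event[high], event[~high])
        stat = np.sqrt(res.test_statistic)
        if stat > best[1] + 1e-12:
            best = (cut, stat)
    return best


def test_maxstat_equals_bruteforce_scan(rng):
    for _ in range(8):
        n = 50
        score = rng.normal(size=n)
        t = rng.exponential(10, size=n)
        e = rng.integers(0, 2, size=n)
        if e.sum() == 0:
            continue
        cut, stat = maxstat_cutpoint(score, t, e)
        cut_bf, stat_bf = brute_force_maxstat(score, t, e)
        assert cut == pytest.approx(cut_bf, abs=1e-12)
        assert stat == pytest.approx(stat_bf, abs=1e-8)


def test_maxstat_clean_gap_cut_falls_inside_gap(rng):
    n = 40
    score = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(5, 6, n // 2)])
    lam = np.where(score > 3, 0.02, 0.5)
    t = rng.exponential(1 / lam)
    cut, _ = maxstat_cutpoint(score, t, np.ones(n, int))
    assert 1.0 < cut < 5.0


def test_maxstat_shift_equivariance(rng):
    n = 60
    score = rng.normal(size=n)
    t = rng.exponential(5, size=n)
    e = rng.integers(0, 2, size=n) | 1
    cut, stat = maxstat_cutpoint(score, t, e)
    cut2, stat2 = maxstat_cutpoint(score + 11.5, t, e)
    assert cut2 == pytest.approx(cut + 11.5, abs=1e-9)
    assert stat2 == pytest.approx(stat, abs=1e-9)


def test_maxstat_admissibility_arithmetic():
    # n = 5 at min_prop = 0.4 -> each side needs >= 2 samples: at most one
    # candidate survives for well-spread scores, and clustered scores give none
    score = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    e = np.ones(5, int)
    cut, _ = maxstat_cutpoint(score, t, e, min_prop=0.4)
    assert cut in (2.5, 3.5)
    with pytest.raises(ValueError, match="admissible"):
        maxstat_cutpoint(np.array([1.0, 1.0, 1.0, 1.0, 9.0]), t, e, min_prop=0.4)


def test_dichotomize_is_strict():
    s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    labels = dichotomize(s, 2.0)
    assert labels.tolist() == ["low", "low", "high"]


# ---------------------------------------------------------------------------
# SignatureModel round trip
# ---------------------------------------------------------------------------


def test_signature_model_json_round_trip(tmp_path, random_expression):
    m = random_expression(n_genes=30, n_samples=6, seed=8)
    sig = SignatureModel(set_a=m.gene_ids[:4], set_b=m.gene_ids[4:9],
                         cutpoint=0.5, orientation_note="test", provenance={"seed": 1})
    p = tmp_path / "model.json"
    sig.to_json(p)
    back = SignatureModel.from_json(p)
    assert back == sig
    scored = back.score(m)
    assert {"tmescore_a", "tmescore_b", "tmescore", "risk_label"} <= set(scored.columns)


def test_signature_model_coverage_guard(random_expression):
    m = random_expression(n_genes=30, n_samples=6, seed=8)
    sig = SignatureModel(set_a=["missing1", "missing2", m.gene_ids[0]],
                         set_b=m.gene_ids[1:5])
    with pytest.raises(ValueError, match="coverage"):
        sig.score(m)


def test_signature_model_requires_disjoint_sets():
    with pytest.raises(ValueError, match="disjoint"):
        SignatureModel(set_a=["g1", "g2"], set_b=["g2", "g3"])
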