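"""Single-sample GSEA, unity normalization, purity scoring and preranked GSEA.

The per-sample enrichment statistic is the *integral* form used by ssGSEA:
expression values within a sample are converted to ranks (highest value ->
rank N, average ranks on ties), genes are walked in order of decreasing
rank, and the score is the sum over all positions of the difference between
the weighted in-set empirical CDF (weights ``rank**alpha``) and the uniform
out-of-set CDF. This differs from the classic GSEA statistic, which takes
the maximum deviation of the same running difference; the latter is
implemented separately in :func:`preranked_gsea` together with a
gene-permutation null.

Tie handling is deterministic: ranks use the average-tie convention and any
residual ordering ties are broken by input gene order (stable sort).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

# Purity-from-score cosine constants from the cited ESTIMATE publication
# (Yoshihara et al. 2013). Exposed as arguments; not a contribution of this
# package. Note the original constants were calibrated on the ESTIMATE score
# scale, so purity values computed from other enrichment scales are
# rank-meaningful rather than calibrated fractions.
ESTIMATE_COS_INTERCEPT = 0.6049872018
ESTIMATE_COS_SLOPE = 0.0001467884


@dataclass
class EnrichmentMatrix:
    """Set-by-sample enrichment scores, raw or unity-normalized."""

    scores: pd.DataFrame  # sets x samples
    normalized: bool = False

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def _rank_columns(values: np.ndarray) -> np.ndarray:
    """Average ranks per column; the largest value gets rank N."""
    return rankdata(values, axis=0)


def ssgsea_score(
    expression_column: pd.Series | np.ndarray,
    gene_set: list[str] | np.ndarray,
    alpha: float = 0.25,
    gene_ids: list[str] | None = None,
) -> float:
    """ssGSEA score of one gene set in one sample.

    Parameters
    ----------
    expression_column : Series or array
        Per-gene expression for a single sample. If an array, ``gene_ids``
        must give the gene order.
    gene_set : list of str
        Member gene IDs; the intersection with the gene universe must be a
        proper non-empty subset.
    alpha : float
        Rank-weighting exponent (0.25 is the conventional ssGSEA default).
    """
    if isinstance(expression_column, pd.Series):
        ids = list(expression_column.index)
        vals = expression_column.to_numpy(dtype=float)
    else:
        if gene_ids is None:
            raise ValueError("gene_ids is required when expression_column is a bare array")
        ids = list(gene_ids)
        vals = np.asarray(expression_column, dtype=float)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    member = np.isin(np.asarray(ids, dtype=object), np.asarray(list(gene_set), dtype=object))
    m = int(member.sum())
    n = len(ids)
    if m == 0:
        raise ValueError("gene set has no genes in the expression column")
    if m == n:
        raise ValueError("gene set covers all genes; score is undefined")
    ranks = rankdata(vals)
    order = np.argsort(-ranks, kind="stable")
    in_ordered = member[order]
    w = ranks[order] ** alpha
    w_in = np.where(in_ordered, w, 0.0)
    cum_in = np.cumsum(w_in) / w_in.sum()
    cum_out = np.cumsum(~in_ordered) / (n - m)
    return float(np.sum(cum_in - cum_out))


def ssgsea_matrix(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
) -> EnrichmentMatrix:
    """ssGSEA scores for every set and sample (vectorized across samples).

    Sets with an empty intersection with the gene universe are excluded with
    a warning; sets covering the entire universe are an error.
    """
    sets = sets.restrict_to(m.gene_ids)
    values = m.values.to_numpy(dtype=float)
    g, s = values.shape
    ranks = _rank_columns(values)
    order = np.argsort(-ranks, axis=0, kind="stable")
    col_idx = np.arange(s)[None, :]
    ranks_ordered = ranks[order, col_idx]
    w_ordered_full = ranks_ordered**alpha

    gene_pos = {gid: i for i, gid in enumerate(m.gene_ids)}
    out = np.empty((len(sets), s))
    for si, name in enumerate(sets.names):
        member = np.zeros(g, dtype=bool)
        member[[gene_pos[x] for x in sets[name]]] = True
        mm = int(member.sum())
        if mm == g:
            raise ValueError(f"gene set {name!r} covers the entire gene universe")
        in_ordered = member[order]  # g x s
        w_in = np.where(in_ordered, w_ordered_full, 0.0)
        cum_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0, keepdims=True)
        cum_out = np.cumsum(~in_ordered, axis=0) / (g - mm)
        out[si] = (cum_in - cum_out).sum(axis=0)
    return EnrichmentMatrix(pd.DataFrame(out, index=sets.names, columns=m.sample_ids), normalized=False)


def unity_normalize(e: EnrichmentMatrix) -> EnrichmentMatrix:
    """Rescale each row to [0, 1]: (x - min) / (max - min).

    A constant row becomes all zeros (with a warning) — there is no
    information to spread over the unit interval.
    """
    if e.normalized:
        return EnrichmentMatrix(e.scores.copy(), normalized=True)
    lo = e.scores.min(axis=1)
    hi = e.scores.max(axis=1)
    span = hi - lo
    const = span == 0
    if const.any():
        logger.warning("constant enrichment row(s) set to zero: %s", list(e.scores.index[const]))
    safe = span.replace(0, 1.0)
    norm = e.scores.sub(lo, axis=0).div(safe, axis=0)
    norm.loc[const] = 0.0
    return EnrichmentMatrix(norm, normalized=True)


def estimate_purity(
    m: ExpressionMatrix,
    stromal_set: list[str],
    immune_set: list[str],
    alpha: float = 0.25,
    cos_intercept: float = ESTIMATE_COS_INTERCEPT,
    cos_slope: float = ESTIMATE_COS_SLOPE,
) -> pd.DataFrame:
    """Stromal/immune infiltration scores and inferred tumor purity.

    Stromal and immune scores are per-sample ssGSEA scores of the two gene
    sets; their sum is the combined infiltration score, and purity is the
    cosine transform ``cos(c0 + c1 * score)`` clamped to [0, 1].
    """
    sets = GeneSetCollection({"stromal": list(stromal_set), "immune": list(immune_set)})
    scores = ssgsea_matrix(m, sets, alpha=alpha).scores
    stromal = scores.loc["stromal"]
    immune = scores.loc["immune"]
    combined = stromal + immune
    purity = np.cos(cos_intercept + cos_slope * combined).clip(0.0, 1.0)
    return pd.DataFrame(
        {
            "stromal_score": stromal,
            "immune_score": immune,
            "estimate_score": combined,
            "purity": purity,
        }
    )


@dataclass
class GseaResult:
    """Classic (max-deviation) GSEA outcome for one gene set."""

    set_name: str
    es: float
    nes: float
    p_perm: float
    n_perm: int
    leading_edge: list[str]


def _running_es(weights: np.ndarray, member: np.ndarray, n_out: int) -> tuple[float, int]:
    """Signed maximum deviation of the weighted KS running sum."""
    total_in = weights[member].sum()
    if total_in == 0:  # all-zero stats in the set: fall back to equal weights
        inc_in = np.where(member, 1.0 / member.sum(), 0.0)
    else:
        inc_in = np.where(member, weights / total_in, 0.0)
    inc = inc_in - np.where(member, 0.0, 1.0 / n_out)
    run = np.cumsum(inc)
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def preranked_gsea(
    gene_stats: pd.Series,
    gene_set: list[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA with a gene-label permutation null.

    ``gene_stats`` is a per-gene ranking statistic (e.g. correlation with a
    sample-level score); genes are ordered by decreasing statistic, in-set
    steps are weighted by ``|stat|**weight``, and the enrichment score (ES)
    is the signed maximum deviation of the running sum. The null distribution
    re-draws the set membership uniformly at random ``n_perm`` times; the
    normalized ES divides by the mean |null ES| of matching sign and the
    permutation p-value is the one-sided, sign-matched tail frequency with
    +1 smoothing.
    """
    stats = gene_stats.astype(float)
    if not np.isfinite(stats.to_numpy()).all():
        raise ValueError("gene_stats must be finite")
    ids = np.asarray(stats.index, dtype=object)
    member_ids = set(gene_set)
    member = np.array([g in member_ids for g in ids])
    m = int(member.sum())
    n = len(ids)
    if m == 0 or m == n:
        raise ValueError("gene set must be a proper non-empty subset of the ranked genes")

    order = np.argsort(-stats.to_numpy(), kind="stable")
    stat_sorted = stats.to_numpy()[order]
    member_sorted = member[order]
    weights = np.abs(stat_sorted) ** weight
    es, peak = _running_es(weights, member_sorted, n - m)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_member = np.zeros(n, dtype=bool)
        perm_member[rng.choice(n, size=m, replace=False)] = True
        null[i], _ = _running_es(weights, perm_member, n - m)

    same_sign = null >= 0 if es >= 0 else null <= 0
    n_same = int(same_sign.sum())
    if n_same:
        tail = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (tail + 1) / (n_same + 1)
        mean_same = float(np.abs(null[same_sign]).mean())
        nes = es / mean_same if mean_same > 0 else np.nan
    else:
        p, nes = 1.0 / (n_perm + 1), np.nan

    ordered_ids = ids[order]
    if es >= 0:
        leading = [g for g in ordered_ids[: peak + 1] if g in member_ids]
    else:
        leading = [g for g in ordered_ids[peak:] if g in member_ids]
    return GseaResult(set_name="", es=es, nes=float(nes), p_perm=float(p), n_perm=n_perm,
                      leading_edge=list(leading))


def gsea_collection(
    gene_stats: pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`preranked_gsea` for every set; one row per set."""
    seeds = np.random.SeedSequence(seed).spawn(len(sets))
    rows = []
    for name, child in zip(sets.names, seeds):
        res = preranked_gsea(gene_stats, sets[name], weight=weight, n_perm=n_perm,
                             seed=int(child.generate_state(1)[0] % (2**31)))
        rows.append({"set_name": name, "es": res.es, "nes": res.nes,
                     "p_perm": res.p_perm, "n_perm": res.n_perm,
                     "leading_edge_size": len(res.leading_edge)})
    return pd.DataFrame(rows).set_index("set_name")


def score_to_gene_ranking(m: ExpressionMatrix, score: pd.Series) -> pd.Series:
    """Per-gene Pearson correlation of log2(TPM+1) with a sample-level score.

    Turns "samples ranked by score" into a gene-level statistic suitable for
    preranked GSEA. Zero-variance genes get statistic 0.
    """
    score = score.reindex(m.sample_ids)
    s = score.to_numpy(dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(s) == 0:
        raise ValueError("score is constant; correlation is undefined")
    x = m.log2().to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ sc) / denom
    r[~np.isfinite(r)] = 0.0
    return pd.Series(r, index=m.gene_ids, name="pearson_r")
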