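"""Moderated differential expression and multiple-testing correction.

Two-group tests use an empirical-Bayes moderated t-statistic: per-gene
pooled variances are shrunk toward a common prior variance ``s0^2`` with
prior degrees of freedom ``d0``, both estimated by closed-form moment
matching of ``log s_g^2`` against a scaled-F model (Smyth's method). With
``d0 = 0`` the statistic reduces to the ordinary pooled two-sample t; as
``d0 -> inf`` every gene is tested against the common prior variance.

Expression is tested on the log2(TPM + 1) scale. A differentially expressed
gene (DEG) is one with |log2FC| strictly greater than the fold-change
threshold and a Benjamini–Hochberg adjusted p-value below alpha.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["log2fc", "t_stat", "p_value", "adj_p", "mean_a", "mean_b", "passes_filter"]


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from per-gene variances.

    Fits ``s2 ~ s0^2 * F(d, d0)`` via the first two moments of ``log s2``.
    Returns ``d0 = inf`` when the observed spread of log-variances is no
    wider than the chi-square sampling spread alone.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1e-8
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = np.var(z, ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    m: ExpressionMatrix | pd.DataFrame,
    group_labels: pd.Series | np.ndarray,
    lfc_thr: float = 1.0,
    alpha: float = 0.05,
    d0: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per gene.

    Parameters
    ----------
    m : ExpressionMatrix or DataFrame
        TPM/FPKM matrices are tested on log2(x+1); a DataFrame (or a LOG2
        matrix) is used as is.
    group_labels : binary per sample
        The two groups, aligned to the matrix columns. ``log2fc`` is
        mean(group B) − mean(group A) with A/B the sorted label values.
    d0 : float, optional
        Override the estimated prior degrees of freedom (0 disables
        moderation; ``inf`` uses the prior variance alone).

    Returns a DEG table indexed by gene with columns ``log2fc, t_stat,
    p_value, adj_p, mean_a, mean_b, passes_filter``.
    """
    if isinstance(m, ExpressionMatrix):
        x = m.log2()
    else:
        x = m
    labels = pd.Series(np.asarray(group_labels), index=x.columns)
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    mask_a = (labels == levels[0]).to_numpy()
    mask_b = (labels == levels[1]).to_numpy()
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")

    xa = x.to_numpy(dtype=float)[:, mask_a]
    xb = x.to_numpy(dtype=float)[:, mask_b]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    lfc = mean_b - mean_a
    d = na + nb - 2
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / d

    if d0 is None:
        d0_hat, s0_sq = _fit_prior(s2, d)
    else:
        d0_hat = float(d0)
        _, s0_sq = _fit_prior(s2, d) if d0_hat > 0 else (None, 0.0)
    if np.isinf(d0_hat):
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e9  # effectively normal
    else:
        s2_post = (d0_hat * s0_sq + d * s2) / (d0_hat + d)
        df_total = d0_hat + d

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj = bh_adjust(p)
    passes = (np.abs(lfc) > lfc_thr) & (adj < alpha)
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "t_stat": t,
            "p_value": p,
            "adj_p": adj,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "passes_filter": passes,
        },
        index=x.index,
    )
    out.attrs["d0"] = d0_hat
    out.attrs["s0_sq"] = s0_sq
    out.attrs["groups"] = (levels[0], levels[1])
    return out


def one_vs_rest_degs(
    m: ExpressionMatrix | pd.DataFrame,
    multi_labels: pd.Series | np.ndarray,
    lfc_thr: float = 1.0,
    alpha: float = 0.05,
) -> tuple[dict, pd.DataFrame]:
    """One-vs-rest moderated t-tests per group.

    Returns ``(tables, overlap)`` where ``tables[g]`` is the full signed DEG
    table for group g versus the rest (log2fc > 0 means higher in g) and
    ``overlap`` counts shared genes between the per-group DEG *sets*. A
    group's DEG set (see :func:`deg_sets`) contains the genes
    **over-expressed** in that group (log2fc > threshold and adjusted p <
    alpha): a gene elevated in one group inevitably re-appears as
    down-regulated in the other groups' contrasts, so two-sided sets would
    overlap by construction, whereas up-regulated sets are group-specific.
    """
    cols = m.values.columns if isinstance(m, ExpressionMatrix) else m.columns
    labels = pd.Series(np.asarray(multi_labels), index=cols)
    counts = labels.value_counts()
    small = sorted(counts.index[counts < 2].tolist())
    if small:
        logger.warning("skipping group(s) with fewer than 2 samples: %s", small)
    groups = sorted(g for g in pd.unique(labels) if g not in set(small))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 samples each")
    tables = {}
    for g in groups:
        binary = np.where(labels == g, 1, 0)  # rest=0 (A), group=1 (B): log2fc = group - rest
        tables[g] = moderated_t_test(m, binary, lfc_thr=lfc_thr, alpha=alpha)
    sets = deg_sets(tables)
    overlap = pd.DataFrame(0, index=groups, columns=groups)
    for g in groups:
        overlap.loc[g, g] = len(sets[g])
    for g1, g2 in combinations(groups, 2):
        shared = len(sets[g1] & sets[g2])
        overlap.loc[g1, g2] = shared
        overlap.loc[g2, g1] = shared
    return tables, overlap


def deg_sets(tables: dict) -> dict:
    """Per-group DEG sets: genes over-expressed in the group and passing the filter."""
    return {
        g: set(t.index[t["passes_filter"] & (t["log2fc"] > 0)]) for g, t in tables.items()
    }
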