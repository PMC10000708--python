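"""Derivation of the TME signature gene sets and the TMEscore.

Pipeline position: after consensus TME subtyping and one-vs-rest DEG
calling, the DEGs are narrowed by (1) a random-forest contribution filter —
genes whose out-of-bag permutation importance for predicting the TME group
is positive — and (2) a prognostic filter — genes whose univariate Cox Wald
p-value is below alpha. The surviving genes are consensus-clustered into
two blocks; the block over-expressed in the poorer-prognosis sample group
becomes signature set A, the other set B, and

    TMEscore = ssGSEA(set B) - ssGSEA(set A)

per sample. The score is dichotomized at the maximally selected rank
statistic: the admissible cutpoint maximizing the standardized log-rank
statistic between the induced groups.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .enrichment import ssgsea_matrix, unity_normalize, EnrichmentMatrix
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .survival import _logrank_oev, univariate_cox_screen

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gene filters
# ---------------------------------------------------------------------------


def rf_permutation_importance(
    x: pd.DataFrame,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    min_samples_leaf: int = 10,
) -> pd.Series:
    """Per-tree out-of-bag permutation importance (mean decrease in accuracy).

    For each tree, the accuracy on its out-of-bag samples is compared with
    the accuracy after permuting one feature at a time (only features the
    tree actually splits on; the others contribute exactly zero). The
    decrease is averaged over all trees. ``min_samples_leaf`` (default 10)
    keeps the trees from chasing noise in tiny nodes, so genes carrying no
    group information are mostly never split on and score exactly zero.
    Unlike whole-forest permutation
    importance, this stays informative when many features are correlated —
    trees that happened not to sample a gene's surrogates must rely on the
    gene itself.

    ``x`` is genes x samples; returns a Series of importances per gene.
    """
    feat = x.to_numpy(dtype=float).T  # samples x genes
    n, p = feat.shape
    rf = RandomForestClassifier(
        n_estimators=n_trees, min_samples_leaf=min_samples_leaf,
        random_state=seed % (2**32 - 1), n_jobs=1,
    )
    rf.fit(feat, y)
    y_codes = np.searchsorted(rf.classes_, y)
    rng = np.random.default_rng(seed)
    imp_sum = np.zeros(p)
    for tree, sampled in zip(rf.estimators_, rf.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sampled)
        if oob.size == 0:
            continue
        x_oob = feat[oob]
        y_oob = y_codes[oob]
        base = (tree.predict(x_oob).astype(int) == y_oob).sum()
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for f in used:
            saved = x_oob[:, f].copy()
            x_oob[:, f] = saved[rng.permutation(oob.size)]
            correct = (tree.predict(x_oob).astype(int) == y_oob).sum()
            x_oob[:, f] = saved
            imp_sum[f] += (base - correct) / oob.size
    return pd.Series(imp_sum / len(rf.estimators_), index=x.index, name="importance")


def rf_importance_filter(
    m: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    rule: str = "importance_gt_zero",
    top_n: int | None = None,
    min_samples_leaf: int = 10,
) -> list[str]:
    """Keep genes that contribute to predicting the TME group.

    A random-forest classifier (genes as features, TME group as target) is
    grown and genes are ranked by out-of-bag permutation importance
    (:func:`rf_permutation_importance`). The default rule retains genes with
    strictly positive importance; the ``top_n`` rule keeps the ``top_n``
    highest-ranked genes instead.
    """
    x = m.log2() if isinstance(m, ExpressionMatrix) else m
    y = np.asarray(labels)
    if len(pd.unique(y)) < 2:
        raise ValueError("rf_importance_filter needs at least 2 groups")
    if x.shape[1] < 10:
        raise ValueError("rf_importance_filter needs at least 10 samples")
    if rule not in ("importance_gt_zero", "top_n"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "top_n" and not top_n:
        raise ValueError("rule='top_n' requires top_n")

    importances = rf_permutation_importance(
        x, y, n_trees=n_trees, seed=seed, min_samples_leaf=min_samples_leaf
    )
    if rule == "top_n":
        kept = importances.sort_values(ascending=False).head(top_n).index.tolist()
    else:
        kept = importances.index[importances > 0].tolist()
    logger.info("random-forest filter kept %d / %d genes", len(kept), x.shape[0])
    return kept


def prognostic_filter(
    m: ExpressionMatrix | pd.DataFrame,
    clinical: ClinicalTable,
    alpha: float = 0.05,
) -> list[str]:
    """Keep genes whose univariate Cox Wald p-value is below ``alpha``.

    Expression enters the hazard model on the log2(TPM+1) scale. Genes whose
    univariate fit fails (constant expression, non-convergence) are dropped.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    x = m.log2() if isinstance(m, ExpressionMatrix) else m
    samples = [s for s in x.columns if s in clinical.data.index]
    if len(samples) < len(x.columns):
        logger.warning("prognostic_filter: %d sample(s) lack clinical data", len(x.columns) - len(samples))
    clin = clinical.subset(samples)
    if clin.os_event.sum() < 1:
        raise ValueError("prognostic filter needs at least one event")
    screen = univariate_cox_screen(
        x[samples], clin.os_time.to_numpy(dtype=float), clin.os_event.to_numpy(dtype=int)
    )
    kept = screen.index[screen["converged"] & (screen["wald_p"] < alpha)].tolist()
    logger.info("prognostic filter kept %d / %d genes at alpha=%g", len(kept), x.shape[0], alpha)
    return kept


# ---------------------------------------------------------------------------
# A/B split and TMEscore
# ---------------------------------------------------------------------------


def split_signature_sets(
    m: ExpressionMatrix | pd.DataFrame,
    gene_clusters: pd.Series,
    sample_groups: pd.Series,
    clinical: ClinicalTable,
) -> tuple[list[str], list[str], str]:
    """Partition signature genes into the adverse set A and favorable set B.

    ``gene_clusters`` assigns each retained gene to one of two clusters;
    ``sample_groups`` assigns each sample to one of two gene-expression
    groups. The sample group with the log-rank excess of observed deaths is
    the poorer-prognosis group; the gene cluster with the higher mean
    (z-scored log2) expression in that group becomes set A.
    """
    x = m.log2() if isinstance(m, ExpressionMatrix) else m
    clusters = sorted(gene_clusters.unique())
    if len(clusters) != 2:
        raise ValueError(f"expected exactly 2 gene clusters, got {clusters}")
    if (gene_clusters.value_counts() < 1).any():
        raise ValueError("a gene cluster is empty")
    groups = sorted(sample_groups.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 sample groups, got {groups}")

    samples = [s for s in x.columns if s in clinical.data.index]
    clin = clinical.subset(samples)
    sg = sample_groups.reindex(samples)
    oe, _ = _logrank_oev(
        clin.os_time.to_numpy(dtype=float),
        clin.os_event.to_numpy(dtype=int),
        (sg == groups[1]).to_numpy(dtype=float),
    )
    adverse_samples = sg.index[sg == (groups[1] if oe > 0 else groups[0])]
    adverse_group = groups[1] if oe > 0 else groups[0]

    z = x.sub(x.mean(axis=1), axis=0).div(x.std(axis=1).replace(0, 1.0), axis=0)
    cluster_means = {
        c: float(z.loc[gene_clusters.index[gene_clusters == c], adverse_samples].mean().mean())
        for c in clusters
    }
    set_a_cluster = max(clusters, key=lambda c: cluster_means[c])
    set_b_cluster = clusters[0] if set_a_cluster == clusters[1] else clusters[1]
    set_a = gene_clusters.index[gene_clusters == set_a_cluster].tolist()
    set_b = gene_clusters.index[gene_clusters == set_b_cluster].tolist()
    note = (
        f"set A = gene cluster {set_a_cluster} (mean z {cluster_means[set_a_cluster]:+.3f}) "
        f"over-expressed in the poorer-prognosis sample group {adverse_group}; "
        f"set B = gene cluster {set_b_cluster}"
    )
    return set_a, set_b, note


def compute_tmescore(
    m: ExpressionMatrix,
    set_a: list[str],
    set_b: list[str],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Per-sample TMEscore components: score(B) − score(A).

    Scores are raw ssGSEA scores by default (two like-scaled quantities);
    ``normalize`` applies unity normalization to each component first.
    """
    sets = GeneSetCollection({"set_a": list(set_a), "set_b": list(set_b)})
    e = ssgsea_matrix(m, sets, alpha=alpha)
    if normalize:
        e = unity_normalize(e)
    missing = [name for name in ("set_a", "set_b") if name not in e.set_names]
    if missing:
        raise ValueError(f"signature set(s) with no genes in the matrix: {missing}")
    a = e.scores.loc["set_a"]
    b = e.scores.loc["set_b"]
    return pd.DataFrame({"tmescore_a": a, "tmescore_b": b, "tmescore": b - a})


# ---------------------------------------------------------------------------
# Maximally selected rank statistic
# ---------------------------------------------------------------------------


def maxstat_cutpoint(
    score,
    time,
    event,
    min_prop: float = 0.1,
) -> tuple[float, float]:
    """Cutpoint maximizing the standardized log-rank statistic |Z|.

    Candidates are midpoints between consecutive distinct score values for
    which both induced groups keep at least ``ceil(min_prop * n)`` samples.
    Ties in |Z| resolve to the smaller cutpoint. Note the maximally selected
    statistic is used for *selection* only; a log-rank p-value reported on
    the selected split is anti-conservative.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(score)
    if not 0 < min_prop < 0.5:
        raise ValueError("min_prop must be in (0, 0.5)")
    if event.sum() < 1:
        raise ValueError("maxstat needs at least one event")
    min_n = math.ceil(min_prop * n)
    distinct = np.unique(score)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_cut, best_stat = None, -np.inf
    for cut in candidates:
        high = score > cut
        n_high = int(high.sum())
        if n_high < min_n or n - n_high < min_n:
            continue
        oe, v = _logrank_oev(time, event, high.astype(float))
        if v <= 0:
            continue
        stat = abs(oe) / np.sqrt(v)
        if stat > best_stat + 1e-12:
            best_cut, best_stat = float(cut), float(stat)
    if best_cut is None:
        raise ValueError("no admissible cutpoint (min_prop too large or degenerate scores)")
    return best_cut, best_stat


def dichotomize(score: pd.Series, cutpoint: float) -> pd.Series:
    """High/low labels: ``high`` iff score > cutpoint."""
    return pd.Series(np.where(score > cutpoint, "high", "low"), index=score.index, name="risk_label")


# ---------------------------------------------------------------------------
# The fitted artifact
# ---------------------------------------------------------------------------


@dataclass
class SignatureModel:
    """Frozen TME signature: gene sets A/B, scoring parameters and cutpoint."""

    set_a: list[str]
    set_b: list[str]
    alpha: float = 0.25
    normalize: bool = False
    cutpoint: float | None = None
    orientation_note: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.set_a) & set(self.set_b):
            raise ValueError("signature sets A and B must be disjoint")
        if not self.set_a or not self.set_b:
            raise ValueError("signature sets must be non-empty")

    def score(self, m: ExpressionMatrix, min_coverage: float = 0.5) -> pd.DataFrame:
        """Score a cohort with the frozen sets; the model is not modified.

        Genes absent from the cohort are dropped from the sets for scoring;
        if either set's coverage falls below ``min_coverage`` the run aborts.
        """
        universe = set(m.gene_ids)
        cov_a = len([g for g in self.set_a if g in universe]) / len(self.set_a)
        cov_b = len([g for g in self.set_b if g in universe]) / len(self.set_b)
        if cov_a < min_coverage or cov_b < min_coverage:
            raise ValueError(
                f"signature coverage too low (set A {cov_a:.0%}, set B {cov_b:.0%}); "
                f"need >= {min_coverage:.0%}"
            )
        if cov_a < 1 or cov_b < 1:
            logger.warning("signature coverage: set A %.0f%%, set B %.0f%%", 100 * cov_a, 100 * cov_b)
        scores = compute_tmescore(m, self.set_a, self.set_b, alpha=self.alpha, normalize=self.normalize)
        if self.cutpoint is not None:
            scores["risk_label"] = dichotomize(scores["tmescore"], self.cutpoint)
        return scores

    def to_json(self, path: str | Path) -> None:
        payload = {
            "set_a": self.set_a,
            "set_b": self.set_b,
            "alpha": self.alpha,
            "normalize": self.normalize,
            "cutpoint": self.cutpoint,
            "orientation_note": self.orientation_note,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)
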