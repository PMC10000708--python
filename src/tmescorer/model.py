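"""The TMEscore model: end-to-end fitting, results and validation.

Follows the statsmodels convention: :class:`TMEScoreModel` is constructed
from data (expression matrix, clinical table, cell-type signature
collection) plus a :class:`PipelineConfig`; :meth:`TMEScoreModel.fit` runs
the whole derivation and returns a :class:`TMEScoreResults` carrying the
frozen :class:`~tmescorer.signature.SignatureModel`, per-sample scores and
labels, the stage-by-stage report, headline survival statistics and a
``summary()`` table. Scoring new cohorts and immunotherapy-cohort
validation hang off the results object and never re-derive the gene sets.

Stage order: ssGSEA on cell-type signatures -> unity normalization ->
consensus subtyping of samples (k chosen by consensus stability) -> one-vs-rest
DEGs -> random-forest contribution filter -> univariate-Cox prognostic
filter -> consensus clustering of the surviving genes (k = 2) and of the
samples on those genes (k = 2) -> A/B split oriented by prognosis ->
TMEscore -> maximally selected cutpoint -> log-rank / Cox / group
comparisons.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from .diffexpr import deg_sets, one_vs_rest_degs
from .enrichment import ssgsea_matrix, unity_normalize
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .signature import (
    SignatureModel,
    compute_tmescore,
    dichotomize,
    maxstat_cutpoint,
    prognostic_filter,
    rf_importance_filter,
    split_signature_sets,
)
from .survival import (
    chi_square_test,
    compare_enrichment_by_group,
    cox_ph_fit,
    km_estimate,
    logrank_test,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunable knobs of the TMEscore derivation.

    Defaults follow the published workflow where it states them (ssGSEA
    alpha 0.25; consensus reps 1000, pItem 0.8, pFeature 1 with
    complete-linkage/Manhattan sample clustering; DEG thresholds |log2FC| > 1
    and BH-adjusted p < 0.05; random forest with 500 trees) and documented
    surrogates where it does not (Ward/Euclidean consensus base for gene
    clustering, positive permutation importance, univariate Cox p < 0.05,
    maxstat minimum group proportion 0.1).
    """

    ssgsea_alpha: float = 0.25
    reps: int = 1000
    p_item: float = 0.8
    p_feature: float = 1.0
    sample_base: str = "hclust_complete_manhattan"
    gene_base: str = "hclust_wardD2_euclidean"
    sample_k_min: int = 2
    sample_k_max: int = 5
    select_k_threshold: float = 0.1
    lfc_thr: float = 1.0
    deg_alpha: float = 0.05
    n_trees: int = 500
    rf_rule: str = "importance_gt_zero"
    rf_top_n: int | None = None
    prognostic_alpha: float = 0.05
    maxstat_min_prop: float = 0.1
    normalize_signature_scores: bool = False
    covariates: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(d["covariates"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


class TMEScoreModel:
    """Derives a TMEscore signature from a cohort.

    Parameters
    ----------
    expression : ExpressionMatrix
        TPM (or FPKM, converted by the caller) gene-by-sample matrix.
    clinical : ClinicalTable
        Overall-survival times/events for (a subset of) the samples.
    cell_signatures : GeneSetCollection
        TME cell-type signature gene sets quantified by ssGSEA.
    config : PipelineConfig, optional
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        clinical: ClinicalTable,
        cell_signatures: GeneSetCollection,
        config: PipelineConfig | None = None,
    ):
        self.config = config or PipelineConfig()
        common = [s for s in expression.sample_ids if s in clinical.data.index]
        if len(common) < 10:
            raise ValueError(f"only {len(common)} samples have both expression and survival data")
        if len(common) < len(expression.sample_ids):
            logger.info(
                "restricting to %d / %d samples with survival data",
                len(common), len(expression.sample_ids),
            )
        self.expression = expression.subset_samples(common)
        self.clinical = clinical.subset(common)
        self.cell_signatures = cell_signatures.restrict_to(self.expression.gene_ids)

    @classmethod
    def from_files(
        cls,
        expr_path: str | Path,
        clinical_path: str | Path,
        gmt_path: str | Path,
        unit: str = "TPM",
        config: PipelineConfig | None = None,
    ) -> "TMEScoreModel":
        from .io import fpkm_to_tpm, read_clinical, read_expression_matrix, read_gmt

        expr = read_expression_matrix(expr_path, unit=unit)
        if expr.unit == "FPKM":
            expr = fpkm_to_tpm(expr)
        return cls(expr, read_clinical(clinical_path), read_gmt(gmt_path), config=config)

    # -- fitting ----------------------------------------------------------

    def fit(self, seed: int = 0) -> "TMEScoreResults":
        cfg = self.config
        seeds = np.random.SeedSequence(seed).spawn(6)
        child = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
        report: dict = {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "seed": seed,
            "n_samples": len(self.expression.sample_ids),
            "n_genes": len(self.expression.gene_ids),
            "stages": {},
        }

        def stage(name):
            t0 = _time.perf_counter()
            logger.info("stage %s ...", name)

            def done(**counts):
                report["stages"][name] = {"seconds": round(_time.perf_counter() - t0, 3), **counts}

            return done

        # 1. cell-type quantification
        done = stage("ssgsea")
        try:
            raw = ssgsea_matrix(self.expression, self.cell_signatures, alpha=cfg.ssgsea_alpha)
            cell_scores = unity_normalize(raw)
        except Exception as err:
            raise PipelineError("ssgsea", str(err)) from err
        done(n_sets=len(cell_scores.set_names))

        # 2. sample consensus subtyping
        done = stage("sample_subtyping")
        try:
            sweep = _cluster.consensus_sweep(
                cell_scores.scores.T,
                range(cfg.sample_k_min, cfg.sample_k_max + 1),
                reps=cfg.reps, p_item=cfg.p_item, p_feature=cfg.p_feature,
                base=cfg.sample_base, seed=child[0],
            )
            chosen_k = _cluster.select_k(sweep, threshold=cfg.select_k_threshold)
            chosen = next(r for r in sweep if r.k == chosen_k)
            tme_groups = chosen.labels_series().rename("tme_group")
        except Exception as err:
            raise PipelineError("sample_subtyping", str(err)) from err
        done(chosen_k=chosen_k, group_sizes=tme_groups.value_counts().sort_index().tolist())

        # 3. one-vs-rest DEGs
        done = stage("degs")
        try:
            deg_tables, deg_overlap = one_vs_rest_degs(
                self.expression, tme_groups, lfc_thr=cfg.lfc_thr, alpha=cfg.deg_alpha
            )
            deg_union = sorted({g for s_ in deg_sets(deg_tables).values() for g in s_})
        except Exception as err:
            raise PipelineError("degs", str(err)) from err
        if len(deg_union) < 4:
            raise PipelineError("degs", f"only {len(deg_union)} DEGs pass the filter")
        done(n_degs=len(deg_union))

        # 4. random-forest contribution filter
        done = stage("rf_filter")
        try:
            rf_genes = rf_importance_filter(
                self.expression.subset_genes(deg_union), tme_groups,
                n_trees=cfg.n_trees, seed=child[1], rule=cfg.rf_rule, top_n=cfg.rf_top_n,
            )
        except Exception as err:
            raise PipelineError("rf_filter", str(err)) from err
        if len(rf_genes) < 4:
            raise PipelineError("rf_filter", f"only {len(rf_genes)} genes retained")
        done(n_genes=len(rf_genes))

        # 5. prognostic filter
        done = stage("prognostic_filter")
        try:
            prog_genes = prognostic_filter(
                self.expression.subset_genes(rf_genes), self.clinical, alpha=cfg.prognostic_alpha
            )
        except Exception as err:
            raise PipelineError("prognostic_filter", str(err)) from err
        if len(prog_genes) < 4:
            raise PipelineError("prognostic_filter", f"only {len(prog_genes)} genes retained")
        done(n_genes=len(prog_genes))

        # 6. gene clustering (k=2) and sample grouping on the signature genes
        done = stage("gene_clustering")
        try:
            sig_expr = self.expression.subset_genes(prog_genes)
            logx = sig_expr.log2()
            z = logx.sub(logx.mean(axis=1), axis=0).div(logx.std(axis=1).replace(0, 1.0), axis=0)
            gene_cons = _cluster.consensus_cluster(
                z, k=2, reps=cfg.reps, p_item=cfg.p_item, p_feature=cfg.p_feature,
                base=cfg.gene_base, seed=child[2],
            )
            gene_clusters = gene_cons.labels_series().rename("gene_cluster")
            sample_cons = _cluster.consensus_cluster(
                z.T, k=2, reps=cfg.reps, p_item=cfg.p_item, p_feature=cfg.p_feature,
                base=cfg.gene_base, seed=child[3],
            )
            gene_groups = sample_cons.labels_series().rename("tme_gene_group")
        except Exception as err:
            raise PipelineError("gene_clustering", str(err)) from err
        done(
            gene_cluster_sizes=gene_clusters.value_counts().sort_index().tolist(),
            sample_group_sizes=gene_groups.value_counts().sort_index().tolist(),
        )

        # 7. A/B split and TMEscore
        done = stage("tmescore")
        try:
            set_a, set_b, note = split_signature_sets(sig_expr, gene_clusters, gene_groups, self.clinical)
            scores = compute_tmescore(
                self.expression, set_a, set_b,
                alpha=cfg.ssgsea_alpha, normalize=cfg.normalize_signature_scores,
            )
        except Exception as err:
            raise PipelineError("tmescore", str(err)) from err
        done(set_a=len(set_a), set_b=len(set_b))

        # 8. maxstat cutpoint and survival statistics
        done = stage("survival")
        try:
            tme = scores["tmescore"]
            cut, max_stat = maxstat_cutpoint(
                tme.to_numpy(),
                self.clinical.os_time.to_numpy(),
                self.clinical.os_event.to_numpy(),
                min_prop=cfg.maxstat_min_prop,
            )
            risk = dichotomize(tme, cut)
            scores = scores.assign(risk_label=risk)
            lr = logrank_test(self.clinical.os_time, self.clinical.os_event, risk)
            cox_uni = cox_ph_fit(
                self.clinical.os_time, self.clinical.os_event, pd.DataFrame({"tmescore": tme})
            )
            cox_multi = None
            covs = [c for c in cfg.covariates if c in self.clinical.data.columns]
            if covs:
                design = pd.DataFrame({"tmescore": tme})
                for c in covs:
                    design[c] = pd.to_numeric(self.clinical.data[c], errors="coerce")
                design = design.dropna()
                cox_multi = cox_ph_fit(
                    self.clinical.subset(design.index).os_time,
                    self.clinical.subset(design.index).os_event,
                    design,
                )
        except Exception as err:
            raise PipelineError("survival", str(err)) from err
        done(cutpoint=round(cut, 6), logrank_p=lr.p)

        # 9. cell-infiltration contrast between score groups
        done = stage("enrichment_contrast")
        try:
            contrast = compare_enrichment_by_group(cell_scores, risk)
        except Exception as err:
            raise PipelineError("enrichment_contrast", str(err)) from err
        done(n_significant=int((contrast["adj_p"] < 0.05).sum()))

        signature = SignatureModel(
            set_a=set_a,
            set_b=set_b,
            alpha=cfg.ssgsea_alpha,
            normalize=cfg.normalize_signature_scores,
            cutpoint=cut,
            orientation_note=note,
            provenance={"seed": seed, "config_hash": cfg.config_hash()},
        )
        report["chosen_k"] = chosen_k
        report["n_signature_genes"] = len(set_a) + len(set_b)
        report["cutpoint"] = cut
        report["maxstat_statistic"] = max_stat
        report["logrank"] = {"chi2": lr.chi2, "p": lr.p, "z": lr.z}
        report["cox_hr_per_unit_tmescore"] = float(cox_uni.hr.iloc[0]) if cox_uni.converged else None
        return TMEScoreResults(
            model=self,
            signature=signature,
            scores=scores,
            tme_groups=tme_groups,
            gene_groups=gene_groups,
            gene_clusters=gene_clusters,
            cell_scores=cell_scores,
            consensus_sweep=sweep,
            deg_tables=deg_tables,
            deg_overlap=deg_overlap,
            logrank=lr,
            cox_univariate=cox_uni,
            cox_multivariate=cox_multi,
            enrichment_contrast=contrast,
            report=report,
        )


@dataclass
class TMEScoreResults:
    """Fitted TMEscore artifact plus diagnostics.

    The attributes most callers need: ``signature`` (the frozen gene sets
    and cutpoint), ``scores`` (per-sample tmescore_a/b, tmescore,
    risk_label), ``logrank`` / ``cox_univariate`` (headline statistics) and
    ``report`` (a JSON-serializable stage summary).
    """

    model: TMEScoreModel
    signature: SignatureModel
    scores: pd.DataFrame
    tme_groups: pd.Series
    gene_groups: pd.Series
    gene_clusters: pd.Series
    cell_scores: object
    consensus_sweep: list
    deg_tables: dict
    deg_overlap: pd.DataFrame
    logrank: object
    cox_univariate: object
    cox_multivariate: object
    enrichment_contrast: pd.DataFrame
    report: dict

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        r = self.report
        lines = [
            "TMEscore model results",
            "=" * 58,
            f"Samples / genes          {r['n_samples']} / {r['n_genes']}",
            f"TME subtypes (chosen k)  {r['chosen_k']}  sizes "
            + "/".join(str(c) for c in self.tme_groups.value_counts().sort_index()),
            f"Signature genes          set A {len(self.signature.set_a)}, set B {len(self.signature.set_b)}",
            f"TMEscore cutpoint        {r['cutpoint']:+.4f} (maxstat |Z| = {r['maxstat_statistic']:.3f})",
            f"High / low TMEscore      "
            + " / ".join(str(c) for c in self.scores['risk_label'].value_counts().sort_index()[::-1]),
            f"Log-rank high vs low     chi2 = {self.logrank.chi2:.3f}, p = {self.logrank.p:.3g}",
        ]
        if self.cox_univariate is not None and self.cox_univariate.converged:
            hr = self.cox_univariate.hr.iloc[0]
            lo = self.cox_univariate.ci_lower.iloc[0]
            hi = self.cox_univariate.ci_upper.iloc[0]
            p = self.cox_univariate.wald_p.iloc[0]
            lines.append(f"Cox HR per unit score    {hr:.3f} (95% CI {lo:.3f}-{hi:.3f}, p = {p:.3g})")
        if self.cox_multivariate is not None and self.cox_multivariate.converged:
            lines.append("Multivariate Cox")
            for name in self.cox_multivariate.coef.index:
                lines.append(
                    f"  {name:<22} HR {self.cox_multivariate.hr[name]:.3f} "
                    f"({self.cox_multivariate.ci_lower[name]:.3f}-{self.cox_multivariate.ci_upper[name]:.3f}), "
                    f"p = {self.cox_multivariate.wald_p[name]:.3g}"
                )
        lines.append(f"Orientation              {self.signature.orientation_note}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def km_curves(self) -> dict:
        """Kaplan–Meier curves of the high and low TMEscore groups."""
        out = {}
        clin = self.model.clinical
        for label in ("high", "low"):
            mask = self.scores["risk_label"] == label
            ids = self.scores.index[mask]
            out[label] = km_estimate(clin.os_time.loc[ids], clin.os_event.loc[ids])
        return out

    # -- applying the frozen model ---------------------------------------

    def predict(self, expression: ExpressionMatrix) -> pd.DataFrame:
        """Score a new cohort with the frozen signature (no re-derivation)."""
        return self.signature.score(expression)

    def validate_response_cohort(
        self,
        expression: ExpressionMatrix,
        clinical: ClinicalTable,
    ) -> dict:
        """Frozen-model validation on an immunotherapy cohort.

        Scores the cohort, splits by the cohort's median and upper-quartile
        TMEscore, and reports a log-rank test plus the response-by-group
        chi-square and responder rates for each split.
        """
        if clinical.response is None:
            raise ValueError("validation cohort lacks a response column")
        scored = self.predict(expression)
        common = [s for s in scored.index if s in clinical.data.index]
        scored = scored.loc[common]
        clin = clinical.subset(common)
        tme = scored["tmescore"]
        out: dict = {"n": len(common)}
        for split_name, q in (("median", 0.5), ("upper_quartile", 0.75)):
            cut = float(tme.quantile(q))
            label = pd.Series(np.where(tme > cut, "high", "low"), index=tme.index)
            entry: dict = {"cutpoint": cut, "n_high": int((label == "high").sum()),
                           "n_low": int((label == "low").sum())}
            if entry["n_high"] and entry["n_low"]:
                lr = logrank_test(clin.os_time, clin.os_event, label)
                entry["logrank_chi2"], entry["logrank_p"] = lr.chi2, lr.p
                resp = (clin.response == "responder").astype(int)
                table = pd.crosstab(label, resp).reindex(
                    index=["low", "high"], columns=[0, 1], fill_value=0
                )
                entry["response_rate_high"] = float(resp[label == "high"].mean())
                entry["response_rate_low"] = float(resp[label == "low"].mean())
                try:
                    chi2, dof, p = chi_square_test(table.to_numpy())
                    entry["response_chi2"], entry["response_p"] = chi2, p
                except ValueError as err:
                    logger.warning("response chi-square unavailable: %s", err)
                    entry["response_chi2"] = entry["response_p"] = None
            out[split_name] = entry
        return out
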