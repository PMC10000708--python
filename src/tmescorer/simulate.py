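"""Synthetic cohorts with planted tumor-microenvironment structure.

The generator emulates the statistical shape of a bulk-RNA cohort used for
TME scoring: a TPM expression matrix in which blocks of cell-type signature
genes are shifted in latent TME groups, group-specific differentially
expressed genes are planted on top, survival follows an exponential model
whose hazard depends on a latent risk score, censoring is independent and
uniform, and immunotherapy response is a logistic function of the same
latent score.

Orientation convention
----------------------
The latent score is a *risk* score: samples in the designated adverse group
carry ``+infiltration_effect``, samples in the favorable group
``-infiltration_effect``, everyone else 0. The event hazard is
``baseline_hazard * exp(survival_beta * latent)``, so with the default
``survival_beta = 1`` the adverse group dies fastest. Because TME signature
set A is anchored to the poorer-prognosis samples downstream, the true
TMEscore is proportional to ``-latent``: high TMEscore means longer survival
and (with the default negative ``response_slope``) a higher response rate,
matching the direction the score is designed to have.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection

# 28 immune/stromal cell populations typical of TME deconvolution panels.
CELL_TYPE_NAMES = [
    "Activated_CD8_T_cell", "Central_memory_CD8_T_cell", "Effector_memory_CD8_T_cell",
    "Activated_CD4_T_cell", "Central_memory_CD4_T_cell", "Effector_memory_CD4_T_cell",
    "T_follicular_helper_cell", "Gamma_delta_T_cell", "Type_1_T_helper_cell",
    "Type_17_T_helper_cell", "Type_2_T_helper_cell", "Regulatory_T_cell",
    "Activated_B_cell", "Immature_B_cell", "Memory_B_cell",
    "Natural_killer_cell", "CD56bright_NK_cell", "CD56dim_NK_cell",
    "Myeloid_derived_suppressor_cell", "Natural_killer_T_cell", "Activated_dendritic_cell",
    "Plasmacytoid_dendritic_cell", "Immature_dendritic_cell", "Macrophage",
    "Eosinophil", "Mast_cell", "Neutrophil", "Fibroblast",
]


@dataclass
class CohortConfig:
    """Generating-model parameters for a synthetic cohort.

    Defaults describe the study conditions the package targets: 300 samples
    in three latent TME groups with proportions mirroring the discovery
    cohort (40.1/46.9/13.0%), a two-log2-unit infiltration shift of the
    planted cell-type signatures, 150 group-specific DEGs at log2FC 2,
    unit log-hazard per unit latent risk score, ~30% independent censoring,
    and a logistic response model oriented so that responders concentrate
    where the true TMEscore is high.
    """

    n_samples: int = 300
    n_genes: int = 1000
    n_cell_types: int = 28
    genes_per_signature: int = 10
    n_groups: int = 3
    group_proportions: tuple[float, ...] = (0.401, 0.469, 0.130)
    infiltration_effect: float = 2.0
    n_planted_degs: int = 150
    deg_log2fc: float = 2.0
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0
    noise_sd: float = 1.0
    survival_beta: float = 1.0
    baseline_hazard: float = 0.03  # events per month; median ~23 months at latent 0
    weibull_shape: float = 1.0  # 1.0 = exponential survival
    censoring_rate: float = 0.3
    response_intercept: float = -1.0
    response_slope: float = -1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if len(self.group_proportions) != self.n_groups:
            raise ValueError("group_proportions length must equal n_groups")
        if abs(sum(self.group_proportions) - 1.0) > 1e-8:
            raise ValueError("group_proportions must sum to 1")
        n_signature = self.n_cell_types * self.genes_per_signature
        if n_signature + self.n_planted_degs > self.n_genes:
            raise ValueError(
                f"gene budget infeasible: {self.n_cell_types}x{self.genes_per_signature} signature genes "
                f"+ {self.n_planted_degs} DEGs > {self.n_genes} genes"
            )
        for name in ("baseline_log2_sd", "noise_sd", "baseline_hazard", "weibull_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted: labels, latent risk scores and gene assignments."""

    group_label: pd.Series
    latent_score: pd.Series
    signature_genes: dict[str, list[str]]
    cell_type_group: dict[str, int]
    planted_degs: dict[str, tuple[int, float]]  # gene -> (group, true log2FC)
    survival_beta: float
    adverse_group: int
    favorable_group: int

    @property
    def adverse_deg_ids(self) -> list[str]:
        return [g for g, (grp, _) in self.planted_degs.items() if grp == self.adverse_group]

    @property
    def favorable_deg_ids(self) -> list[str]:
        return [g for g, (grp, _) in self.planted_degs.items() if grp == self.favorable_group]


def _cell_type_names(n: int) -> list[str]:
    names = list(CELL_TYPE_NAMES)
    while len(names) < n:
        names.append(f"Cell_type_{len(names) + 1:02d}")
    return names[:n]


def _calibrate_censoring_horizon(rates: np.ndarray, target: float) -> float:
    """Upper bound ``u`` of Uniform(0, u) censoring achieving P(censored) ~ target.

    For C ~ U(0, u) and T ~ Exp(lam), P(C < T) = (1 - exp(-lam*u)) / (lam*u),
    averaged over the cohort's individual hazards.
    """

    def p_censored(u: float) -> float:
        x = rates * u
        return float(np.mean(np.where(x < 1e-12, 1.0, (1.0 - np.exp(-x)) / np.maximum(x, 1e-300))))

    lo, hi = 1e-9, 1e9
    return brentq(lambda u: p_censored(u) - target, lo, hi, xtol=1e-9, rtol=1e-12)


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GeneSetCollection, GroundTruth]:
    """Simulate one cohort. Fully deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"GENE{i + 1:05d}" for i in range(g)]

    groups = rng.choice(config.n_groups, size=n, p=np.asarray(config.group_proportions))
    adverse_group, favorable_group = 0, config.n_groups - 1

    # --- gene layout ------------------------------------------------------
    names = _cell_type_names(config.n_cell_types)
    signature_genes: dict[str, list[str]] = {}
    cell_type_group: dict[str, int] = {}
    cursor = 0
    for t, name in enumerate(names):
        signature_genes[name] = gene_ids[cursor : cursor + config.genes_per_signature]
        cell_type_group[name] = t % config.n_groups
        cursor += config.genes_per_signature
    planted_degs: dict[str, tuple[int, float]] = {}
    for i in range(config.n_planted_degs):
        planted_degs[gene_ids[cursor + i]] = (i % config.n_groups, config.deg_log2fc)
    cursor += config.n_planted_degs

    # --- expression in log2 space ----------------------------------------
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=g)
    log2x = np.tile(baseline[:, None], (1, n)) + rng.normal(0.0, config.noise_sd, size=(g, n))
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    for name, genes in signature_genes.items():
        mask = groups == cell_type_group[name]
        rows = [gene_pos[gid] for gid in genes]
        log2x[np.ix_(rows, mask)] += config.infiltration_effect
    for gid, (grp, lfc) in planted_degs.items():
        log2x[gene_pos[gid], groups == grp] += lfc

    values = np.exp2(log2x)
    values = values / values.sum(axis=0, keepdims=True) * 1e6
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), "TPM")

    # --- latent risk score and survival ----------------------------------
    latent = config.infiltration_effect * (
        (groups == adverse_group).astype(float) - (groups == favorable_group).astype(float)
    )
    rates = config.baseline_hazard * np.exp(config.survival_beta * latent)
    if config.weibull_shape == 1.0:
        event_time = rng.exponential(1.0 / rates)
    else:
        # Weibull with proportional hazards: S(t) = exp(-rate * t^shape)
        u = rng.uniform(size=n)
        event_time = (-np.log(u) / rates) ** (1.0 / config.weibull_shape)
    if config.censoring_rate > 0:
        horizon = _calibrate_censoring_horizon(rates, config.censoring_rate)
        cens_time = rng.uniform(0.0, horizon, size=n)
    else:
        cens_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, cens_time)
    os_event = (event_time <= cens_time).astype(int)
    os_time = np.maximum(os_time, 1e-6)

    # --- covariates and response -----------------------------------------
    age = np.round(rng.normal(65.0, 8.0, size=n), 1)
    sex = rng.integers(0, 2, size=n)
    p_resp = 1.0 / (1.0 + np.exp(-(config.response_intercept + config.response_slope * latent)))
    response = np.where(rng.uniform(size=n) < p_resp, "responder", "non-responder")

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "age": age,
                "sex": sex,
                "response": response,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    collection = GeneSetCollection(
        {name: list(genes) for name, genes in signature_genes.items()},
        {name: f"synthetic signature, planted in group {cell_type_group[name]}" for name in signature_genes},
    )
    truth = GroundTruth(
        group_label=pd.Series(groups, index=sample_ids, name="group"),
        latent_score=pd.Series(latent, index=sample_ids, name="latent_score"),
        signature_genes=signature_genes,
        cell_type_group=cell_type_group,
        planted_degs=planted_degs,
        survival_beta=config.survival_beta,
        adverse_group=adverse_group,
        favorable_group=favorable_group,
    )
    return expr, clinical, collection, truth


def generate_immunotherapy_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GeneSetCollection, GroundTruth]:
    """A validation cohort with a guaranteed non-null response label.

    Same generating model as :func:`generate_cohort`; exists so that
    validation runs are explicit about requiring the response column.
    """
    expr, clinical, collection, truth = generate_cohort(config)
    assert clinical.response is not None and clinical.response.notna().all()
    return expr, clinical, collection, truth
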