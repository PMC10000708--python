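# Methods

`tmescorer` implements a tumor-microenvironment (TME) scoring workflow for
bulk expression cohorts: quantify immune/stromal cell infiltration per
sample, group samples into TME subtypes, distil the subtype-associated
prognostic genes into two signature sets, and summarize each sample with a
single score whose dichotomization stratifies survival and immunotherapy
response. This note records the models, the defaults and why, the numerical
choices, and what the synthetic-cohort tests do and do not demonstrate.

## Single-sample enrichment (ssGSEA)

For one sample, expression values are converted to ranks `r_g ∈ {1..N}`
(highest value → rank `N`; ties receive average ranks). Walking the genes
in order of decreasing rank, the in-set running sum grows by
`r_g^α / Σ_{g∈S} r_g^α` at member genes and the out-of-set sum by
`1/(N−m)` elsewhere; the score is the **sum over all N positions** of the
difference of the two running sums (the integral form used for
single-sample scoring), not the maximum deviation used by classic GSEA.
`α = 0.25` by default. Two consequences are load-bearing and tested:

* the score depends on expression only through within-sample ranks, so any
  strictly monotone per-sample transform (library-size scaling, log) leaves
  it unchanged;
* residual ordering ties after ranking are broken by input gene order
  (stable sort), making scores deterministic.

Per-set scores across a cohort are rescaled to the unit interval
("unity normalization": `(x − min)/(max − min)` per set; a constant row
becomes all zeros with a warning).

Purity estimation follows the ESTIMATE idea: stromal and immune gene-set
scores are summed and mapped through `cos(c0 + c1·score)`. The cosine
constants default to the values published for the original ESTIMATE score
scale; because our enrichment scale differs, the resulting "purity" is
monotone-faithful (ranks samples correctly) but not a calibrated fraction.

Classic preranked GSEA (maximum-deviation statistic, weight `|stat|^p`) is
provided with a gene-label permutation null: NES divides the ES by the mean
|null ES| of matching sign, and the permutation p-value is the sign-matched
tail frequency with +1 smoothing. Under a random gene set the p-values are
uniform (tested by Kolmogorov–Smirnov).

## Consensus subtyping

Monti-style consensus clustering: in each of `reps` iterations (default
1000; simulation-scale runs use 100), `⌈0.8·n⌉` items are drawn without
replacement and clustered by the base clusterer; the consensus matrix entry
is co-clusterings / co-samplings. Sample subtyping uses complete-linkage
hierarchical clustering with Manhattan distance as the base; gene
clustering uses Ward/Euclidean (the source convention "k-means with Ward.D
linkage" is internally inconsistent — k-means has no linkage — so
Ward/Euclidean hierarchical clustering is the default base and
`kmeans_euclidean` is available via config). Final labels cut an
average-linkage tree of `1 − consensus`.

**Choosing k.** The classic CDF delta-area criterion is computed and
reported, but it is not the default decision rule: on our cohorts the
relative delta area stays above the conventional 0.1 threshold well past
the true k (measured 0.49/0.21/0.13/0.12 for k = 2..5 on clean 3-group
data), a known bias of the area criterion. The default rule is therefore
the PAC (proportion of ambiguous clustering) criterion: the fraction of
off-diagonal consensus values in (0.1, 0.9), with the chosen k the largest
k whose PAC is ≤ 0.1 and a fallback of k = 2 when nothing is stable. On
planted 3-group cohorts PAC is exactly 0 at k = 3 and ≥ 0.19 at k = 4; on
i.i.d. noise PAC exceeds 0.9 everywhere and the rule returns 2.

## Differential expression

Two-group contrasts use an empirical-Bayes moderated t on log2(TPM+1):
per-gene pooled variances `s_g²` (d = n−2 df) are shrunk toward a prior
`s0²` with prior df `d0`, both estimated in closed form by matching the
first two moments of `log s_g²` to a scaled-F model (the trigamma-inverse
construction). The moderated statistic uses
`s̃² = (d0·s0² + d·s_g²)/(d0 + d)` with `d0 + d` degrees of freedom.
Setting `d0 = 0` recovers the ordinary pooled t exactly (tested to 1e-10);
`d0 → ∞` tests every gene against the common prior variance. A DEG has
|log2FC| **strictly** greater than 1 and Benjamini–Hochberg adjusted
p < 0.05.

For k subtypes, each group is contrasted against the rest. A group's DEG
*set* contains only the genes **over-expressed** in it: a gene elevated in
one group necessarily reappears as down-regulated in the other groups'
contrasts, so two-sided sets would overlap by construction, while
up-regulated sets are group-specific (and empirically disjoint on planted
cohorts). Groups with fewer than two samples are skipped with a warning.

## Signature derivation and the TMEscore

1. **Random-forest contribution filter.** A 500-tree random forest
   (features = DEGs, target = TME subtype) is grown with
   `min_samples_leaf = 10`; genes are ranked by classical per-tree
   out-of-bag permutation importance (mean decrease in accuracy) and
   retained if importance > 0. Two deliberate choices: per-tree OOB
   importance (rather than whole-forest held-out importance) stays
   informative when many genes are correlated — a saturated forest loses no
   held-out accuracy when one of many redundant genes is permuted — and the
   leaf-size floor keeps noise genes out of deep overfit splits, so they
   are mostly never used and score exactly zero. On planted data (30
   informative among 330, n = 150) this retains all informative genes and
   drops >80% of noise genes. A `top_n` rule is available.
2. **Prognostic filter.** Univariate Cox per gene on log2(TPM+1); retain
   Wald p < 0.05. The screen is a vectorized Newton–Raphson on the Efron
   partial likelihood (all genes simultaneously; agrees with per-gene
   lifelines fits to ~1e-7 without ties) because fitting hundreds of genes
   one at a time is needlessly slow.
3. **A/B split.** The surviving genes are consensus-clustered at k = 2
   (Ward/Euclidean on z-scored log2 expression), and the samples are
   likewise grouped at k = 2 on the same genes. The sample group with the
   log-rank excess of observed deaths is the poorer-prognosis group; the
   gene cluster with the higher mean z-scored expression in that group
   becomes **set A** (adverse), the other **set B**. Orientation is
   recorded in the fitted model.
4. **Score.** `TMEscore = ssGSEA(set B) − ssGSEA(set A)` per sample, on raw
   (like-scaled) component scores by default; a flag normalizes the
   components first. By construction high TMEscore tracks the
   favorable-prognosis expression program.
5. **Dichotomization.** The maximally selected rank statistic: candidate
   cutpoints are midpoints between consecutive distinct score values
   leaving at least `⌈0.1·n⌉` samples on each side; the cutpoint maximizing
   the standardized log-rank |Z| wins (ties → smaller cutpoint). The
   statistic is used for *selection only*: a log-rank p-value recomputed on
   the selected split is anti-conservative (measured type-I rate ≈ 0.4 at
   nominal 0.05 on null data), which is why the selection statistic itself
   is reported separately and downstream confirmation should come from
   independent cohorts, as in the frozen-model validation.

Survival machinery: Kaplan–Meier and final Cox models (Wald 95% CIs, Efron
ties) are delegated to lifelines; the standardized log-rank statistic is
implemented directly (it is maxstat's inner loop) and cross-checked against
lifelines and a hand-tabulated O/E/V oracle. The log-rank z is reported
with sorted group levels, so its sign is deterministic. A score test of
β = 0 for a single covariate is provided and equals the log-rank chi-square
without ties (verified to 1e-8).

## Synthetic cohorts: what they emulate and what they do not

`CohortConfig` defaults describe the study conditions the tests target:
300 samples in three latent TME groups with proportions (0.401, 0.469,
0.130) mirroring the discovery cohort's subtype fractions; 28 cell-type
signature blocks of 10 genes whose log2 expression is shifted by
`infiltration_effect = 2` in the group each cell type is assigned to; 150
group-specific DEGs at log2FC 2; i.i.d. Gaussian log2 noise (SD 1) around
gene baselines N(3, 1); columns rescaled to TPM.

The **latent score is a risk score**: samples in the designated adverse
group carry `+infiltration_effect`, the favorable group
`−infiltration_effect`, others 0, and the event hazard is
`baseline_hazard · exp(survival_beta · latent)` (default β = 1, baseline
0.03 events/month, i.e. median survival ≈ 23 months at latent 0 —
pancreatic-cancer-like). Censoring is independent Uniform(0, u) with `u`
solved in closed form so the expected censored fraction matches
`censoring_rate` (default 0.3). Survival is exponential by default for
closed-form checks; a Weibull shape parameter is configurable. Response is
Bernoulli(logistic(−1 − 1.5·latent)): the negative slope puts responders
where the true TMEscore is high, matching the direction the score is meant
to have, with an overall responder rate ≈ 27% at latent 0. All randomness
flows from one seeded generator; identical configs and seeds reproduce
byte-identical cohorts.

Deliberately **not** modeled: gene-length and library-size biases, batch
effects, count noise (expression is log-normal, not negative binomial),
correlated survival covariates, informative censoring, and any overlap
between cell-type signatures. Passing tests therefore demonstrate that the
pipeline recovers structure *of the kind it assumes*, at realistic sizes
and noise — not that it is robust to the full messiness of real tumor
cohorts, where signature cross-talk and batch structure can blur subtypes.

## Problem sizes and numerical choices

Simulation-based checks run at the sizes stated in their docstrings —
typically 300 samples × 1000 genes with 100 consensus resamples per k for
end-to-end runs (a full fit ≈ 5 s), 10–20 seeds for recovery rates, 200
replicates for CI coverage — chosen so the whole suite completes in a few
minutes while leaving Monte-Carlo margins well away from the asserted
bounds. The pipeline default of 1000 resamples matches the published
protocol and is what `run-all` uses unless configured otherwise.

Other numerics: Newton iterations stop at |Δβ| < 1e-10 (Cox screen) with
steps clipped to ±2; the trigamma inverse uses the standard Newton update
with asymptotic guards; exp() arguments in the partial likelihood are
clipped at ±500 after covariate centering (Cox estimates are
shift-invariant); BH adjustment delegates to statsmodels; Mann–Whitney
p-values are exact for groups of ≤8 and normal-approximated above;
chi-square tests are Pearson without continuity correction; 0/0 consensus
entries (never co-sampled pairs) become 0 with a warning — vanishingly rare
at `reps ≥ 100`, `p_item = 0.8`.

## Known limitations

* The score scale depends on the gene universe size, so cutpoints are
  cohort-specific; cross-cohort validation deliberately re-splits at the
  cohort's own median/upper quartile rather than transferring the cutpoint.
* `select_k` is a stand-in for the visual CDF inspection used in practice;
  both PAC and delta-area are reported so a user can disagree with the
  default rule.
* The RF retention rule ("importance > 0") has no significance guarantee;
  it is a screening heuristic, deliberately followed by the prognostic
  filter.
* Purity values are rank-level only (see above).
* Validation-cohort scoring drops signature genes missing from the new
  platform and aborts below 50% coverage per set; no cross-platform
  identifier mapping is attempted.
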