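# tmescorer

Tumor-microenvironment (TME) scoring for bulk expression cohorts.

Solid tumors — pancreatic ductal adenocarcinoma being the extreme case —
embed their malignant cells in a microenvironment of immune cells,
fibroblasts and stroma that shapes prognosis and the response to immune
checkpoint blockade. `tmescorer` turns a gene-by-sample expression matrix
plus survival data into a single per-sample **TMEscore** that summarizes
that microenvironment, for computational oncologists who want a
reproducible, testable version of the workflow:

1. quantify the relative abundance of TME cell populations per sample by
   single-sample GSEA (ssGSEA) over cell-type signature gene sets, with
   per-set unity normalization;
2. find TME subtypes by consensus clustering of the normalized scores
   (resampled complete-linkage/Manhattan clustering; the number of
   subtypes chosen by consensus stability);
3. derive signature genes: one-vs-rest moderated-t DEGs per subtype
   (|log2FC| > 1, BH-adjusted p < 0.05), narrowed by random-forest
   out-of-bag permutation importance and a univariate Cox prognostic
   filter;
4. split the surviving genes into two consensus clusters, anchor **set A**
   to the poorer-prognosis expression program and **set B** to the other,
   and score every sample as

   ```
   TMEscore = ssGSEA(set B) − ssGSEA(set A)
   ```

5. dichotomize the score at the maximally selected rank statistic (the
   cutpoint maximizing the standardized log-rank |Z|) and report
   Kaplan–Meier / log-rank / Cox statistics, plus frozen-model validation
   on an immunotherapy cohort (median and upper-quartile splits, response
   chi-square).

High TMEscore tracks the favorable-prognosis, immunologically active
microenvironment: longer overall survival and higher checkpoint-blockade
response rates.

Because the real discovery data are controlled-access tumor cohorts, the
package ships a first-class synthetic-cohort generator
(`tmescorer.simulate`) that plants known cell-type structure, DEGs,
survival effects and response links, so every stage is testable against
ground truth. See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
from tmescorer import (CohortConfig, PipelineConfig, TMEScoreModel,
                       generate_cohort, generate_immunotherapy_cohort)

# a synthetic discovery cohort: 300 samples, 3 planted TME groups
expr, clinical, cell_sets, truth = generate_cohort(CohortConfig(seed=1))

model = TMEScoreModel(expr, clinical, cell_sets, PipelineConfig(reps=100))
results = model.fit(seed=1)
print(results.summary())
```

prints

```
TMEscore model results
==========================================================
Samples / genes          300 / 1000
TME subtypes (chosen k)  3  sizes 127/33/140
Signature genes          set A 138, set B 248
TMEscore cutpoint        -331.0242 (maxstat |Z| = 13.959)
High / low TMEscore      126 / 174
Log-rank high vs low     chi2 = 194.867, p = 2.75e-44
Cox HR per unit score    0.996 (95% CI 0.996-0.997, p = 3.75e-33)
Orientation              set A = gene cluster 1 (mean z +0.823) over-expressed in the poorer-prognosis sample group 1; set B = gene cluster 2
==========================================================
```

Reading the numbers: the consensus stage recovered the three planted
subtypes (sizes 127/33/140); 386 genes survived the DEG → random-forest →
prognostic filters and split into an adverse set A and favorable set B;
the maxstat cutpoint divides the cohort into 126 high- and 174 low-score
samples whose survival curves separate decisively (log-rank p ≈ 3e-44,
the planted hazard structure). The Cox hazard ratio is per unit of the
raw score — below 1 because higher TMEscore means lower hazard.

Validating the frozen signature on an independent response cohort:

```python
vexpr, vclin, _, _ = generate_immunotherapy_cohort(CohortConfig(seed=2))
val = results.validate_response_cohort(vexpr, vclin)
print(val["median"])
```

```
{'cutpoint': 160.55, 'n_high': 150, 'n_low': 150,
 'logrank_chi2': 83.16, 'logrank_p': 7.57e-20,
 'response_rate_high': 0.353, 'response_rate_low': 0.147,
 'response_chi2': 17.08, 'response_p': 3.58e-05}
```

— the high-TMEscore half of the validation cohort survives longer and
responds to therapy 2.4× as often, without re-deriving any gene set.

The same workflow is scriptable from the shell:

```bash
tmescorer simulate --out-dir data --seed 1
tmescorer run-all --expr data/expression.tsv --gmt data/cell_signatures.gmt \
                  --clinical data/clinical.tsv --seed 1 --out-dir run
tmescorer score --expr new_cohort.tsv --model run/signature_model.json --out scores.tsv
```

with further subcommands (`tpm`, `ssgsea`, `cluster`, `deg`,
`select-genes`, `build-signature`, `cutpoint`, `survival`, `gsea`,
`validate`) exposing each stage individually.

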