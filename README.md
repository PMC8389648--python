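# gsreg — gene set regularity functionome analysis

`gsreg` screens two-group expression studies (cases vs normal controls)
for *dysregulated biological functions* rather than differentially
expressed genes. It implements a rank-conservation statistic in the
DIRAC family, developed for comparing serous ovarian tumours (borderline
tumours and carcinomas of all FIGO stages) against normal ovarian
tissue over a GO-defined gene set collection, and is intended for
bioinformaticians analysing microarray or RNA-seq intensity matrices
with case/control annotations.

## The model

For a gene set *G* with *m* measured genes, the control cohort defines a
**pairwise-ordering template**: for each of the C(*m*, 2) unordered gene
pairs, the direction ("gene *a* expressed below gene *b*") chosen by the
majority of control samples — the most common gene expression ordering.
A sample's **gene set regularity (GSR) index** for *G* is

    GSR(s, G) = #{pairs whose ordering in s matches the template} / C(m, 2)

so GSR = 1 means the sample preserves the control ordering exactly,
GSR = 0 means every pair is reversed, and a uniformly random ordering
scores 0.5 in expectation. The vector of GSR indices over every gene
set in the collection is the sample's **functionome**.

Downstream, each gene set's per-sample GSR values are compared between
cases and controls with a two-sided Mann–Whitney U test and
Benjamini–Hochberg FDR adjustment. Significant terms are ranked by the
**cluster weight index** CWI_t = w_t / Σ_u w_u with w = −log10(max(q, ε)),
clustered on the GO `is_a` graph; pathways are separately ranked by raw
p-value, and the per-group top-k pathway lists can be intersected across
disease groups to find shared candidates. Functionome profiles are also
classified case-vs-control with an RBF-kernel SVM under stratified
5-fold cross-validation repeated 10 times (sensitivity, specificity,
accuracy, AUC). A synthetic-cohort generator with known ground truth
makes every stage testable without external data.

## Worked example

```python
from gsreg import (SimulationConfig, simulate_cohort, build_templates,
                   functionome, compare_groups, compute_cwi, group_summary,
                   cross_validated_svm)

config = SimulationConfig(n_genes=500, n_sets=50, set_size=10,
                          n_controls=30, n_cases=30,
                          frac_dysregulated=0.2, scramble_intensity=1.0,
                          noise_sd=0.1, seed=42)
matrix, collection, truth = simulate_cohort(config)
templates = build_templates(matrix, collection, "control")
profiles = functionome(matrix, collection, templates)
cases = profiles.loc[matrix.group_samples("case")]
controls = profiles.loc[matrix.group_samples("control")]

summary = group_summary(cases, controls)
table = compute_cwi(compare_groups(cases, controls))
report = cross_validated_svm(profiles, matrix.groups, "case", seed=42)
```

prints (via the obvious `print` calls):

```
case mean GSR    0.8852
control mean GSR 0.9863
significant sets 11 / 50 (truth: 10)
         case_mean  control_mean    q     cwi
set_id
SET0004     0.4674        0.9978  0.0  0.0983
SET0025     0.4889        0.9970  0.0  0.0983
SET0048     0.4600        0.9956  0.0  0.0982
             mean  min  max
sensitivity   1.0  1.0  1.0
specificity   1.0  1.0  1.0
accuracy      1.0  1.0  1.0
auc           1.0  1.0  1.0
```

Reading: controls sit near GSR 1 (their ordering *is* the template up
to measurement noise); the ten truly scrambled sets drop to ≈ 0.5 in
cases, pulling the case grand mean down to 0.885. The screen recalls
all 10 planted sets (plus one false positive at this seed, consistent
with FDR control at q < 0.05, not per-set error control); fully
scrambled sets are so far from the control ordering that the SVM
separates the groups perfectly.

The same pipeline runs from the shell: `gsreg simulate`, `gsreg gsr`,
`gsreg rank`, `gsreg classify`, `gsreg select` (see `gsreg --help`).
`gsreg select` also scores immunohistochemistry validation tables with
the composite Q = intensity grade (0–3) × percent positive cells
(0–100), maximum 300, and flags candidate genes against the EMT
biomarker panel (CDH1, CTNNB1, SNAI1, SNAI2, TWIST1). The package
bundles the published per-group top-50 dysfunctional-pathway rankings
for the serous ovarian tumour groups; intersecting them yields the
single shared pathway, aryl hydrocarbon receptor binding (GO:0017162).

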