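# Methods

## The GSR index

Let a gene set *G* contain *m* ≥ 2 genes measured in every sample. Each
control sample orders the genes by expression; for each unordered pair
{g_i, g_j} the **template direction** is the ordering chosen by the
majority of controls, and its **support** is the fraction of controls
voting that way (by construction in [0.5, 1]). A sample's GSR index for
*G* is the fraction of the C(m, 2) pairs whose in-sample ordering
matches the template. The index is a pure rank statistic: it is
invariant under any strictly increasing per-sample transform of the
expression values, which is what makes pooling heterogeneous intensity
scales defensible. Its endpoints are definitional — 1 for a sample that
reproduces the control ordering, 0 for a complete reversal — and a
uniformly random ordering has expectation 0.5 because each pair matches
an arbitrary fixed template with probability ½.

**Ties.** Expression ties within a sample, and exact 50/50 template
votes, are resolved by a single deterministic rule: the
lexicographically smaller gene symbol is deemed lower. Applying the
same rule during template construction and scoring keeps the two sides
symmetric; tied template votes are stored with support 0.5. Real
intensity data rarely ties, but integer-quantised data does, and an
undefined tie would otherwise leak platform-dependent ordering into the
statistic.

**Template scope.** One template per gene set is built from the pooled
control group and reused for every case group. Per-control-cohort
templates would be a straightforward variant but are not implemented;
with per-dataset controls the pooled template is the only choice that
gives all case groups a common reference.

**Set restriction.** Gene sets are intersected with the measured genes
before any computation; sets falling below `min_set_size` (default 5,
floor 2) are dropped. Very small sets make the index coarse — a 2-gene
set can only score 0 or 1 — so the default trades a little coverage for
index resolution.

## Dysregulation screening

Per gene set, the case and control GSR samples are compared with a
two-sided Mann–Whitney U test: exact enumeration when n₁ + n₂ ≤ 20 and
the pooled values are tie-free, otherwise the tie-corrected normal
approximation (scipy's implementation in both regimes). The fully
degenerate input — every GSR value identical in both groups — is
defined to give p = 1, so constant null profiles never register as
findings. P-values are Benjamini–Hochberg adjusted across all sets and
flagged at q < α (default 0.05).

Two rankings are derived from the same table, mirroring the two ways
screens of this kind are reported:

* **Dysregulated terms by CWI.** Each significant term gets weight
  w = −log10(max(q, ε)) with ε = 10⁻¹⁶ guarding q = 0; the cluster
  weight index divides each weight by the total weight of all
  significant terms, so CWIs sum to 1 and rank terms by share of the
  overall significance mass. When a GO `is_a` graph is supplied,
  terms are additionally labelled with the connected component
  (cluster) of the significant subgraph they belong to; without a
  graph all significant terms form one cluster. A variant that
  multiplies each weight by the absolute SVM feature weight is
  available via the `svm_weights` argument.
* **Dysfunctional pathways by p-value.** Sets passing a configurable,
  less stringent threshold (default raw p < 0.05) ranked by ascending
  p and truncated to the top k (default 50). Ties in either ranking
  break lexicographically by set identifier, keeping output order
  deterministic.

Group-level dysregulation is summarised as the grand mean GSR over all
sets and samples of the case group, reported next to the control grand
mean rather than divided or subtracted — the appropriate "correction"
depends on the study design, so the raw pair is the primary output.

## Classification

Functionome profiles are classified case vs control with an RBF-kernel
SVM under stratified k-fold cross-validation (default k = 5) repeated
r times (default r = 10) with per-repeat reshuffling seeded from a
single integer. Stratification keeps both classes in every fold under
the heavy class imbalance typical of tumour/control designs. Within a
repeat, out-of-fold predictions are pooled into one confusion table
(per-fold averaging is available by flag but pooled is the default —
per-fold rates are noisy at tens of samples); AUC is computed from the
pooled decision values by the rank (Mann–Whitney) formulation with
ties counted ½, which the tests cross-check against the U statistic.
The kernel bandwidth uses the median heuristic, gamma = 1/(2·median²)
of the pairwise sample distances, and C = 1; both are exposed since the
method's published description names only "kernel-based SVM".

## Target selection

Per-group top-k pathway lists are intersected; each common pathway is
reported with its 1-based rank in every group and ordered by mean rank.
Gene-level candidates are ranked by **repetitive frequency** — the
number of selected GO terms annotating the gene — with deterministic
ties, and flagged against the EMT biomarker panel (CDH1, CTNNB1, SNAI1,
SNAI2, TWIST1). The bundled reference data for the serous ovarian
tumour study (five top-50 pathway lists; the 25 shared dysregulated
terms with expert semantic categories and most-repeated genes) are
consumed as fixtures: the category assignment was expert curation and
is input, never recomputed. Survival-based filtering of candidates is
out of scope; an external keep/drop list can be applied downstream.
Immunohistochemical validation tables are scored as Q = I × P
(intensity grade 0–3 × percent positive cells 0–100, maximum 300).

## Synthetic cohorts

The generator emulates the ordering structure the index detects, not
microarray physics. Every gene gets a distinct baseline (evenly spaced
levels, shuffled, with sub-spacing jitter so the canonical ordering is
unambiguous); controls are baseline + N(0, σ²); in each of the
round(f · n_sets) dysregulated sets, each case sample independently has
⌈θ·m⌉ of the set's m genes' baselines permuted among themselves before
noise. Per-sample scrambling makes cases exchangeable draws from a
disordered distribution — lost regularity — rather than a cohort with a
coherent alternative ordering; at θ = 1 the expected case GSR is 0.5.
Defaults (200 disjoint sets of 10 genes, 30 controls vs 30 cases,
f = 0.2, θ = 1, σ = 0.1 on a baseline range of 4–12) give a cohort
where the screen should operate near its design point: the validation
suite checks ≥ 95% sensitivity and precision there, ≤ 5% discovery
proportion under f = 0 across 20 seeds, and monotone decline of the
case mean GSR in θ. Problem sizes in the suite (20–200 sets, 30–50
samples per arm) were chosen as the smallest cohorts at which these
operating characteristics are stable.

What the generator does **not** emulate: probe-level noise, batch and
platform effects, correlated genes within or across sets, overlapping
set memberships (available behind a flag but off by default), missing
data, or survival outcomes. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model,
not that real cohorts of any particular composition will reproduce any
published effect size.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng(seed)`; a
  config plus seed reproduces a cohort bit-exactly, and the
  classification report is deterministic given its seed.
* Template votes use exact float comparison; support of a tied pair is
  stored as 0.5 exactly, and tie detection uses `isclose` against 0.5
  to be safe under vote-count division.
* Duplicate gene rows on ingest collapse by per-sample maximum —
  deterministic, monotone and platform-agnostic; profiles with any
  missing cell are dropped whole, logged at warning level.
* BH adjustment and exact/asymptotic Mann–Whitney come from
  statsmodels and scipy respectively; the GSR index, CWI, AUC and the
  intersection/frequency logic are implemented here and validated
  against independent oracles (pair enumeration, U-statistic
  equivalence, counting) in the test suite.

## Known limitations

* Probe-to-symbol mapping and cross-platform normalisation are the
  caller's responsibility; inputs are assumed gene-symbol keyed.
* The CWI clustering labels components but the normalisation is global
  over all significant terms; per-cluster normalisation would change
  the index's interpretation and is not provided.
* The exact published rule for condensing per-group CWI rankings to a
  shared top-25 term list is not algorithmically specified; the
  mean-rank intersection machinery is provided, and the published
  25-term list ships as reference data rather than a reproduction
  claim.
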