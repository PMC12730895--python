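# Methods

This note documents the model, the derivation rules and their default
parameters, the synthetic-data generator, and the numerical and design
choices made where the procedure was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Score model

The score is a weighted sum of z-scored biomarkers. On a discovery cohort
with binary RECIST outcomes (CR/PR → responder, SD/PD → non-responder, any
other label → unknown and excluded from fitting):

1. **Screening.** Categorical candidates (`resistance_flag`,
   `response_flag`) are tested with two-sided Fisher's exact test on the
   presence × outcome 2×2 table; continuous candidates with the two-sided
   Mann–Whitney U test. Selection threshold α = 0.05. Missing values are
   dropped pairwise per biomarker; a biomarker constant across samples is
   auto-rejected because its test is undefined.
2. **Correlation pruning.** Among selected pairs with Spearman |ρ| > 0.5
   (average ranks for ties; absolute value guards anti-correlated
   duplicates), the member with the smaller effect size is rejected,
   iterating in descending-|ρ| order until no violating pair remains.
3. **Weights.** w_b ∝ −log₁₀ p_b, normalized to sum to one. p-values are
   floored at 1e-300 before the log for numerical safety.
4. **Standardization.** μ_b and σ_b are the discovery-cohort mean and
   sample SD (n−1 denominator); σ_b = 0 is a fitting error. Binary flags
   are z-scored like any other selected biomarker (a flag exists to pass
   them raw, but the default treats the formula literally).
5. **Cutoff.** The threshold maximizing Youden's J = sensitivity +
   specificity − 1 on the discovery ROC. Ties break toward the smallest
   threshold (the more sensitive classifier); classification is "high" iff
   score > cutoff, so a score exactly at the cutoff is "low" — conservative
   toward not recommending therapy.

**Effect sizes for pruning.** "Smaller effect" is not defined by the
procedure's description, so comparable [0, 1] magnitudes are used: the
rank-biserial correlation |2U/(n₁n₂) − 1| for continuous biomarkers and
|tanh(log OR / 2)| (Yule's Q magnitude, Haldane-corrected odds ratio) for
flags. Exact ties break toward the earlier candidate in the canonical
biomarker order.

**Mann–Whitney variant.** Exact enumeration when both groups have ≤ 8
observations and no ties; otherwise the normal approximation with tie and
continuity correction. Both one-sided directions are of interest, so all
tests are two-sided.

**Missing data.** A sample missing a selected biomarker cannot be scored;
nothing is imputed by default (optional mean-imputation must be requested
explicitly by passing the discovery means). Panels mark missing fields
explicitly — a missing input never silently becomes zero.

## Biomarker derivations and QC

All thresholds live in `QcThresholds` with these defaults:

| rule | default | comparison |
|---|---|---|
| tumor / normal mean coverage | 60× / 20× | fail if below |
| tumor-normal SNP correlation | 0.80 | fail if below |
| somatic variants seen in gnomAD | 0.70 | fail if above |
| tumor content | 0.30 | fail if below |
| variant read depth (both samples) | 20× | keep if ≥ |
| variant allele frequency | 5% | keep if strictly > |
| supporting reads | 3 | keep if ≥ |
| CNV loglikelihood | 100 | keep if strictly > |

Tumor content, when not provided by the CNV caller, is 2 × median of the
15 highest VAFs, capped at 1 (heterozygous clonal variants in a diploid
tumor sit at VAF ≈ purity/2; the multiplier is configurable since only the
median rule itself is fixed). With fewer than 15 variants all are used;
with none, tumor content is undefined and the sample is flagged for manual
review rather than auto-failed. QC reports list every failed rule.

**Target region.** Per study: bases covered ≥ 20× in at least half of the
normal samples (real-valued n/2: 2 of 4 passes, 1 of 3 fails), intersected
with exons padded ±2 bases. The common region is the exact intersection of
the study regions. Intervals are 0-based half-open; variant positions
1-based; adjacent intervals merge so base arithmetic is unambiguous. TMB
counts variants with impact strictly above "protein altering" (levels
`moderate`/`high` of the packaged VEP-consequence table) inside the region,
divided by region megabases.

**Repertoire entropy.** α-chain clones with count ≥ 2; H = −Σ pᵢ ln pᵢ in
nats ("log" is taken as the natural log; base is configurable via the
formula itself being one line). Zero or one retained clone gives H = 0.

**Resistance/response flags.** Deleterious = homozygous deletion
(copy number 0 overlapping the gene per the CNV call's gene annotation) or
SNV/indel with high impact or a COSMIC CMC tier. The resistance flag
additionally requires the alteration in the main clone: VAF ≥ 0.8 × tumor
clonality for small variants and, analogously, CNV clonality ≥ 0.8 × tumor
clonality (the source procedure reads main-clone status "directly from the
CNV calls" without a numeric rule; the same 80% fraction is applied).
Tumor clonality is interpreted on the same scale as the CNV clonality
field. "CALX" in the published resistance gene list is not an HGNC symbol
and is resolved as an alias of *CANX* (calnexin); *PDL1* resolves to
*CD274*. The response flag ignores clonality entirely and excludes
variants of unclear significance (high impact without CMC, or vice versa).

**HLA allele loss and divergence.** A locus loses an allele when a
deleting CNV (copy number < 2) overlapping the HLA gene has clonality
≥ 0.25, or when the per-allele tumor/normal assigned-read ratios (r₁, r₂)
satisfy |r₁ − r₂| / max(r₁, r₂) > 0.40 (the published ">40% deviation" is
ambiguous; this formula is recorded and configurable). The allele with the
smaller ratio is the lost one; neoantigen candidates restricted to a lost
allele do not count. HED per locus is 0 for homozygous or loss-flagged
loci, else the mean per-aligned-site Grantham distance over the
binding-groove alignment (gap positions excluded), and the sample value
averages loci A, B, C (per-locus values are always reported). The packaged
Grantham matrix is generated from the classical composition / polarity /
molecular-volume formula (α = 1.833, β = 0.1018, γ = 0.000399, ρ = 50.723,
integer-rounded); a few entries differ by one unit from commonly reprinted
tables whose original rounding is not exactly reproducible. The packaged
binding-groove allele table is **synthetic** (seeded random aligned
sequences with realistic pairwise divergence) — it exercises the
divergence arithmetic, not real IMGT/HLA sequence content.

**Expression.** CPM = 1e6 × count / library size. The combined chemokine
marker is the mean over *CXCL9/10/11* of log₂((CPM + 1) / (median cohort
CPM + 1)); the cohort median is the fold-change reference because the
source defines none, and the median is robust and batch-neutral. This
marker is computed and reported but is not a default fit candidate.
Expression inputs are assumed batch-homogeneous or pre-corrected.

## Evaluation

ROC points are generated with the strict `score > threshold` convention
(thresholds are the distinct scores plus −∞) so the Youden cutoff composes
exactly with the classifier's tie rule; the trapezoidal AUC then equals
the tie-corrected pair-concordance probability U/(n₁n₂). Kaplan–Meier
curves come from lifelines. The univariate Cox model (binary group) uses
the Breslow tie convention, Newton–Raphson on the partial likelihood, and
Wald confidence intervals and p-values; a group without events or a
monotone likelihood (complete event-order separation, detected as
|β| > 35) raises a diagnostic error instead of returning a silent
estimate. The stratified response table uses TMB > 10 mutations/Mb (the
regulatory cutoff) and TCR entropy above the cohort median by default —
the published stratification thresholds are not stated, so both are
parameters; empty strata report an undefined (NaN) rate. Survival times
are in days.

## Synthetic-data generator

`simulate_panels` draws two outcome groups: continuous biomarkers from a
Gaussian copula (target Spearman ρ converted to latent Pearson r =
2 sin(πρ/6); a non-PSD specification is a config error) with
responder-group location shifts in latent-SD units, log-normal marginals
for burdens and CPMs and normal marginals for entropy and divergence;
flags as per-group Bernoulli draws. Default conditions mirror the
discovery study: 225 samples with 98 responders; burden, entropy, response
flag and PDL1 informative; neoantigen burden correlated with TMB at
ρ = 0.8 (so pruning removes it); resistance events rare (~1%) as observed.
`simulate_survival` draws exponential event times with a planted group
hazard ratio (default 0.48) and censors each subject independently with
the configured probability at a uniform fraction of its event time, so the
censoring fraction matches the rate in expectation and rate 1 produces the
no-events diagnostic. `simulate_raw_sample` emits parseable
variant/CNV/clone/neoantigen/count/HLA files whose derived biomarkers
match an emitted `truth.json` exactly (counts, flags) or to floating
tolerance (entropy, CPM). A single root seed expands into named
counter-based streams, so outputs are byte-identical per seed and
independent of generation order.

What the generator does **not** emulate: sequence content (CDR3s and
peptides are random strings), mutational signatures, batch effects,
read-level data, or cohort heterogeneity across studies. Passing tests
therefore demonstrate correctness of the derivations, the statistics and
their calibration under the stated sampling model — not clinical
performance on real cohorts, which requires the original
controlled-access data.

## Simulation-study designs

Problem sizes were chosen so each study has adequate power while staying
desk-scale:

- **Planted-effect recovery** (200 reps): n = 50/50, TMB shifted +1.5
  latent SD and entropy +0.9, other biomarkers null. The +0.9 secondary
  effect balances selection power (~99%) against p-value-order stability
  (~98%), putting the joint success probability near 97%.
- **Null calibration** (1000 reps): n = 150/150, all shifts zero, flags at
  prevalence 0.5. Fisher's exact test is conservative on discrete tables —
  its exact size at 50/50 samples and prevalence 0.5 is 3.5%, and a
  near-zero-prevalence flag cannot calibrate any test — so the calibration
  design uses the larger groups (exact Fisher size 4.3% by full
  enumeration) and maximally informative flags.
- **Hazard-ratio recovery** (200 reps): n = 400, planted HR 0.5, 20%
  censoring; the Wald SE of log HR is ≈ 0.11 at ~320 events, so the
  [0.40, 0.62] band is close to a 95% interval.

## Known limitations

- The groove allele table is synthetic; real HED values require IMGT/HLA
  alignments supplied by the user in the same TSV format.
- The Cox routine is univariate with a binary covariate by design;
  multivariable modeling is out of scope.
- Fisher's exact test is conservative at low prevalence: rare flags (like
  resistance events at ~1%) are essentially never selected at realistic
  cohort sizes, mirroring the discovery study's own rejection of the
  resistance biomarker.
- Streaming very large VCFs is not supported; cohorts are desk-scale
  tables.
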