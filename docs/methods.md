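# Methods

`metacurate` implements the computational core of a crowd-curation and
meta-analysis workflow for public gene-expression repositories: free-text
sample metadata is searched and annotated with regular expressions, the
precision of independent annotators is scored with chance-corrected
agreement statistics, and curated case/control contrasts are pooled across
studies into ranked differential-expression signatures.

## Annotation model

A *tag* is a reusable key (`breast_cancer`, `Age`) bound per sample to a
Boolean, categorical, or quantitative value. Curators annotate at the
*series* (study) level: one regular expression applied to one attribute
field either **matches** (every sample whose field text contains a match is
annotated `True`) or **captures** (the first group's text becomes the
value). Conventions chosen to suppress the empirically dominant error
classes:

- match-mode rules may not contain capturing groups, and capture-mode rules
  must contain exactly one — match/capture confusion is forced into a hard
  error at rule construction;
- quantitative captures must parse as numbers; failures are skipped with a
  warning, never coerced;
- a Boolean tag records only `True`; absence of an annotation is not
  `False` (case and control status are separate tags);
- rules are case-sensitive by default (patterns such as `IDC` rely on
  case), with a per-rule flag;
- regexes are applied per field, not across concatenated fields; repeated
  `characteristics_ch1` header lines are parsed into numbered fields so a
  rule can target one line.

## Agreement statistics

A cross-annotation pair is one (series, tag) annotated independently by two
curators, compared over the union of samples either one annotated. A sample
annotated by one curator only enters the contingency table under an
explicit *untagged* category. This convention is load-bearing: when a
validator's regex matches exactly the complement of the original samples
(the classic case/control mix-up), the table is anti-diagonal and

κ = (p_o − p_e) / (1 − p_e)

evaluates to −1 for balanced classes; dropping non-shared samples would
instead leave nothing to compare. κ is multi-category (categorical capture
tags need more than a 2×2 table). When both raters are uniform, p_e = 1 and
κ is returned as an explicit undefined state (`None`) — never 0 or NaN —
and such pairs are excluded from mean-κ summaries while still counting
toward concordance. Concordance is the plain fraction of agreeing samples,
with "validated concordant" meaning exactly 1.0. Corpus summaries pool
concordance at the sample-annotation level (large series weigh more);
per-tag discordance reports pool all of a tag's samples into one table and
sort by increasing agreement. The histogram reserves a central
−0.25 ≤ κ ≤ 0.25 band for random-level agreement.

Blinding replaces every GSE/GSM/GPL accession (in identifiers and inside
attribute text) with opaque stable tokens, keeping the bijection private so
pairs can be re-joined after validation.

## Meta-analysis

Per study, a gene's effect is the raw mean difference of (assumed
log-scale) processed expression, θ = mean(case) − mean(control), with
unpooled Welch variance v = s²₁/n₁ + s²₂/n₂ (sample variances, n−1
denominators; missing values excluded pairwise; genes need ≥ 2 non-missing
values per arm and v > 0). A standardized-effect option (Cohen's d with its
large-sample variance) exists for settings where raw differences are not
comparable across platforms, but the raw difference is the default.

Fixed-effect pooling uses inverse-variance weights w_i = 1/v_i:
θ_F = Σwθ/Σw, se_F = (Σw)^(−1/2), Q = Σw(θ − θ_F)². Random effects use the
DerSimonian–Laird moment estimator
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) — truncation at zero is explicit —
with re-weighting w*_i = 1/(v_i + τ²); k = 1 gives τ² = 0 by convention, so
the random-effects result collapses to the fixed-effect one. p-values are
two-sided normal tests on θ/se (no t reference; consistent with
inverse-variance pooling), and FDR is Benjamini–Hochberg (delegated to
statsmodels behind a validating wrapper that rejects p ∉ (0, 1]). Genes
observed in fewer than `min_k` studies are flagged, not dropped.

Probe-level matrices are collapsed to genes *before* effect estimation
(deterministic, simple variance bookkeeping); the collapse rule defaults to
the per-sample mean over a gene's probes, with median and
keep-most-variable-probe alternatives. Multi-gene probes are ambiguous and
dropped by default.

## Signatures

Each gene is scored −log10(p) × effect, so the score is antisymmetric in
the effect and zero at p = 1. Up/down rankings sort the signed score with
deterministic tie-breaking (|effect| descending, then gene id). Signatures
are compared by (i) Spearman ρ of scores over the shared gene universe
(average ranks for ties; asymptotic two-sided p; ρ within 1e−12 of ±1 is
snapped to exactly ±1 to absorb float error in rank sums), (ii) the
intersection of FDR-significant sets, and (iii) top-N overlap per
direction, both top lists taken within the shared universe. Two independent
random top-N lists from an N-gene universe overlap in n²/N genes on
average — 200²/19725 ≈ 2.03, i.e. about two genes — and the implementation
adds a hypergeometric upper-tail p-value for the observed counts as an
extension beyond the chance expectation. A single-cohort Welch t-test
signature (effect = mean difference) is provided as a comparator.

## Synthetic corpora

The generator emulates a desk-scale multi-study case/control corpus.
Defaults: 10 series; per-series arm sizes drawn uniformly from 8–20 cases
and 5–15 controls (unequal sizes exercise unequal-variance pooling); 1,000
genes, 10% differential with per-gene effect δ_g ~ N(1.0, 0.25²) on the
log2 scale; between-study heterogeneity u_gi ~ N(0, τ²) with τ² = 0.5;
residual noise σ = 1.0; baselines ~ N(7, 2) mimicking log2 microarray
intensities:

x_gs = baseline_g + (δ_g + u_gi)·case_s + ε,  ε ~ N(0, σ²).

Case samples carry `tissue: invasive ductal carcinoma` in their
characteristics text, controls `tissue: normal breast`; distractor strings
(`IDCidA`, `non-IDC`) are planted so naive substring tagging mis-fires
while the canonical keyword regex tags exactly the planted cases. Series
are written as standard series-matrix files (byte-identical for a fixed
seed) with a truth JSON and probe-map TSV; an optional probes-per-gene > 1
mode exercises collapsing.

The generator produces additive Gaussian log-scale data with independent
genes. It does not model RNA-seq counts, probe saturation,
platform-specific distributions, batch structure beyond the additive
between-study term, or gene–gene correlation — so passing recovery tests
demonstrates correctness of the estimators under the stated model, not
performance on real repository data. The cross-annotation simulator
generates validator errors in the three observed classes: independent
per-sample flips, capture-of-the-wrong-field (values independent of truth,
κ ≈ 0), and complement tagging (κ = −1 on balanced classes).

## Numerical choices and calibration checks

- Undefined κ is detected as p_e ≥ 1 − 1e−12 to absorb accumulation error
  in the marginal products.
- τ² truncation makes the homogeneous-θ identity (Q ≈ 0 ⇒ τ² = 0 ⇒ random
  ≡ fixed) exact in floating point.
- Pooling is verified against a loop-coded textbook oracle to 1e−12 on
  1,000 random instances and against reference values frozen from R's
  metafor (`rma`, methods FE and DL) on small instances; κ is verified
  against scikit-learn's `cohen_kappa_score` where defined.
- Calibration suite sizes (chosen for a desk-scale default run): mean κ
  over 2,000 independent Bernoulli(0.5) annotator pairs of 200 samples is
  0 to two decimals; DL τ² averaged over the differential genes of 100
  seeded corpora recovers 0.5 within 0.05 (the moment estimator carries a
  small positive bias when within-study variances are estimated at these
  arm sizes); random-effects 95% CIs cover the planted δ_g at 90–98%
  (DerSimonian–Laird intervals are known to undercover mildly at k = 10);
  null corpora keep the BH q < 0.1 discovery fraction at or below the
  nominal 10%.

## Known limitations

- Only the series-matrix dialect is parsed, not full SOFT family files.
- Full-text search is case-insensitive substring (with a whole-word
  option), one hit per matching field; no tokenization or stemming.
- Raw mean differences pooled across heterogeneous platforms are
  questionable when scales differ; the standardized option exists but is
  not the default.
- Agreement summaries weight by sample annotations; a per-pair weighting
  would give different corpus-level concordance when series sizes vary.
- No study-quality weighting, publication-bias diagnostics, or
  leave-one-out sensitivity analyses.
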