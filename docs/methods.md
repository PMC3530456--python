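# Methods

This note records the statistical models implemented in epiconcord, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions that affect results.

## Differential methylation

Beta values are methylation fractions in [0, 1]. Entries whose detection
p-value exceeds the threshold (default 0.05) are masked as missing; the
comparison is strict (`p > 0.05` excluded, `p = 0.05` kept). After
masking, probes with fewer than `min_per_group` (default 3) usable
values in either group are dropped: a variance estimated from fewer than
three observations is too unstable to test.

The per-probe test is an equal-variance two-sample t on beta values.
Proprietary array-software scoring models are not reproducible from
their published descriptions; an equal-variance t preserves the monotone
p ↔ DiffScore relationship the calling rule relies on, which is what
matters downstream. Beta values are bounded and heteroscedastic near the
boundaries, so a logit M-value variant (`use_mvalues=True`) is available;
group means and Δβ are always reported on the beta scale because the
Δ5mC% statistic is defined there.

The signed DiffScore is `10 · sgn(Δβ) · (−log10 p)`, with Δβ = 0 mapping
to 0 and numerical p = 0 capped at ±350 (the ceiling commonly seen in
array-software exports; configurable). BH q-values are reported alongside
per-probe p-values; the default gene gate remains the conventional
|DiffScore| ≥ 13 (p ≤ 0.05) rule, with the q column available for
stricter gating.

Gene aggregation: a gene is a DMG iff at least one autosomal probe
passes the gate; the direction comes from the probe with maximal
|DiffScore|. When probes of opposite sign tie at the maximal absolute
score the gene is marked `ambiguous` and excluded from concordance.
This max-|DiffScore| rule is a documented design choice — probe-to-gene
aggregation has no unique convention. Probes annotated to several genes
contribute to each. Δ5mC% uses post-masking group means and is printed
at 1 decimal in table output.

## Differential expression

The expression matrix is consumed already log2-scaled and summarized per
gene; upstream normalization is out of scope. `quantile_normalize`
exists to condition synthetic or lightly processed data: every column is
mapped onto the row-mean reference distribution, with ties resolved by
order of appearance so an already-normalized matrix is a fixed point.

The moderated t shrinks per-gene pooled variances s² (d = n₁+n₂−2
residual df) toward an intensity-dependent prior. The prior curve is
fitted by lowess (tricube-weighted local linear regression, span 0.3,
configurable) of log s² on mean intensity; the prior df d0 is
moment-matched on the log scale from

    Var[log s²] = ψ′(d/2) + ψ′(d0/2),

solving for d0 by Newton inversion of the trigamma function, and the
trend is bias-corrected from E[log s²] to log s0² using the digamma
means of the scaled-χ² factors. When the residual spread around the
trend is no larger than ψ′(d/2), the data show no gene-specific variance
heterogeneity beyond the trend and d0 is effectively infinite: the test
then uses s0²(A) alone with a normal reference. d0 = 0 is accepted as an
explicit no-shrinkage limit and reproduces the ordinary pooled t
exactly (tested to 1e-10).

DEGs are genes with BH q ≤ 0.10. BH ties take the maximum rank within a
tie block (standard step-up behavior). Signed fold changes follow the
array-table convention (linear ratio if ≥ 1, else negative reciprocal);
printed values round half away from zero to 1 decimal, matching how such
tables are typeset.

## Concordance

The DMG/DEG intersection joins by exact, case-sensitive gene symbol; no
alias service is consulted, and symbols present in only one layer are
logged. The 2×2 direction map is total: hypo+up → hypo_up, hyper+down →
hyper_down, hyper+up → hyper_up, hypo+down → hypo_down; only the first
two count as concordant, but same-direction genes are retained with
their class label because they are biologically informative (gene-body
methylation and hydroxymethylation can track expression positively).
Concordance re-uses calling-time thresholds; nothing is re-thresholded
at integration. Output tables split by class and sort by descending
|signed FC| with a stable sort.

## Enrichment

Over-representation uses the plain hypergeometric upper tail P(X ≥ k)
with sets intersected against the universe first; the default universe
is the assay's annotated genes, the standard background for array
studies. The conservative EASE-style variant (tail at k−1) sits behind a
flag. The two-sided Fisher exact test sums table probabilities not
exceeding the observed one; both engines are checked against exhaustive
combinatorial enumeration in the tests. BH correction is a single shared
implementation (`transcriptome.bh_fdr`).

## Targeted validation

* IQR outlier filter: keeps values within median ± 1.5·IQR, quartiles by
  linear interpolation between order statistics (numpy's default,
  "type 7"); the convention matters because the exclusion set can depend
  on it. The conventional Tukey fences (Q1/Q3 ± 1.5·IQR) are available
  behind a flag. The median is never excluded. Note the filter is not
  idempotent in general: removing points moves the quartiles, and a
  second pass can exclude further values (e.g. whenever the IQR of the
  filtered set collapses); re-filtering only ever shrinks the set.
* Two-sample t-tests: pooled-variance by default (Welch behind a flag),
  either from raw values or from mean/SEM/n summaries via the
  SEM → SD conversion; the two routes agree to 1e-10 on the same data.
  Zero pooled variance with equal means is the clean null (t = 0,
  p = 1); with unequal means it is flagged as an error.
* qPCR: replicate wells are averaged per sample before ΔCt = Ct_target −
  Ct_housekeeping; ΔΔCt is the case-group mean ΔCt minus the
  control-group mean, and fold = 2^−ΔΔCt, also reported as a negative
  reciprocal below 1 for table parity. No amplification-efficiency
  modeling beyond the exact 2-fold-per-cycle assumption.
* Pyrosequencing: per-sample region value is the mean over CpG sites
  (equal site lists enforced), then group mean ± SEM, plus per-site
  group means.

## Synthetic data

The generator emulates a two-group integrative array study at benchmark
scale: 2,000 CpG probes over 1,000 genes (≈ 2 probes/gene, close to the
~1.9 probes/gene density of a 27K-scale methylation array), 12 cases vs
12 controls. Defaults plant Δβ = 0.15 on the probes of ~20% of genes,
|log2FC| = 1 on 20% of genes, and make 10% of genes concordant (planted
in both layers with consistent directions, split evenly between hypo_up
and hyper_down); these are the conditions under which the recovery
properties in the test suite are stated (sensitivity ≥ 0.8, false
concordant proportion ≤ 0.2).

Baseline probe methylation comes from a three-mode Beta mixture —
unmethylated (mean ≈ 0.1), methylated (≈ 0.85) and a minor intermediate
mode (≈ 0.5), weights 0.45/0.45/0.10 — reproducing the characteristic
bimodality of Infinium beta values that any caller must tolerate.
Effects are additive on the beta scale (the Δ5mC% statistic is defined
on raw beta); case means are clipped to (0.02, 0.98) and the achieved
(possibly truncated) shift is what the truth set records. Sample values
are Beta-distributed with concentration 50 (a realistic per-probe
sampling noise of σ ≈ 0.07 at β = 0.5). Detection failures are
independent across entries at rate 1%.

Expression baselines are Normal(8, 1.5) on the log2 scale with residual
sd 0.4 at the anchor intensity and a log-variance slope of −0.1 per log2
unit, giving the intensity–variance trend the moderated-t prior must
identify. ELISA samples are Normal with sd = SEM·√n so group-mean
standard errors match stated summaries; qPCR control ΔCt sits at 5
cycles with the case group offset by −log2(fold).

Each modality draws from its own RNG stream derived from the master
seed, so modalities can be regenerated independently; identical config
and seed give byte-identical outputs.

What the simulator does **not** emulate: raw IDAT/CEL intensities,
probe-type chemistry differences, batch or position effects, correlated
detection failures, cell-type composition, gene–gene correlation, or
probes annotated to multiple genes. Passing recovery tests therefore
demonstrate the statistical machinery on clean planted effects, not
robustness to those real-data complications.

## Numerical conventions and limitations

* TSV everywhere: UTF-8, tab-delimited, '.' decimal, 'NA' missing.
* Gene symbols are opaque case-sensitive strings.
* Rounding for printed-table reproduction is half-away-from-zero at 1
  decimal.
* The t-test on beta values treats bounded fractions as approximately
  normal within groups; at n ≈ 12 per group this is adequate for
  calling (type-I error ≈ 5% in the null simulations) but p-values for
  probes near the 0/1 boundary are approximate — the M-value flag is
  the remedy when that matters.
* The DiffScore gate (p ≤ 0.05 per probe) controls no family-wise or
  false-discovery rate by itself; the reported BH q column does.
* Genome-scale counts from any particular study are not reproducible
  without its raw arrays; the package's reproduction surface is worked
  examples (printed tables, group summaries) plus planted-truth
  simulation.
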