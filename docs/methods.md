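# Methods

## Problem and data model

The package analyses collections of case-control genotype counts at
biallelic SNPs. Each record holds the six counts (MM/MW/WW × case/control)
for one study; genotypes are labelled by *role* — MM is the homozygote of
the mutant (minor/risk) allele — so one schema covers SNPs with any
nucleotide substitution, and the actual allele letters travel as metadata.
The bundled IL7RA / multiple-sclerosis table stores 27 such records across
four SNPs; every transcribed row is guarded by a test asserting that its
counts sum to the study's published case and control totals.

## Per-study effects

A *genotype contrast* collapses the 3×2 table into a 2×2 exposure table.
Seven contrasts are implemented: the three pairwise odds ratios OR1 (MM vs
WW), OR2 (MW vs WW), OR3 (MM vs MW), and the dominant (MM+MW vs WW),
recessive (MM vs MW+WW), allelic (M vs W allele counts, two per subject)
and overdominant (MW vs MM+WW) models. The per-study effect is the crude
odds ratio ad/bc with the Woolf (logit) SE √(1/a+1/b+1/c+1/d), a 95% CI of
exp(log OR ± 1.96·SE), and a two-sided normal Z-test. A single zero cell is
handled by the Haldane-Anscombe correction (0.5 added to all four cells,
estimate flagged); policy `error` refuses instead. Two zero cells or an
empty margin leave the OR undefined. The allelic contrast treats the 2n
alleles as independent — the usual approximation, exact under HWE.

## Hardy-Weinberg screening

Controls are screened with the three-cell Pearson χ² against expected
counts n·q², n·2q(1−q), n·(1−q)² (q = mutant-allele frequency), 1 df, no
continuity correction; monomorphic samples return χ²=0, p=1, flagged. A
conditional exact test (enumeration of heterozygote counts given n and the
minor-allele count) is available as `method="exact"` but is not the
default: the χ² version reproduces the HWE classifications of the bundled
table's source. Deviating studies (p < 0.05) are flagged and kept in the
primary pooling — their influence is probed by the sensitivity analysis —
unless `hwe_policy="exclude"` is chosen.

## Pooling and heterogeneity

Fixed effect is Mantel-Haenszel, OR_MH = Σ(a_i d_i/n_i) / Σ(b_i c_i/n_i),
with the Robins-Breslow-Greenland variance of log OR_MH; an
inverse-variance fixed pooler is exposed for cross-checks. Random effects
is DerSimonian-Laird: τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)) on fixed IV
weights, then w*_i = 1/(se_i²+τ²). Cochran's Q and I² = max(0,(Q−df)/Q)·100
are always computed from the Woolf per-study estimates, independent of the
pooling branch, so the heterogeneity column of a report does not depend on
which pooler produced the OR. `pool_auto` takes the random branch when
I² ≥ 50% (threshold configurable), else Mantel-Haenszel; a single study
pools to its own crude OR. All pooled estimates were cross-checked once
against R `metafor` (rma.mh, rma method="DL") and the agreeing values are
frozen into the test suite; metafor's Q dialect differs from the
Woolf-weight Q in the third decimal on the bundled data, which the frozen
tolerance records.

## Inheritance-model selection

The decision rules classify each of (OR1, OR2, OR3) and map the pattern:
(+,+,−) dominant; (+,−,+) recessive; (−,+,+) complete overdominant,
provided OR2's effect magnitude |log OR2| is below both |log OR1| and
|log OR3|; (+,+,+) codominant, provided |log OR1| exceeds both others. Any
other pattern is undetermined and triggers pooling of all six candidate
models (OR1, OR2, OR3, allelic, dominant, recessive).

Two deliberate design choices:

* **"+" means statistically significant in either direction.** The rules'
  source table defines "+" only as "a significant result". Reading it as
  risk-only would break the natural symmetry requirement that relabeling
  which homozygote is "mutant" (MM↔WW) maps a dominant decision to a
  recessive one on the same data — under relabeling every risk OR inverts
  to a significant protective OR. The direction-blind reading satisfies
  that symmetry (verified by test) and leaves every decision on the bundled
  data unchanged.
* **Marginal significance is a second pass, not a softer default.**
  Estimates with α ≤ p < α_marginal (defaults 0.05, 0.10) are classed
  MARGINAL; the first pass ignores them, and only if it returns
  undetermined are they promoted to "+" and the rules re-evaluated, setting
  a `marginal_used` flag. This reproduces the behaviour seen in practice:
  clear recessive calls never touch marginal logic, a borderline dominant
  call uses it, and a SNP with a lone marginal protective contrast stays
  undetermined. α_marginal is a package codification — the source describes
  the 0.05–0.10 band only descriptively.

For a decided model the headline contrast is the model's own collapse
(dominant → MM+MW vs WW, recessive → MM vs MW+WW, overdominant → MW vs
MM+WW, codominant → MM vs WW). For an undetermined decision the headline
used for diagnostics and power is the allelic contrast, matching how the
undetermined SNP in the bundled analysis is displayed in forest/funnel
form.

## Diagnostics

* *Leave-one-out*: re-pools the contrast omitting each study (k ≥ 3); flags
  whether the 95% CI's exclusion of 1 ever differs from the full-set
  result.
* *Cumulative by size*: studies ranked by total n (descending by default,
  ties broken by study_id); step j pools the j largest. Pooling is done in
  the original supply order of the included subset so the final step is
  bit-identical to pooling the full set directly.
* *Egger*: OLS of θ_i/se_i on 1/se_i; two-sided t-test of the intercept on
  k−2 df. A perfect fit (zero residual) is reported degenerate with p=NaN.
* *Begg*: Kendall's tau-b between the standardized deviates
  u_i = (θ_i−θ̄)/√(se_i²−1/Σw) and the variances se_i²; the z statistic
  uses the untied null variance k(k−1)(2k+5)/18 on the
  concordant−discordant pair count; fully tied inputs return tau = 0.
* *Power*: uncorrected two-sided two-proportion test. The control exposure
  probability p0 is the pooled control frequency of the headline contrast's
  exposed class (e.g. the MM genotype for a recessive call), the detectable
  OR ψ is the pooled OR, and
  p1 = ψp0/(1+p0(ψ−1)), power = Φ((|p1−p0| − z_{1−α/2}σ₀)/σ₁) with σ₀ the
  pooled-proportion null SE and σ₁ the alternative SE. Published per-study
  power figures for comparable analyses come from closed-source calculators
  whose exact formula (corrected vs uncorrected χ²) is unstated, so
  per-study power values are reproduced only approximately and are reported
  for orientation, not asserted.

## Synthetic-data generator

Controls are multinomial draws from genotype probabilities
(q²+fq(1−q), 2q(1−q)(1−f), (1−q)²+fq(1−q)) — HWE at f = 0, inbreeding-style
distortion otherwise. Cases re-weight the control simplex by per-genotype
odds multipliers: dominant (ψ,ψ,1), recessive (ψ,1,1), multiplicative
codominant (ψ²,ψ,1), overdominant (1,ψ,1), null (1,1,1); this prospective
sampling is a valid stand-in for the retrospective design because the odds
ratio is invariant to outcome-based sampling, and the population-level
contrast OR it implies equals ψ exactly (tested). Heterogeneity perturbs
each study's log ψ by N(0, τ²) — the same scale the DL model assumes. Each
study draws from `default_rng([seed, study_index])`, so collections are
reproducible and order-stable. Defaults (8 studies of 500/500, MAF 0.3)
mirror the scale of the bundled collections.

What the generator does *not* emulate: covariates and confounding,
genotyping error, linkage/haplotype structure, selective publication.
Calibration tests passing on synthetic data therefore validate the
estimators' statistical behaviour (type-I error ≈ α, ≈95% CI coverage,
model recovery ≥ 90% at large n, τ² tracking, HWE-violation detection), not
robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

95% CIs use z = 1.96 exactly. I² is truncated at 0; τ² at 0 (DL reduces to
IV-fixed when Q ≤ df). Monomorphic control samples short-circuit the HWE
test. Counts must be non-negative integers; fractional counts are rejected,
not rounded. Problem sizes in the statistical tests (e.g. 1000 replicates
for type-I/coverage, 200 for model recovery, collections of 4-10 studies of
400-5000 subjects per arm) were chosen to keep Monte-Carlo error well
inside the asserted bands while the whole suite runs in well under a
minute.

## Known limitations and open discrepancies

Three published figures for the bundled IL7RA table do not survive honest
recomputation from its own genotype counts, and the corresponding
assertions are deliberately left failing rather than adjusted:

* the rs3194051 heterozygote contrast (GG vs GA) is printed as OR 1.17
  (1.02–1.33) with I² = 76%, but no inverse-variance-type weighting of the
  eight per-study ORs can yield a pooled value below 1.24 (DL gives 1.277,
  I² = 50.2%; the fixed/random branch choice itself does reproduce). The
  three sibling contrasts of the same SNP reproduce to printed precision
  from the same counts.
* the HWE screen finds four control groups at p < 0.05 (χ², 1 df), not the
  narrated three — the table's own printed p-values also show four below
  0.05.
* leave-one-out significance is *not* universally stable: the borderline
  dominant pooled CI (1.01–1.37) of rs11567686 loses significance when any
  of three studies is omitted, and the rs3194051 recessive call when the
  largest study is omitted; the published claim of unchanged significance
  is reported with "data not shown".

Beyond that: no risk-ratio/risk-difference measures, no Peto OR,
Hartung-Knapp, trim-and-fill or meta-regression; subgroup analyses are out
of scope; the pipeline treats each (study, SNP) row as independent and does
not model linkage between SNPs typed in the same cohort.
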