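# Methods

`polydiff` tests whether the SNPs associated with a complex trait are more
differentiated among populations than genetic drift predicts, and, where
they are, in which direction.  This note documents the statistical model,
the defaults and why they were chosen, what the synthetic data emulate (and
do not), and the numerical choices a maintainer would want to know.

## The enrichment test

For a set of trait-associated SNPs (GWAS hits clumped to near-independence)
the test compares the mean of a per-SNP differentiation statistic — F_ST or
the LD-score coefficient of variation (LDCV) — against a resampling null of
control SNPs matched on minor allele frequency and LD score:

1. All eligible SNPs (MAF ≥ 0.01) are assigned to 20 MAF bins of width
   0.025 over (0, 0.5]; each MAF bin is further cut at the 20 quantiles of
   its LD-score distribution, giving a 20 × 20 grid.  MAF and LD scores
   come from the reference (EUR-like) population, because that is where the
   effect sizes were estimated and hence where ascertainment acts.
2. A control set copies the associated SNPs' cell occupancy exactly, drawn
   without replacement within a set and independently across sets (default
   10,000 sets; validation runs use 200, which adds a little Monte-Carlo
   noise to the null moments but none to the mean).
3. With observed mean statistic `m_obs` and control-set means `m_1..m_S`,
   the primary P-value is two-tailed normal,
   `z = (m_obs − mean(m)) / sd(m)`, `p = 2·Φ(−|z|)`; an empirical rank
   P-value `(1 + #{|m_s − mean| ≥ |m_obs − mean|}) / (S + 1)` is reported
   alongside.  A variance version of the test (comparing `var` instead of
   `mean`) is available for checking dispersion effects.

Matching is the load-bearing part: F_ST is a function of MAF, and GWAS
power is too, so unmatched controls would make ascertainment look like
selection.  Matching modes `maf_only` and `maf_and_afr_ld` exist to probe
sensitivity to the matching choice.  The control pool excludes the
associated SNPs themselves; an option re-includes them for exact-protocol
replication.

**Empty matching cells.**  On small panels a hit's MAF × LD cell may hold
no other SNP.  Rather than fail, sampling falls back to the cell's whole
MAF bin (warning logged); a cell whose pool is merely smaller than the
required count is sampled with replacement (warned).

## Differentiation statistics

**F_ST.**  Default is the Weir–Cockerham (1984) estimator computed from
per-population sample sizes, allele frequencies and observed
heterozygosity.  Two forms are exposed:

* `fst_per_snp` — the per-SNP ratio `a/(a+b+c)`, used as the per-SNP
  statistic in the enrichment contrast.  Its expectation with few
  populations is Jensen-biased toward zero (with r = 3 demes and a true
  F = 0.15 the mean per-SNP value is ≈ 0.127), but the bias depends only
  on MAF and sample configuration, so it cancels between associated SNPs
  and MAF-matched controls.
* `fst_overall` — the multi-locus ratio-of-averages `Σa / Σ(a+b+c)` that
  Weir & Cockerham recommend for combining loci; it is consistent for the
  generating F (0.152 ± 0.001 measured on a 20,000-SNP F = 0.15 panel)
  and is what the estimator-consistency validation checks, with a
  leave-one-SNP-out jackknife standard error.

Nei's G_ST (unweighted) and the pairwise Hudson estimator (ratio of summed
numerators/denominators over population pairs) are selectable; with
harmonized sample sizes the choice is second-order for the enrichment
contrast.  Negative estimates are retained (truncation would bias the
null).  A SNP is undefined (NaN) only when the pooled sample is
monomorphic; differentially fixed SNPs are the F_ST → 1 limit, not
missing.

**LD score and LDCV.**  The LD score of a focal SNP is the sum of squared
dosage correlations (composite LD — panels may be unphased) with all SNPs
on the same chromosome within ±10 Mb, self term included; pairs with
r² < 0.01 are excluded so that thousands of chance correlations do not
accumulate.  LDCV is sd/mean of a SNP's LD scores across populations, with
the sample (n−1) standard deviation — with the population count fixed this
is a constant rescaling that cancels in the matched contrast.  No
small-sample r² correction is applied (the scores feed matched contrasts,
not regression); missing dosages are mean-imputed inside the vectorized
correlation (the scalar `ld_r2` is pairwise-complete; post-QC missingness
is bounded by the 98% call-rate filter).

## Clumping

PLINK-style greedy clumping: candidates below the P threshold are visited
in ascending P (exact ties broken by genomic position, so runs are
reproducible); each index SNP absorbs unassigned candidates within ±1 Mb
with reference-panel r² ≥ 0.01.  Thresholds 5×10⁻⁸ and 5×10⁻⁶ are the two
operating points studied; the looser one trades extra false positives for
more true ones, and in the power validation that trade wins or ties.
Window distance is measured index-to-candidate.  No secondary P threshold
is applied.

## Direction analyses

The polygenic score `ĝ_i = Σ_l x_il b̂_l` uses harmonized per-allele
effects; missing dosages are imputed as twice the individual's own
population allele frequency (dropping individuals would bias small
panels).  Scores are standardized over the *combined* sample — the only
scope under which the population deviation is interpretable — and
decomposed as `ĝ_i = μ + v_j + e_i`; the least-squares solution under the
population-size weighting is `v_j = mean_j − μ`, so `Σ n_j v_j = 0`
exactly.  Standard errors use the pooled within-population residual s.d.
The "s.d. units" of `v_j` are those of the standardized individual score.

No significance is attached to the direction itself: the enrichment test
carries the significance, and the 95% band of `v_j` over matched control
sets is drawn only to display drift variability.

fTIA — the frequency of the allele with positive estimated effect — is the
effect-size-free counterpart (robust to cross-population effect-size
heterogeneity): under drift each population's mean fTIA is ~0.5 and the
between-population difference ~0.  SNPs with b̂ = 0 have no defined
trait-increasing allele and are dropped (logged).  Both analyses agree in
sign when a simulated frequency shift is injected, which is the package's
concordance check.

## Trait simulation and the GWAS scan

Phenotypes follow the standard additive model `y = g + e`,
`g = Σ_i w_i u_i` with standardized causal genotypes `w_i` and effects
`u_i ~ N(0,1)`; the residual is `N(0, var(g)(1/h² − 1))`, so h² = 1 gives
`y = g` exactly and h² = 0 is rejected.  Causal-sampling modes: `random`
(drift null), `top_fst` (upper half of the F_ST distribution — the
selection alternative), `maf_skew` (+500 causals with MAF < 0.1) and
`clustered` (two extra causals within 1 Mb of each primary), covering the
confound scenarios.

The scan regresses the phenotype on each SNP's dosage with the top 10
genotype PCs as covariates.  The engine residualizes the dosage matrix
against the covariate basis once (float32; per-SNP betas agree with an
exact OLS to ~10⁻⁵, and with statsmodels in the tests), after which each
trait costs one matrix–vector product.  PCs come from a thinned random
subset of SNPs (default cap 4,000) — the usual cost-saving on large
cohorts; on a homogeneous cohort they are near-noise covariates either
way.  Monomorphic SNPs are emitted as missing.

### Desk scaling of the study

The design this emulates ran GWAS on ~54,000 individuals with m = 1,000
causal variants — per-causal non-centrality `n·h²/m ≈ 27`.  The bundled
validation studies use a 5,000-individual cohort and scale m to 100,
keeping the per-variant signal (≈ 25) and hence realistic hit counts
(~30 per trait at P < 5×10⁻⁶); all calibration and power claims are
properties of rates, not absolute counts.  The full-size trait model
(m = 1,000) is exercised by `scripts/acceptance.py` with a 25,000-individual
cohort, the smallest size whose expected clumped-hit count at P < 5×10⁻⁶
clears 100 per trait (a requirement of that analysis, sized analytically
from the non-central χ² power curve before any run).

## Synthetic data

The drift generator is Balding–Nichols: ancestral frequency p per SNP
(uniform on [0.01, 0.5] by default), population frequencies
`Beta(p(1−F)/F, (1−p)(1−F)/F)` — the canonical exchangeable-drift model,
directly parameterized by the F the test must not confound.  Defaults
mirror the harmonized design the package emulates: three populations
(EUR/AFR/EAS-like) of 1,099 diploids, F = 0.15.  Local LD comes from a
block latent-haplotype model (Gaussian copula: blocks of 10 SNPs share a
latent factor with loading √0.7), which is O(n·m) and analytically
controllable; realized dosage r² is attenuated where block-mates differ in
frequency, as for real tag SNPs.  A GWAS cohort can be drawn from any
population's latent frequencies so cohort and panel share SNP identifiers.

What the generator does *not* emulate: coalescent site-frequency spectra,
recombination-map structure, mosaic haplotypes, genotyping error and
imputation artifacts.  Passing tests therefore show the statistics and
their calibration are implemented correctly under controlled drift — not
that any particular real dataset would yield a given P-value.

A note on QC retention: with F = 0.15 drift around a [0.01, 0.5] ancestral
spectrum, roughly a fifth of SNPs fall below MAF 0.01 in at least one of
three populations and are (correctly) removed by the per-population MAF
filter; the generator does not hide this by truncating the spectrum.

Selection alternatives are injected by shifting target SNPs' population
frequencies on the logit scale (clamped to [0.001, 0.999]) and redrawing
their genotypes; the shift can be coupled to the trait-increasing allele so
direction analyses have a known truth.

## Forward simulation

A discrete-generation Wright–Fisher diploid simulator with two unlinked
segments: segment 1 gives each new mutation a 5% chance of being
deleterious (s = −0.01, additive h = 0.5, multiplicative fitness across
loci); segment 2 is fully neutral.  Mutation is infinite-sites at
2.36×10⁻⁸ per bp per generation; recombination is uniform at 10⁻⁸ per bp
(human-typical; the source design did not specify one).  The demographic
schedule is the standard Out-of-Africa model: 7,310 ancestral diploids,
African expansion to 14,474 at 5,920 generations before the end, a
European founding bottleneck (1,861, then 1,032) with exponential growth
to exactly 34,039 at generation 58,000, and symmetric migration
(1.5×10⁻⁴ during the bottleneck epoch, 2.5×10⁻⁵ during growth).  Epoch
boundaries not printed in the source are taken from the published
Out-of-Africa calibration; the printed start/terminal sizes are the
checked anchors.

A rescaling factor λ divides sizes and times and multiplies mutation,
recombination, selection and migration rates, preserving 4Nμ and N·s.
Desk-scale default: λ = 10 with two 100-kb segments (the full-scale run
used 10 Mb), so absolute variant counts are deliberately not reproduced —
only the directional contrast is claimed.  Fixed and lost variants are
pruned each generation (a fixed deleterious variant rescales every fitness
equally, so pruning is exact).  Samples of 500 diploids per deme are drawn
at the end.

The background-selection contrast compares mean F_ST (and mean LDCV) of
common (per-deme MAF > 0.01) segment-2 variants against MAF/LD-matched
*non-deleterious* segment-1 variants, reusing the enrichment binning with
automatic coarsening (10×4 → 5×2 → 2×1 → 1×1) until every target cell has
matching candidates — a few hundred variants per replicate cannot fill a
20×20 grid.  Matching statistics are taken from the African-deme sample,
which retains the most variation.

**What desk scale can and cannot show here.**  Rescaling preserves 4Nμ and
N·s but not two quantities that the F_ST contrast lives on.  First, the
deleterious load per selected unit, U_del/s, falls ~100× when the segment
shrinks from 10 Mb to 100 kb (mutation rate rises only ×λ while length
falls ×100), taking the expected diversity reduction from B ≈ exp(−U/s)
≈ 0.3 at full scale to ≈ 0.99 at desk scale.  Second, the number of
roughly independent genealogies per segment, ~4NrL, falls from ~2,900 to
~29, so a segment's mean F_ST has a per-replicate standard deviation of
~0.07 — far above the ~0.002 shift the residual BGS effect produces.  The
sign of the matched contrast over 20 desk replicates is therefore close to
a coin flip (measured 8/20 positive, mean difference −0.009 ± 0.072 s.d.),
and the package does not claim it.  What the simulator *does* reproduce
robustly, and what the suite asserts, is the mechanism: at a load where
B is materially below 1 (U_del/s ≈ 0.36), nucleotide diversity at neutral
variants on the selected segment drops to ~0.6 of the fully neutral
segment's, and the clean-split F_ST contrast trends positive.  Recovering
the full-scale sign result would need ~10-Mb segments even at λ = 10
(hours per replicate), which is deliberately out of scope.

## Numerical and engineering choices

* HWE: exact conditional test (enumeration by the standard recurrence over
  heterozygote counts), the PLINK convention; verified against a
  rational-arithmetic enumeration oracle.  Monomorphic sites return 1.
* Relatedness pruning: greedy removal of the individual with most
  over-threshold partners, ties by sample id — deterministic, and verified
  by an exhaustive post-hoc pair scan.
* Coordinates are 1-based; windows inclusive; chromosome order is natural
  (numeric labels first, so "2" < "10").
* All randomness flows through `numpy.random.Generator` objects seeded
  from explicit integers; every pipeline config must carry a seed, and
  identical config + seed reproduces byte-identical outputs.
* LD-score bin boundaries use `searchsorted(side="left")`, sending
  boundary ties to the lower bin deterministically.
* The forward simulator keeps one uint8 haplotype matrix per segment so
  reproduction is a contiguous row gather (mixed row/column indexing was
  the original bottleneck); a desk-scale replicate runs in ~30 s.

## Known limitations

* The block-copula LD model produces exchangeable blocks, not realistic
  haplotype structure; LD-score distributions are narrower than in real
  genomes.
* Per-SNP Weir–Cockerham values are Jensen-biased with few populations
  (see above); use `fst_overall` for absolute levels.
* The enrichment test loses power for highly polygenic traits at small
  cohort sizes because control SNPs can tag causal variants by chance; the
  validation studies therefore keep per-causal non-centrality at the
  full-scale level rather than diluting it.
* The forward simulator is not a tree-sequence engine; at λ = 1 and 10-Mb
  segments it would be slow (hours), which is why the rescaled
  configuration is the default and absolute variant counts are out of
  scope.
* v_j band coverage runs ~1–4 points below the nominal 95% at small hit
  counts: significance-ascertained hits carry more heterogeneous weights
  (fewer effective SNPs) than their matched controls; the effect shrinks
  as hit counts grow.
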