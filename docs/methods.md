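# Methods

`resistkit` re-implements, as a tested library, the computational analysis
behind a longitudinal study of escalating pyrethroid resistance in
*Anopheles coluzzii* from south-west Burkina Faso: whole-genome two-colour
microarray comparisons of field populations against susceptible laboratory
colonies in 2011 and 2012, a hypothesis-driven filter cascade for candidate
resistance genes, kdr target-site population genetics, and qPCR validation.
This note records the models, the parameters that matter, and the design
choices made where the original description left the details open.

## Two-colour loop-design differential expression

**Model.** Each array co-hybridizes two RNA populations labelled cy3 and
cy5; the analysis works on the within-array log ratio
M = log2(cy5) − log2(cy3) after flooring intensities at ε (default 1.0
fluorescence unit) and within-array centring (median by default; an
M-on-A lowess alternative removes intensity-dependent dye trends).
Populations and arrays form a connected interwoven-loop graph, and the
expected M of array *h* is

    E[M_h] = β(cy5 population) − β(cy3 population) + δ,

a fixed-effects model with one effect per population (a reference absorbed
at zero) and a common cy5 dye coefficient δ, fitted per probe by ordinary
least squares.  Contrasts are linear combinations of population effects;
two-sided p-values come from the t distribution on (arrays − rank) residual
degrees of freedom, and q-values are Benjamini–Hochberg per contrast.  No
empirical-Bayes variance moderation is applied; per-probe variances are
used as estimated.  The 2011 triangle (VKR/VKC/MAL) and the 2012
four-population loop (VKR/TEN/MAL/NG) are fitted separately and their
contrast tables merged, because the two experiments share no arrays and
their array-level variances need not agree; the merged table is what the
cascade consumes.

**Degenerate fits.** Probes whose residual sum of squares is numerically
zero with positive degrees of freedom (guaranteed on noise-free synthetic
data) receive an undefined p/q and a `zero_residual` flag rather than
p = 0.  Downstream, the cascade's significance gates treat an undefined q
as carrying no evidence against the probe — the strict sign rules then
decide — which is what makes noise-free planted-truth recovery exact and
is irrelevant on any data with measurement noise.

**Dye-swap invariances.**  With the dye coefficient fitted, contrast
estimates do not depend on which replicate of a comparison carries which
dye orientation (verified exactly on noise-free data with a systematic
cy5 offset).  The superficially similar transformation "swap an array's
cy3/cy5 labels and negate its M" is an exact symmetry only when the
recorded ratios carry no dye offset: negating M flips the sign of that
array's dye term in the data while the model's dye column cannot follow,
so with a non-zero offset the transformed system has no exact solution.
Both statements are tested in the form in which they are true.

## The candidate filtering cascade

Filters, in reporting order (all intersective, so the final set is
order-independent):

* **A–C** — log2FC > 0 in *every* resistant-field-vs-susceptible-colony
  contrast (2011 VK7/MAL; 2012 VK7/MAL; 2012 VK7/NG) with q below the
  threshold (default 0.05).  Whether significance is required in every
  contrast or in at least one is configurable (`significance_mode`:
  `all`, the stricter reading of "consistently", is the default).
* **E** — strictly larger VK7/MAL log2 fold change in 2012 than in 2011;
  a point-estimate comparison with no test on the difference.
* **D** — log2FC > 0 and q < threshold in VK7 vs Tengrela.

Surviving probes are collapsed to genes through a user-supplied two-column
probe→gene map (decoupling the pipeline from any annotation release); the
per-gene fold change is the arithmetic mean of per-probe fold changes on
the natural scale.  A mirrored list applies the same machinery with every
sign reversed and no year condition, yielding the consistently
down-regulated set.  Candidate profiles over the three VK7-vs-susceptible
contrasts are clustered agglomeratively with Euclidean distance; the
linkage is configurable (average by default) and rows are sorted by probe
identifier before linkage so ties resolve deterministically.

The published candidate counts (605 → 374 → 157 probes → 136 genes, and
291 down-regulated probes) depend on the deposited array data and are not
recomputed here; what the package asserts is the structure those numbers
exemplify — each step's survivors nest inside the previous step's — on any
input, together with exact recovery of planted candidates on synthetic
data.

## kdr population genetics

**Allele frequencies.**  Mutant-allele frequency with an exact
Clopper–Pearson 95% interval by default (Wilson by flag).  The published
interval for the representative cell (102 F of 124 alleles, printed
0.744–0.886) is reproduced by Clopper–Pearson on the lower bound exactly
and within 0.001 on the upper; Wilson matches neither bound, so
Clopper–Pearson is the documented default.  Across the full published
table no standard interval method reproduces every printed bound at three
decimals (the frequencies themselves all reproduce exactly), so interval
agreement is reported, not asserted, beyond the representative cell.

**Association tests.**  Dead-vs-survivor allele counts are compared by the
two-tailed Fisher exact test (sum of all conditional table probabilities
not exceeding the observed table's); the reported odds ratio is the sample
cross-product ratio, oriented so that OR > 1 means the mutant allele
increases survival odds, with Haldane's 0.5 correction only when a cell is
zero.  Across-group frequency homogeneity uses the Pearson chi-square on
the k×2 allele-count table (df = k−1), flagging expected counts below 1.

**Two-locus EM phasing.**  For the L1014F/N1575Y pair the only
phase-ambiguous genotype class is the double heterozygote LF/NY, which may
carry {L-N, F-Y} or {L-Y, F-N}.  Under Hardy–Weinberg random pairing, EM
gene counting splits that class by the relative likelihood of the two
resolutions (initialized 50/50) and re-normalizes haplotype counts until
the largest frequency change falls below 1e-8 (or a 1000-iteration cap,
flagged if hit).  The log-likelihood is recorded at every iteration and is
non-decreasing.  Because every genotype class — the ambiguous one
included — contributes a fixed number of F and Y *alleles*, the
maximum-likelihood allele frequencies equal the observed ones; the
likelihood therefore has a single free parameter, which is how the test
suite's independent grid-search oracle scans it exhaustively at 5e-4
resolution.  The structural field constraint that 1575Y occurs only on a
1014F background is *estimated*, not imposed: the L-Y frequency is free
and comes out at (near) zero on data respecting the constraint.

**Haplotype–survival association.**  One EM over the pooled sample (a
per-group EM is available by flag) yields per-individual expected
haplotype counts, partitioned by outcome into a 2×2 table (haplotype vs
all others × survivor vs dead) per haplotype; the cross-product odds ratio
(Haldane correction on zero cells) and a 1-df Pearson chi-square are
reported.  Haplotypes with fewer than half an expected copy across both
groups are omitted as absent.  This is a standard expected-count
construction and is not claimed to reproduce any particular legacy tool
numerically.  A third 1014 allele (1014S) in the input is an error unless
explicitly collapsed onto the wildtype, matching data in which that allele
was screened for but absent.

## qPCR relative quantification

Per biological replicate (technical wells are averaged per replicate
first; wells more than 0.5 cycles from their replicate median would be
flagged upstream), the target quantity is E_t^(Ct_cal − Ct_s) and the
normalization factor is the geometric mean over the three reference genes
of E_r^(Ct_cal − Ct_r), with E the per-primer amplification efficiency in
(1, 2] and Ct_cal the calibrator population's mean Ct per gene.  The ratio
of the two is the efficiency-corrected relative expression (the familiar
2^−ΔΔCt when all E = 2).  An arithmetic-mean-of-Ct reference aggregation is
available by flag.  Means ± SEM are reported per population; year-on-year
changes are tested with a two-tailed t-test on log ratios (Welch by
default, pooled by flag; the two coincide in balanced equal-variance
designs), unadjusted for multiplicity.  The calibrator population is a
free choice (the earliest collection by convention) since only ratios
between populations are identified.

## Synthetic data and what it does (not) establish

The generators are pure functions of (parameters, seed) and are inverted
exactly by the corresponding estimators at zero noise, which pins down
sign conventions end to end.

* **Expression.**  Probe intensities are 2^(true log2 level + array effect
  + cy5 dye offset + N(0, noise_sd) per channel).  Defaults: 1000 probes
  (a desk-scale stand-in for the 8×15K array), 3 replicates per loop edge
  with alternating dye orientation, noise_sd 0.25, dye bias 0.1, array
  effect SD 0.2.  Replicate-level variance was not reported for the
  original arrays; these are stand-ins exposed as parameters.  Planted
  log2 effects are drawn from U(1.2, 3.0) with year-on-year and
  VK7-over-Tengrela increments U(0.7, 1.6), matching the magnitude range
  of the reported fold changes (about 2× to 9× and beyond, with
  between-year differences of 1.4×–3.6×).  Each planted class violates
  the single filter rule it is named for, with one structural exception:
  a probe down against MAL in 2012 while up in 2011 *necessarily* also
  violates the 2012-greater-than-2011 rule — the two conditions cannot be
  decoupled for sign violations — so the `fails_step_B` class violates B
  and, as a consequence, E; tests assert such probes are removed at the
  A–C stage and never reach the final list.
* **Genotypes.**  Two haplotypes i.i.d. from the specified frequencies
  (L-Y structurally zero by default); survival odds are a baseline times
  the product of per-copy haplotype odds ratios; sampling continues until
  both outcome arms are filled, which leaves odds ratios unchanged.  Note
  the estimand of the marginal 2×2 haplotype table is the *allelic* OR,
  which for a per-copy (non-collapsible logistic) effect of 2.7 sits near
  2.6 at these frequencies — the recovery band in the validation accounts
  for this, and no attempt is made to tune it away.
* **qPCR.**  Target Ct shifted by −log(level)/log(E) cycles; reference Ct
  constant across populations up to noise.

What passing these checks shows: the estimators are unbiased under the
assumed noise model, calibrated under the null, and exactly invert their
own generative conventions.  What they do not show: robustness to spatial
artefacts, saturation, probe-specific dye bias, genotyping error, or
cross-hybridization — none of which the generators emulate.

## Validation problem sizes

The shipped validation uses: 200-probe null simulations × 200 runs for
p-value calibration (pooled KS) and BH false-discovery proportion;
500-probe planted simulations for zero-noise recovery; exhaustive Fisher
enumeration over all 2×2 tables with margins ≤ 30 up to the row/column
swaps under which the p-value is invariant; 50 random small genotype
datasets against the grid-search MLE oracle; and 200 genotype simulations
at 2000 specimens per outcome arm for odds-ratio recovery.  These sizes
make the whole validation run in a few minutes on a laptop while keeping
every Monte-Carlo bound comfortably away from its threshold.

## Known limitations

* Per-probe OLS without variance moderation is noisier at very small
  replicate numbers than shrinkage approaches; it is the transparent
  baseline the cascade needs, and moderation is a natural extension.
* The per-experiment fits assume independent array variances per year;
  a pooled two-experiment model is not provided.
* EM phasing is limited to the two kdr loci; no multi-locus phasing or LD
  statistics beyond the association tables.
* Primer efficiencies are inputs; standard-curve estimation from dilution
  series is out of scope.
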