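# Methods

## The measurement and the model

Plate-based ribosome-association screens produce, for every well of a
multi-well plate, two 3'-end RNA-seq libraries from the same lysate: a
**total** library of polyadenylated RNA and a **ribo** library of
ribosome-bound RNA captured by pan-ribosome immunoprecipitation (IP).
After gene-level counting, the data are two gene × well integer matrices
sharing gene and well indices.

**Ribosome association (RA)** for gene *g* in well *w* is the log-scale
ratio of normalized ribo counts over normalized total counts; on a log2
transform this is a difference:

    RA_gw = log2(ribo_gw / s_w^ribo + c) − log2(total_gw / s_w^total + c)

with per-library size factors *s* and pseudocount *c* (default 1.0). It
proxies the fraction of a transcript's pool that is ribosome-bound.
**lfcRA** subtracts, per gene, the mean RA over vehicle-control (DMSO)
wells, giving each drug-treated well a log2 fold change from baseline.

### Normalization and transform

Size factors use median-of-ratios: `s_w = median_g count_gw / geomean_g`,
the median over genes with all-positive counts of the ratio of a well's
count to that gene's geometric mean across wells. Spike-ins and
blacklisted (poly(A)-minus) genes are excluded from the reference because
spike-ins are present in only half the wells and would distort factors.
Factors are reported unscaled; only their ratios are identified, and they
enter the GLM as offsets where an overall constant is absorbed by the
intercept.

The variance-stabilizing transform is the fully specified log-shift
`log2(count/s + c)`. It matches the log-ratio semantics of RA in the
moderate-count regime where RA is interpretable; it does not reproduce the
parametric VST curve of count-model packages at very low counts (values
compress toward 0 instead of plateauing).

### Differential RA: NB GLM with a condition × library-type interaction

For one drug versus control, the ribo and total libraries of the selected
wells are stacked into one sample set and each gene is fit with a log-link
negative-binomial GLM (variance `mu + alpha*mu^2`):

    full:    ~ condition + type + condition:type
    reduced: ~ condition + type

with log size factors as offsets. The interaction coefficient is the
between-condition change in the log ribo:total ratio — differential RA —
reported as lfcRA on the log2 scale. Significance is a likelihood ratio
test against chi-square with 1 df, with Benjamini–Hochberg adjustment per
contrast; genes that are all-zero, annotation-excluded, or non-convergent
are reported NA and excluded from the BH denominator.

Fitting is Fisher scoring (IRLS), batched across genes with a shared
design matrix. Numerical choices: convergence when every score component
is below 1e-8, at most 100 iterations, step-halving when a step lowers the
penalized likelihood, linear predictor clipped to ±50, and a ridge penalty
of 1e-6·‖β‖² as a fallback for separated fits (an all-zero design cell);
ridge-assisted genes are flagged `ridge` in the output status column.

### Dispersion estimation

Per-gene dispersion is profile maximum likelihood given fitted means from
a preliminary Poisson fit of the full design (the full 2×2 design with
interaction is saturated on cell means, so the means are essentially exact
regardless of dispersion). The profile likelihood is Cox–Reid adjusted —
subtracting `0.5·logdet(XᵀWX)`, `W = mu/(1+alpha·mu)` — which removes most
of the downward bias of plug-in ML dispersion at these sample sizes; the
optimum is located on an 81-point log grid over [1e-8, 30] and refined by
quadratic interpolation in log-alpha. A robust (Huber) regression of the
per-gene estimates on `1/mean` gives the trend `alpha_tr(m) = a0 + a1/m`;
the final dispersion is the weighted geometric mean of the gene estimate
and the trend (weight 0.5 toward the trend by default), floored at 1e-8.
This specified moderation stands in for empirical-Bayes machinery: it is
simple, and its consequences are calibration-tested (null LRT p-values
pass Kolmogorov–Smirnov uniformity at 2000 genes).

## Quality control

**Spike-in depletion.** ERCC spike-ins are not ribosome-bound, so their
log2 ribo:total ratio (summed normalized counts, computed per well over
spike-in-bearing wells) should sit far below the same ratio over genes.
Counts are normalized per library *before* summing. The comparison is a
one-tailed paired Wilcoxon signed-rank test (spike component < gene
component): zero differences dropped; exact null for n ≤ 25 without ties;
with ties and n ≤ 12 the null is enumerated over all 2ⁿ sign assignments
with midranks; otherwise a tie-corrected normal approximation. The same
logic, via a one-tailed Mann–Whitney U, contrasts ncRNA against coding
genes in the RA-versus-abundance stratification.

**Saturation and complexity.** Saturation curves thin each library to a
target depth by multivariate hypergeometric draws from the multiset of
gene-assigned reads (sums are exact) and count detected genes. After
gene-level counting no fragment-level information survives, so library
"complexity" is proxied by genes detected at a fixed common depth (default:
the largest depth feasible for ≥ 90% of libraries), with the raw
library-size ratio available as an alternative proxy. The per-well
ribo:total complexity ratio is corrected by the quotient of lysate input
fractions; its plate mean ρ, divided by the assumed polysome-associated
fraction of polyadenylated mRNA (f_p, default 0.80 from the literature),
estimates IP efficiency: η = ρ/f_p (0.17/0.80 ≈ 21%).

## Screen analytics

- **PCA / outliers:** column-centered covariance PCA (scikit-learn) of RA
  or lfcRA restricted to genes significant in any condition; wells with a
  robust z (median/MAD) above k = 4 on either of the first two components
  are flagged. The outlier rule is a declared stand-in — the numeric rule
  used in comparable published screens is typically unstated.
- **Target sets:** per condition, up = {FDR < q, lfcRA > 0} and down
  analogously; an exclusive mode removes genes shared by two conditions'
  same-direction sets from all of them.
- **Preranked enrichment (classic):** genes ranked by score descending,
  ties broken lexicographically by gene ID; running sum +1/Nh at hits,
  −1/(N−Nh) at misses; ES is the signed maximum deviation; null from
  gene-label permutations (default 1000, seeded); NES = ES / mean |null ES|
  of matching sign; one-sided nominal p = (b+1)/(n_perm+1); family-wise
  adjustment is Bonferroni over the reported set family.
- **Attenuation:** for genes significant under either constituent drug of
  a combination, x is the constituent lfcRA of larger magnitude and y the
  combination lfcRA; attenuated = same sign and |y| < |x| (y = 0 counts as
  attenuated), enhanced = same sign and |y| ≥ |x| (the boundary |y| = |x|
  is "equal effect", hence enhanced), reversed = opposite sign. The three
  classes partition the tested genes.
- **Network:** significant down-targets of each kinase inhibitor are that
  kinase's positive targets; every nonempty region of the Venn partition
  is tested for canonical/candidate TOP-gene enrichment with a one-sided
  Fisher's exact test over the analysis universe, BH-adjusted across all
  (region, set) tests. Fisher tests are one-sided for enrichment by
  default (two-sided available), matching the directional claim the
  network is built to probe.

## The synthetic plate generator

`simdata` draws paired plates with the statistical structure the analysis
assumes, plus full ground truth, so every downstream stage is testable
without sequencing data.

Mean structure: gene abundances are log-normal (log-mean 0, log-sd 1);
spike-ins use a fixed half-log abundance ladder scaled to 2% of the
transcript pool and appear only in alternating plate columns (half-plate
design). Per-well expected depths are gamma with CV 0.2; the ribo library
defaults to 0.17× the total depth, mirroring the observed complexity
ratio. The total mean is `depth_w · p_g`; the ribo mean is
`depth_w^ribo · p_g · ra_g · 2^effect · ip_efficiency`, where baseline RA
is 0.9 for coding genes, 0.3 for ncRNA and 0.2 for spike-ins with a small
log2-normal jitter (sd 0.25, capped at 1). Per-condition effects are
multiplicative on RA and concentrated on designated gene sets (canonical
TOP of 97 genes and candidate TOP of 182 by default); under a combination
"A+B" the truth effect is exactly `attenuation_factor × (effect_A +
effect_B)` (log2-additive before attenuation).

Counts are negative-binomial with `var = mu + alpha·mu²` and the trend
`alpha(mu) = a0 + a1/mu` (defaults a0 = 0.01, a1 = 2.0, in the range
typical of bulk 3'-end counting). The trend is evaluated **per gene** at
its mean expected count across all libraries, giving one dispersion per
gene shared by the ribo and total draws — deliberately the structure the
gene-wise NB model assumes. Evaluating the trend per observation instead
would make the shared-dispersion model misspecified across the very
different ribo and total depths and the interaction LRT intrinsically
anticonservative; the generator's job here is to emulate the analysis's
assumptions, not to model library-preparation differences it cannot see.

Random-number consumption order is fixed (abundances → RA jitter →
extra-set membership → per-condition target choice in sorted condition
order → total depths → ribo depths → total counts → ribo counts) so seeds
are portable.

What the generator does **not** emulate: batch effects beyond per-well
depth, UMI/duplication structure, positional footprint information,
library-type-specific dispersion, and composition shifts from extreme
regulation. Passing tests therefore demonstrate correctness of the
statistical machinery under the model's assumptions, not robustness to
every artifact of real plates.

## Problem sizes used in the test suite

The statistical acceptance tests run at the design conditions of the
screen they emulate: 2000 coding genes with 4+4 wells per library type at
5×10⁵ reads for null calibration (5 seeds); 200 targets with an effect of
−1 log2 at 8+8 wells and 10⁶ reads for power and bias (3 seeds); 96-well
plates with 48 spike-in-bearing wells for depletion QC; and 8-well arms at
10⁶ reads for the three-drug network and combination-attenuation
recoveries. Batched IRLS keeps a full 2000-gene contrast under ~3 s, so
the whole suite runs in well under a minute of compute.

## Known limitations

- The log-shift VST diverges from parametric VSTs at very low counts.
- One dispersion per gene across both library types; true prep-specific
  overdispersion would be absorbed into the interaction-test error.
- The LRT is asymptotic (chi-square, 1 df); calibration is verified at the
  tested sample sizes, not guaranteed for much smaller designs.
- Complexity proxies operate on gene-level counts; they are not estimates
  of unique-fragment complexity and should be compared only within a
  consistently processed plate.
- Counts of significant genes depend on unstated filtering conventions of
  other pipelines and are not comparable across implementations.
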