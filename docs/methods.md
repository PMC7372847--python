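# Methods

`linepanel` analyses trait variation in panels of iso-female inbred lines of
a haplodiploid insect (wasp-style sex determination: fertilised diploid eggs
become daughters, unfertilised haploid eggs become sons, so a mother's sex
ratio is the proportion of eggs she fertilises).  The pipeline covers pooled
window diversity statistics, linkage-disequilibrium (LD) decay, pairwise line
F_ST and a population-structure check, broad-sense heritability, a
permutation-thresholded single-marker GWAS on brood sex ratios and clutch
sizes, a cross-trait window-overlap test, and a lightweight variant-effect
classifier.  A synthetic panel generator supplies ground truth for every
stage.  This note records the models, the defaults and their rationale, the
numerical choices, and the known limits of what the synthetic tests show.

## Synthetic panel generator

**What it emulates.**  An outbred source population sampled into 25–34
iso-female lines, each founded by one mated female and driven towards
homozygosity by one mother–son backcross followed by eight brother–sister
generations (haplodiploid transmission throughout: sons are haploid,
develop from unfertilised eggs carrying one recombined maternal haplotype,
and produce clonal sperm).  Defaults: 34 lines (8 flagged as having lost
their *Wolbachia* infection, 1 flagged as a sex-ratio outlier, leaving 25
analysable), 5 chromosomes of 59 Mb with 20 000 SNPs each (~10^5 SNPs),
call missingness 4.2%, 38 broods per line with mean clutch 60 (sd 15) and a
mean proportion male of 0.14, in the female-biased regime expected under
local mate competition.

**Founder LD model.**  Each founder haplotype is a copy/refresh Markov walk
along the chromosome: between adjacent SNPs separated by `d` bp the latent
state is copied with probability `exp(-p_sim * lambda_h * d)`.  The
haplotype-specific intensity `lambda_h ~ Gamma(shape = 1/2, scale = 1)`
makes the panel-level allelic correlation the Gamma mixture
`E[exp(-p d lambda)] = (1 + p d)^(-1/2)`, i.e. mean `r^2 = 1/(1 + p_sim d)`
— an exact hyperbolic decay.  A single-rate Markov walk cannot do this: its
correlations multiply over intervals and therefore decay exponentially.
The mixture also produces realistic genome-wide variation in local LD
(haplotypes with tiny `lambda` create long conserved segments), which the
decay-landscape module visualises.  `ld_mixture="fixed"` switches to the
homogeneous single-rate walk, where `r^2 = exp(-2 p_sim d)`; the landscape
is then flat, which is what the flat-landscape test uses.  Default
`p_sim = 1/17800` per bp (half-decay 17.8 kb, inside the 10–20 kb regime of
sib-mating species).

**Founder allele frequencies.**  Default spectrum is symmetric (all founder
frequencies 1/2).  With the copy/refresh construction, heterogeneous
per-site frequencies attenuate r^2 below the hyperbola at short range
(correlation of indicators thresholded at different frequencies is < 1 even
for a shared latent state), so the exact LD calibration only holds with
equal frequencies.  Panel-level frequency spread then arises from sampling
~25–34 lines out of the pool — which also reproduces the common-variant
regime (panel mean MAF ≈ 0.42).  A `beta` spectrum is available; its r^2
attenuation is a documented approximation.

**Inbreeding.**  The analytic reference is the diploid full-sib recursion
`F_t = (1 + 2 F_{t-1} + F_{t-2})/4`, checked against a pedigree Monte-Carlo;
it gives F(10) = 0.886 and an expected segregating fraction `1 - F`.  The
simulated pedigree is explicitly haplodiploid and reaches lower residual
heterozygosity (~4–6% realised) than the diploid 9-generation expectation
(13–14%), consistent with the faster fixation of sib-mating with haploid
males.  Panels of real lines show still lower values (~2–3%), plausibly due
to selection during inbreeding, which the generator does not model.

**Phenotypes.**  Per line, `logit(p_line) = beta0 + sum_j beta_j g_j +
u_line`, `u_line ~ N(0, sigma2_L)`; brood male counts are
`Binomial(clutch, p_line)`; clutch is a rounded truncated normal with its
own line effect and optional SNP effects.  `sigma2_L` defaults to the value
solving the variance-partition identity on the arcsine-square-root scale,
`H^2 = p(1-p) sigma2_L / (p(1-p) sigma2_L + 1/n)` with `n` the mean clutch
— the within-brood variance of `asin(sqrt(y/n))` is ~`1/(4n)` regardless of
`p`, the among-line variance ~`p(1-p) sigma2_L / 4` — calibrated to
`H^2 = 0.106` (clutch analogously to 0.078).

**What passing tests do not show.**  The generator has no selection, no
demographic history, no sequencing-error model, no genotype-likelihood
uncertainty and no *Wolbachia* dynamics (status is a metadata flag).  Tests
on it validate the estimators and procedures, not absolute real-data values.

## Population-genetic statistics

Window diversity uses the classical estimators on coverage-standardised
allele counts: sites are subsampled to a fixed draw count `n` (default 20;
multinomial with replacement; sites below min-coverage 10 or above
max-coverage 400 are unusable), alleles below `min_count` (default 5) are
treated as absent, per-site `pi = n/(n-1) (1 - sum f_i^2)`, Watterson
`theta = S/(a1 L)` with `L` the usable sites in the window, and Tajima's D
from the standard constants with that same `n`.  The pooled-sequencing bias
corrections of dedicated pool-seq window tools are deliberately not
replicated — this package implements the classical statistics, so absolute
values are comparable only approximately with such tools.  D is reported
missing (not zero) when `S = 0`; windows below the covered fraction are
omitted.  Default geometry is non-overlapping 400-kb windows; an
overlapping step is supported.

Pairwise line F_ST treats each line as a two-allele population (residual
heterozygote = frequency 1/2) with the Hudson per-site estimator.  Two
combination rules are provided because they answer different questions:
the default ratio-of-averages over sites variable within the pair is the
robust Hudson form, and for nearly fixed inbred lines it is necessarily
large (~0.8–0.95: concordantly fixed sites add zero to both sums);
`universe="panel"` averages per-site values over all panel-variable sites
called in the pair, counting concordant sites as zero, which lands in the
0.2–0.5 range conventionally printed for inbred-line panels.  Values are
clamped to [0, 1] for reporting with the raw ratio retained.  Line
clustering is complete-linkage on the F_ST matrix (scipy), and the
structure check is the Spearman correlation between pairwise F_ST and
absolute line-mean phenotype distance — a non-significant value justifies
scanning without a relatedness correction.

## LD decay

Pairwise `r^2` is the squared Pearson correlation of homozygous allele
codes across lines, pairwise-complete over heterozygous/missing calls
(minimum 10 complete lines per pair), within 1 Mb by default.  Because only
homozygous calls enter, outbred diploid panels are not a valid substrate
(conditioning on homozygosity at two linked sites selects long shared
haplotypes and inflates r^2); inbred panels are the intended input.  The
decay model `r^2 = 1/(1 + p x)` is fitted by trust-region nonlinear least
squares starting from `p0 = 1/median(distance)`, deterministic given the
pairs; `p` collapsing below one tenth of the data span flags the degenerate
flat case.  The model forces `r^2(0) = 1`; sampling noise at near-zero
distance is absorbed by the fit rather than an intercept.  Half-decay is
`1/p` exactly and the level-crossing distance is `(1/v - 1)/p`.  The
landscape applies the same fit per focal SNP over its flanking pairs
(missing when fewer than 10 pairs); both a pooled global fit and per-SNP
fits are available, the pooled fit being the headline.

## Among-line variation and heritability

The among-line sex-ratio test is a quasi-binomial GLM F-test: logit-link
GLM of (males, females) on line, dispersion from the full model's Pearson
chi-square, `F = (deviance difference / df) / dispersion` on
(n_lines - 1, n_broods - n_lines) df.  Broad-sense heritability comes from
a one-way random-intercept model fitted by REML, profiled to a single
optimisation over the variance ratio so the full and null restricted
likelihoods share constants exactly; `H^2 = V_line/(V_line + V_res)`, and
the LR against the no-line-effect boundary is referred to chi-square(1),
which is conservative at the boundary (asserted by a null simulation).
Sex ratio is analysed on the arcsine-square-root scale, clutch size
untransformed, broods unweighted.  The implementation is cross-checked
against statsmodels MixedLM (whose REML loglik it reproduces exactly at
matched parameters).

## Single-marker GWAS and the empirical threshold

Because a candidate genotype is constant within a line and broods are
conditionally independent given the line effect, the brood-level binomial
GLMM with a line random intercept reduces exactly to a line-aggregated
binomial logit-normal model — one (males, total) observation per line with
`logit p = b0 + beta g + sigma z`, `z ~ N(0,1)`.  It is fitted by
Gauss-Hermite quadrature (20 nodes) maximum likelihood with analytic
gradients; p-values are LR tests of the genotype effect against the cached
per-missingness-pattern null.  One numerical subtlety matters: with a
strong genotype effect the null optimum (beta = 0, large sigma) is a
near-stationary saddle of the full likelihood, so the optimiser is
multi-started from group-mean logits whenever the observed group split
exceeds 0.25 logits.  Clutch size uses the analogous linear mixed model,
profiled to a 1-D optimisation over the variance ratio (exact ML).
Heterozygous/missing lines are dropped per SNP, never imputed.

The significance threshold is empirical: line identity is permuted against
the genotype rows (brood structure intact), the full scan re-run per
permutation (default 100, configurable), and for each candidate cutoff `t`
the estimated FDR is `q(t) =` (mean permutation count of null p <= t) /
(observed count <= t), made monotone by a running minimum from the largest
cutoff down (step-up).  The threshold is the largest `t` with `q(t) <= 0.1`;
if none exists the minimum attainable q is reported and nothing is called.

A power note: with the generator calibrated to `H^2 = 0.106`, a single
variant explaining half the among-line logit variance gives a line-level
t-statistic near 4 at 25 lines, while the permutation threshold at q = 0.1
demands p ~ 1e-3; per-replicate detection is therefore ~55–60%, and the
power check is a fixed-seed regression at that level.  Detection of such
variants in a 25-line panel is intrinsically marginal.

## Cross-trait window overlap

Within each non-overlapping window (25, 50, 100, 200, 400 kb ladders) the
SNPs are ranked by p-value per trait; for rank cutoffs r = 1..min(25, N)
the overlap of the two top-r sets is scored with the exact hypergeometric
upper tail against the window's SNP count N, and the window summary is the
minimum over cutoffs.  Significance compares the observed summary against
100 scans in which SNP identities are permuted; a window is flagged only if
the observed summary is strictly below all 100.  The permutation absorbs
the min-over-cutoffs selection.

Two design points required care.  First, ties: exact-LD SNP clumps carry
bit-identical p-values, and any deterministic tie order shared between the
traits fabricates overlap; ties are broken randomly and independently per
trait (seeded).  Second, the permutation unit: permuting the two traits'
assignments *independently* (the default) tests "no per-SNP coupling
between the traits" while controlling for the window SNP-count structure
the permutation was designed to absorb.  Moving the (p_a, p_b) pairs
jointly instead preserves genome-wide coupling and asks whether it is
concentrated in the window beyond a reshuffling of the coupled pairs — a
reference so strict that genuinely window-localised shared architecture
generally cannot beat it once its LD halo leaks over a window edge (the
permuted minima then track the observed summary, frequently to exact ties
of the discrete statistic).  The joint mode is retained as an option.
Known limitation either way: strong local LD violates SNP-level
exchangeability, so the null rate of the flag rule sits somewhat above the
1/101-per-window background on densely typed panels.

## Variant-effect classification

A deliberately small classifier (not a full annotation engine): gene
models from GFF3 (via gffutils) with validated exon/CDS structure (CDS
length divisible by 3 after phase), reference sequences from FASTA, and
strand- and phase-aware codon translation for CDS variants
(synonymous / missense / stop_gained; stop or start loss is reported as
missense, a documented simplification).  Exonic non-CDS positions become
5'/3' UTR by strand, intronic positions intron variants, flanks within
5 kb upstream/downstream by strand, otherwise intergenic.  A splice-region
flag is added 1–3 bp inside an exon end abutting an intron or up to 8 bp
into an intron (the 1–2 bp splice-site core is folded into the region
flag).  One primary call per SNP is selected by a fixed severity order
(stop_gained > missense > splice_region > synonymous > UTR > intron >
up/downstream > intergenic); the full per-transcript call list is kept.
The category summary reports pN/pS = (missense + stop_gained)/synonymous —
a raw polymorphism count ratio, not a rate-normalised dN/dS.

## Problem sizes used in the test suite

Unit and acceptance runs use desk-scale panels: 2-Mb chromosomes with
120–400 SNPs each, 20–34 lines, thinned quasi-independent scan subsets
(every 16th–20th SNP) for calibration checks, 8–12 permutations for
threshold regression tests (100 for the overlap flag rule, matching its
definition), 100 replicate null panels for scan calibration, 200 replicate
phenotype draws for heritability recovery, and 10 + 5 replicate fixtures
for overlap truth/null checks.  These sizes are the package's choices for
routine verification; all estimators accept full-scale inputs.
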