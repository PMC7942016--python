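# Methods

This note records the models behind `editqtl`, the choices made where the
design was genuinely open, and what the synthetic cohorts do and do not
establish about real data.

## Editing quantification and filters

The editing level of a site in a sample is `Phi = G/(A+G)` over reads
covering the site; `Phi` is undefined (masked) at zero coverage.  Sites
enter QTL analysis when, across a tissue's individuals, mean edited
coverage is >= 2 reads, mean total coverage is >= 10 reads, the spread
between the 90% and 10% quantiles of `Phi` is >= 0.10, and the site does
not coincide with a known SNP (which would mimic editing genetically).
Quantiles are type-7 (linear interpolation); the coverage means include
zero-coverage samples; the quantile spread uses every sample with at
least one read.  For association testing each sample additionally needs
>= 20 reads at the site.  These conventions are configurable arguments.

## cis edQTL model

For each site, `Phi` is regressed by ordinary least squares on alternate
allele dosage (0/1/2) for every SNP with MAF >= 5% within a 400-kb window
centred on the site; the p value is the two-sided t test on the slope
(df = n-2).  The effect size is the raw-scale slope: change in `Phi` per
alternate allele.  The lead SNP is, among SNPs attaining the minimum p,
the one nearest the site; an exact distance tie breaks to the lower
genomic coordinate (an arbitrary but deterministic rule).  A site is an
edQTL when the lead p <= 1e-5.  Covariates (population structure,
technical factors) are deliberately omitted — the model is a plain linear
fit, and the synthetic cohorts contain no confounding — but the design
keeps the regression in one routine so covariates could be residualised
upstream.

The permutation FDR alternative permutes the genotype table's sample
labels jointly across SNPs (preserving LD), recomputes each site's
minimum window p per permutation, and returns the largest observed
minimum-p value `t` with `mean permuted #{minp <= t} / observed #{minp <= t}
<= 0.10`.  B defaults to 5 — a desk-scale setting that keeps the
empirical-FDR numerator stable enough for the simulated cohorts used
here; production-scale use should raise it.

Tissue dependence of a genotype effect is tested in the multivariate
model `Phi = mu + alpha*Genotype + beta*Tissue + gamma*Genotype*Tissue + eps`
with a binary tissue factor (skeletal muscle vs the rest; heart tissues
are not pooled with muscle).  Nested Gaussian fits give the LRT
`n*ln(RSS_reduced/RSS_full)` on one degree of freedom; the same machinery
drives the non-linearity statistic, where the full model is quadratic in
dosage and the shift is the quadratic fit at dosage 1 minus the
homozygote-only line at dosage 1.  The Gaussian error model is a choice —
the tests are asymptotic, which the null-calibration experiments bear out
at the simulated sample sizes.

## Allele-specific editing

Per-allele confidence intervals invert the binomial likelihood ratio:
the 95% interval is `{p : 2[l(Phi_hat) - l(p)] <= chi2_1(0.95)}`, found by
bisection to 1e-9; `g = 0` and `g = n` pin the respective boundary
exactly.  The paired test models individual `j`'s two haplotypes as
binomials with `Phi_ref = expit(mu_j + delta/2)` and
`Phi_alt = expit(mu_j - delta/2)`: a per-individual baseline absorbs
between-individual variation, and one shared `delta` (the allele effect
on the logit scale) is the quantity of interest.  The likelihood is
maximised by profiling — Newton in each concave `mu_j` at fixed `delta`,
Brent over `delta` — and `H0: delta = 0` (where the per-individual MLE is
the pooled proportion, in closed form) is tested against chi-square with
1 df.  The symmetric `+/- delta/2` parameterisation makes allele-label
swaps negate `delta` and leave the p value exactly unchanged.  Complete
separation (an allele at 0% or 100% throughout) is detected from the
counts and flagged; the p value is then computed at the boundary and
should be read qualitatively.  This fixed-effects construction stands in
for hierarchical paired-replicate frameworks: with editing usually having
modest per-site depth, the per-individual-baseline LRT calibrates well
(empirical type-I ~= 0.052 at alpha = 0.05, depth 50, five individuals)
at a fraction of the cost.  Usability filters: both alleles covered,
pooled editing >= 1% (pooled, not per allele — the per-allele reading
would discard exactly the strongly allele-specific sites of interest),
and >= 3 heterozygous individuals.  Benjamini-Hochberg controls the FDR
at 10% across pairs.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor: with
`z = beta/se`, `V = se^2`, `r = W/(V+W)`,
`log ABF = 0.5*log(1-r) + r*z^2/2`.  `W = 0.15^2` for quantitative traits;
priors `p1 = p2 = 1e-4` (a SNP is causal for one trait) and `p12 = 1e-5`
(causal for both) are the conventional defaults — all configurable.
Hypothesis sums are accumulated in log space; the two-distinct-variants
term is `S1*S2` minus the diagonal, computed with a stable
log-difference, and degenerates to zero mass at a single shared SNP.
When a trait arrives as p values only (GWAS extracts), z is recovered
from the two-sided p (sign attached if reported) with unit standard
error, and that trait's prior variance switches to `W = 1` on the z
scale; the effect-scale default would otherwise shrink z-based evidence
toward nothing.  Posteriors are exact normalised ratios, so they sum to
one to floating-point accuracy regardless of SNP count.

## miRNA targeting and the degradation model

Mature miRNA abundance is proxied by reads overlapping the cleavage
product of the primary transcript divided by the sample's total aligned
reads, then scaled per miRNA so the largest sample value is 1.  The seed
scanner implements the three canonical site classes on the target read
5'->3': 7mer-m8 (exact Watson-Crick complement of miRNA positions 2-8),
7mer-A1 (complement of positions 2-7 followed by A), 8mer (both); each
start position takes its strongest class.  Context scoring and wobble
pairs are deliberately out of scope — the dichotomy the pipeline needs is
whether a site exists in the edited sequence (A replaced by G at the
editing position), the unedited sequence, or both, and only matches whose
span covers the edited position count as editing-specific.

The steady-state degradation model removes a fraction `d` of the targeted
transcript version.  Targeting unedited:
`E = Phi + (1-d)(1-Phi)`, `Phi' = Phi/E`; targeting edited:
`E = (1-d)Phi + (1-Phi)`, `Phi' = (1-d)Phi/E`.  `E` is the surviving
transcript fraction and `Phi'*E` equals the surviving edited fraction
identically — asserted on a dense grid at relative tolerance 1e-12, the
float round-trip limit of the division.  Because `Phi -> Phi/E` is convex
increasing, unedited-targeting degradation lifts the heterozygote above
the homozygote chord (positive non-linearity shift) and creates an eQTL
in the edQTL's direction; edited-targeting flips the eQTL sign.

The differential-editing test for miRNA perturbation experiments is a
beta-binomial LRT: replicates share a condition mean, the two conditions
share a dispersion `rho` estimated once under the full model by profile
likelihood and held fixed while refitting the common-mean null.
Re-estimating the dispersion in both fits is markedly conservative with
2-3 replicates (the boundary estimate absorbs mean differences); the
fixed-dispersion LRT is calibrated under binomial truth (~0.046 at
alpha = 0.05) and inflates far less than a pure binomial test when the
data are overdispersed (~0.18 vs ~0.42 at rho = 0.05) — the reason
overdispersion is modelled at all.  Significance requires both
`|delta Phi| >= 0.05` (pooled difference; the per-replicate-mean variant
is not used) and BH FDR <= 0.05.

## Synthetic cohorts

The generator emulates: Hardy-Weinberg genotypes at MAFs uniform in a
configurable range (default 0.1-0.5) with explicit haplotypes; editing
effects additive on the logit scale, `Phi = expit(logit(baseline) +
enzyme*slope*dosage)`, with a per-tissue enzyme multiplier in [0,1]
standing for ADAR/ADARB1 abundance (0.2 emulates skeletal muscle);
Poisson total coverage (default mean 50) with beta-binomial edited reads
(default dispersion 0.01 — the noise model of real editing levels is not
established, so this default is an explicit choice); and log-normal
multiplicative expression noise.  Heterozygotes are generated as two
haplotype transcript pools whose logits sit at `eta_het +/- enzyme*slope/2`
around the heterozygote dosage-formula logit: the pooled mean then tracks
the dosage formula while the allelic logit contrast equals the per-allele
cis effect exactly (what the ASED test estimates), and haplotype-resolved
counts sum to the sample totals by construction.  Placing the haplotypes
at `eta0` and `eta0 + enzyme*slope` instead would force the heterozygote
mean below the homozygote chord for every positive slope — a geometric
artifact that would mask the degradation-induced non-linearity the
pipeline is designed to detect.  miRNA couplings apply the degradation
model per haplotype pool, with the effective rate `d` scaled by the
tissue's normalised miRNA level; read shares of the two haplotypes follow
their surviving transcript fractions.  The default cohort (200
individuals, coverage 50, dispersion 0.01) matches the conditions under
which the recovery experiments are run.

Because the generative effect is logit-additive and the edQTL regression
is linear in `Phi`, the recoverable truth is the linearization
`Cov(E[Phi|G], G)/Var(G)` under the realized genotype distribution, and
recovery is scored against it (within 15% for >= 90% of sites at the
default conditions).

What the synthetic cohorts do **not** emulate: linkage disequilibrium
beyond a single causal SNP per site, population structure, covariate
confounding, mapping artefacts at true SNPs, shared hyper-editing
structure between neighbouring sites, and realistic 3'-UTR base
composition.  Passing tests therefore demonstrate correctness of the
statistics and the pipeline logic under the stated generative model, not
robustness to the confounders of real population RNA-seq.

## Numerical conventions

Coordinates are 1-based inclusive internally, BED export is 0-based
half-open (site p -> (p-1, p)), VCF is 1-based; minus-strand UTR
sequences are stored as mRNA 5'->3'.  Missing dosages are dropped
pairwise per test.  Constant-dosage or under-sampled associations are
flagged rather than raised.  All randomness flows through
`numpy.random.default_rng` seeded from a single integer; fixing the seed
fixes every emitted byte.  Experiment sizes in `editqtl.experiments`
(2000 null tests, 100 recovery sites, 100 mechanism replicates, 50
colocalization replicates) are the package's chosen desk-scale study
conditions; all accept larger values.

## Known limitations

The permutation-FDR scheme is a pooled-minimum-p stand-in for
site-specific permutation calibration.  The paired ASED test's chi-square
reference is asymptotic in read depth and mildly anti-conservative at
very low depth.  The seed scanner reports overlapping sites of different
classes at adjacent starts rather than merging them.  Three-trait
colocalization, trans-QTLs, conditional secondary signals, covariate
inference, and read-level simulation are out of scope.
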