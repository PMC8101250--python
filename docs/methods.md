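# Methods

This note documents the models implemented in `tipflow`, the assumptions of
the synthetic-cohort generator, the numerical choices, and the limits of what
the test suite establishes.

## TIP genotyping and the filter cascade

Candidate calls carry, per sample and site: split/discordant read counts per
side, positive coverage (reads supporting the variant), negative coverage
(reads supporting the reference state), reference coverage over the site
(`site_cov`), and mean flanking coverage 100 bp up/downstream. Intervals of
the same chromosome, TE family and variant class are merged by transitive
overlap; the representative position is the midpoint of the intersection of
member intervals, falling back to the midpoint of the union when chained
overlaps make the joint intersection empty. Per-accession evidence is
aggregated across member calls with `max` (configurable to `sum`): the merged
call should be as strong as its best member, not inflated by double-counting
the same reads.

State calling: *present* requires positive coverage ≥ DP (default 3) **and**
`site_cov < 0.8 × flank_cov`. True non-reference insertions interrupt the
reference alignment, so a coverage drop is expected over the site; 0.8 is a
package choice (the expectation of a drop is qualitative) and is configurable.
*Absent* requires negative coverage ≥ DP without qualifying positive evidence
— the DP threshold is applied symmetrically to negative evidence so that
"absent" is as supported a call as "present". Anything else is NA
(uninformative genome).

Population filters run in a fixed order, each logged with its removal count:
(1) a (superfamily, class) blacklist, by default HELITRON presence variants,
which split-read pipelines do not detect reliably; (2) sites with fewer than
`min_informative` non-NA genomes (default 100; parameterized so toy panels can
exercise the boundary); (3) presence sites where no carrier has positive >
negative coverage — heterozygous-like evidence that, in a selfer, indicates a
very recent lab event or an artefact; (4) absence sites flagged as fragmented
reference TEs or as ancestral (shared with the outgroup), which reflect
rearrangements rather than recent mobilization. The flags are inputs; the
outgroup comparison itself is out of scope.

The capture filter (for TE sequence-capture experiments) keeps calls with
split + discordant support between 2 and 15 on *each* side, not spanning
centromeric repeats or the donor element, and detected in exactly one library
(sample-specific new insertions).

## Frequencies, SFS, dating, very recent TIPs

Site frequency = carriers / informative genomes. The folded SFS is a histogram
of MAF = min(f, 1−f) in 500 equal bins on [0, 0.5], written in a text layout
usable as input to DFE-estimation software (DFE fitting itself is out of
scope). Numerical choice: MAF is snapped at 12 decimals before binning so that
folding is exactly symmetric — f and 1 − f differ by one ulp in floating point
and would otherwise straddle a bin edge.

Insertion age = (max pairwise SNP count among carriers in a 70-kb window /
70,000) / μ with μ = 7e-9 per site per generation. The divergence is **not**
halved for two-lineage accumulation — the definition divides the observed
divergence by the mutation rate directly; a `two_lineages` switch is provided.
One generation is treated as one year (an annual plant). Very recent TIPs:
frequency < 0.2% and (private or age < 1000). The frequency threshold is
parameterized because a private site in a panel of n < 500 has frequency
1/n > 0.002; species-scale panels use the default.

## Substitution rate and elimination

No-intercept least squares b = Σxy/Σx², SE = sqrt(RSS/(n−1)/Σx²). The
substitution rate is b_close × 0.2511 (the genome-wide SNP substitution rate).
κ is defined as the ratio of synonymous-SNP fractions (distant over close
pairs): selection removes non-synonymous SNPs over time, so distant pairs are
enriched for synonymous ones, and multiplying observed distant SNP divergence
by κ restores its neutral-equivalent value. The elimination fraction
1 − b_all/(κ·b_close) is clipped to [0, 1): sampling noise can push the raw
value slightly negative in the neutral limit. Its SE comes from the delta
method on the slope ratio with κ treated as fixed.

## Gene impact

Each insertion point receives exactly one category with precedence
exon > 5′UTR > 3′UTR > intron > promoter/near (≤ 250 bp, strand-aware) >
within 2 kb > intergenic. The "nearest gene" used for expression contrasts is
the feature-assignment gene (the containing or nearest annotated gene), not a
separately computed nearest neighbour.

The recurrence null redistributes the observed number of TIPs uniformly over
the genome (10 replicates by default) and counts genes hit within 250 bp;
the analytic expectation Σ_g 1 − (1 − p_g)ⁿ with p_g = extended-span/genome
length is exact under the uniform model and is used as the test oracle.
Multi-hit enrichment is a Fisher exact test against the rounded permutation
expectation (the real contingency table is not observable).

Expression impact is the carrier/non-carrier mean ratio with a pseudocount of
0.5 expression units on both means (avoids division by zero at knock-outs);
a ratio ≤ 0.1 flags an effective knock-out (configurable — no numeric rule is
standard). The extreme-ratio null redraws, per TIP, a random pseudo-carrier
set of the same size and recomputes ratios; extremeness thresholds are
per-category quantiles of the pooled null. Combined per-gene effects pool
carriers of any allele against carriers of none, with a two-sided rank-sum
test and Benjamini–Hochberg correction across genes (the choice of rank-sum
is a package decision; the significance statistic for this contrast is
otherwise unconstrained).

## Environmental model

PVE of a GLM is the deviance pseudo-R², 1 − D_res/D_null — "variance
explained" has no unique GLM definition and this one is monotone under
nesting. Stepwise selection is greedy forward over {each bio-variable as a
fixed effect} ∪ {each as a modifier interaction, entering jointly with its
main effect — hierarchy principle}; the stop rule is strict (ΔPVE must exceed
0.01), ties break by candidate name. Kinship is "taken into account"
everywhere as its top three principal components used as fixed covariates,
including in the binomial CE-shift models.

The restricted Mantel test residualizes the count-distance and
bio-variable-distance matrices (absolute differences) on the kinship distance
(1 − kinship normalized to unit diagonal) and correlates the residuals;
significance uses row/column-coherent permutations with
p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), never zero. Climatic envelopes are
PCA components of the z-scored bio-variables with a deterministic sign
convention (largest-magnitude loading positive). CE-shift tests are run per
CE with BH correction within CE; the `permute_env` flag shuffles the
environment across accessions once as a negative control.

Forecasting holds all genetic terms fixed and replaces only the bio-variable
columns, with future values z-scored by **current** means/SDs; future =
current therefore implies identically zero deltas, asserted to 1e-12. Hold-out
validation draws 100 random testing sets of 100 accessions, refits each
competing design on the complement, averages per-accession predictions, and
flags accessions whose mean error exceeds 4 SD; "predictive variance" is the
variance of per-accession mean prediction errors (the summary is not uniquely
defined; this reading directly measures predictive accuracy).

## The synthetic generator

The generator produces every input the pipeline consumes, on a single linear
toy chromosome (default 1 Mb, 0-based half-open coordinates; 2.5 Mb in the
species-scale acceptance run) with non-overlapping genes carrying
exon/intron/UTR substructure, a central centromeric segment, and sites placed
on a coarse grid (≥ 120 bp apart) so that distinct generated sites can never
merge accidentally.

Panel: n accessions in k genetic groups; kinship is the correlation of a
low-rank latent factor matrix (group centers scaled by `kinship_strength`
plus unit noise), and the kinship PCs are its top eigenvectors. A modifier
allele segregates at a configurable frequency; its default effect is a
3.4-fold (240%) increase in transposition. Climate has group-correlated
gradients on 19 bio-variables with plausible raw scales; the future epoch adds
a warming shift to temperature variables and a relative change to
precipitation.

TIPs: background sites draw carrier counts k with P(k) ∝ k^(−skew)
(rare-skewed; skew → ∞ makes every site private); very recent insertions are
private, one site per event, with per-accession event counts Poisson with
log-link on modifier, bio-variables and interactions — the same family as the
downstream GLM, so recovery tests are well-posed. Coverage evidence is
independent Poisson per accession-site (depth 10 by default): simple, but
sufficient to exercise every filter branch, and configurable fractions of
sites violate each filter (low DP, few informative genomes, positive ≤
negative in all carriers, flagged absences, HELITRON presence). Ground truth
records every site label and generating parameter.

Divergence pairs use a star-like genealogy summary: close pairs (same group,
Poisson SNPs with mean 200, truncated below 500) accumulate TIP differences at
`slope_true` per SNP; distant pairs (mean 20,000 SNPs) are attenuated by the
retention probability after neutral rescaling, so the estimator's elimination
fraction has expectation 1 − retention. Synonymous counts are binomial with a
higher fraction in distant pairs (factor `syn_enrichment` = true κ). Setting
`base_rate = 0` forces all TIP differences to zero. Expression is log-normal
per gene with carriers multiplied by a configured effect (0 = knock-out) at a
configurable fraction of genic TIPs. Dating windows draw max-pairwise SNP
counts as Poisson(70,000 · μ · age) — a one-lineage model matching the
estimator's definition.

What the generator does **not** emulate: read-level data, linkage and
recombination, a coalescent, methylation, TE excision, shared mutational
histories between nearby sites, or spatially autocorrelated climate. Passing
tests therefore demonstrate that the estimators recover parameters under
their own model assumptions and that the filters and nulls behave as
specified — not that the pipeline is robust to the misspecifications of real
data.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds; identical
config + seed reproduces cohorts bit-identically, including on-disk outputs.
The test suite uses cohorts of 40–1000 accessions; coverage and calibration
checks use 100–200 replicate seeds (CI coverage of the modifier coefficient at
n = 1000; stepwise recovery; Mantel p uniformity at 1000 permutations; CE-shift
FDR under uniform carriers; extreme-ratio excess under null expression).
The acceptance script runs a 1000-accession cohort, 300 close + 300 distant
pairs, 10 recurrence replicates, 1000 Mantel permutations and 100 × 100
hold-out draws; these sizes were chosen so the full chain exercises the
species-scale defaults (e.g. the 100-informative-genome and 0.2% frequency
thresholds) at desk scale.

## Known limitations

- The merge rule treats "compatible" as family + class + interval overlap;
  target-site-duplication geometry is not modelled.
- Whether per-accession evidence across merged calls should be `max` or `sum`
  is data-dependent; `max` is the default and both are exposed.
- κ is estimated from pooled synonymous fractions, not per-pair, and is
  treated as noise-free in the elimination SE.
- The binomial CE-shift model can suffer perfect separation when a gene's
  carriers are an exact function of climate; such fits are skipped rather
  than reported with unstable coefficients.
- Poisson GLMs assume equidispersion; overdispersed real counts would need a
  negative-binomial family, which the interface does not currently expose.
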