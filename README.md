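# tipflow

Population-scale analysis of transposable-element (TE) mobilization in
*Arabidopsis thaliana*-like selfing plant panels: genotyping and filtering of
TE insertion polymorphisms (TIPs), frequency spectra and insertion dating,
estimation of the TE insertion substitution rate and of the fraction of
insertions purged by selection, permutation nulls for recurrent gene targeting
and expression impact, and a genotype + environment + G×E Poisson model of
transposition activity with forecasting under future climates.

The package is aimed at population genomicists who have per-sample candidate
TE insertion calls (from split-read/discordant-read detectors), pairwise
divergence tables, gene annotation, expression and bio-climatic data — or who
want to study the behaviour of this analysis chain on synthetic cohorts with
known ground truth, which the built-in generator produces end to end.

## The models

**Genotyping.** Candidate insertion intervals of the same TE family and
variant class are merged transitively at the population level; a site is kept
if at least one sample has ≥ DP supporting reads (DP = 3). Per accession, a
site is called *present* when positive coverage ≥ DP and the reference
coverage over the site drops below 0.8× the flanking coverage, *absent* when
negative coverage ≥ DP without qualifying positive evidence, and *NA*
otherwise. Population filters then remove sites with < 100 informative
genomes, presence sites where no carrier has positive > negative coverage
(heterozygous-like calls, implausible in a selfer), and absence sites flagged
as fragmented or ancestral reference TEs.

**Rates.** With pairwise TIP differences *y* and SNP differences *x*, the
no-intercept regression slope is b = Σxy / Σx². For closely related pairs
(< 500 SNPs apart) the TE insertion substitution rate is

    r = b_close × μ_SNP,   μ_SNP = 0.2511 SNPs per genome per generation.

Long-term SNP divergence is rescaled to its neutral equivalent with
κ = (synonymous fraction, distant pairs) / (synonymous fraction, close pairs),
and the fraction of insertions eventually eliminated is

    E = 1 − b_all / (κ · b_close).

**Dating.** A TIP shared by ≥ 2 accessions is aged from the maximum pairwise
SNP divergence among carriers in a 70-kb window around the site:
age = (max SNPs / 70,000) / μ, with μ = 7 × 10⁻⁹ per site per generation.
*Very recent* TIPs segregate below 0.2% frequency and are private or younger
than 1000 generations.

**G×E model.** Per-accession very-recent counts follow a log-link Poisson GLM
on the top three kinship principal components, a large-effect modifier allele
of the RdDM pathway, z-scored bio-climatic variables (BIO01–BIO19) and
modifier × bio-variable interactions. Variance explained is the deviance
pseudo-R², PVE = 1 − D_res/D_null; bio-variables enter by greedy forward
selection until no candidate adds more than 1% PVE. Climate space is
summarized by PCA into climatic envelopes (CE1–3); family-level environmental
associations use a kinship-restricted (partial) Mantel test; and the fitted
GLM forecasts counts under future climates z-scored with current-epoch
statistics, holding the genetic terms fixed.

## Worked example

```python
import numpy as np, pandas as pd, tipflow as tf
from tipflow.synth import CohortConfig, simulate_cohort, BIO_VARS

cfg = CohortConfig(n_accessions=300, base_rate=3.0, modifier_effect=3.4,
                   retention_prob=0.1, gxe_effects={"BIO04": 0.4}, seed=7)
cohort = simulate_cohort(cfg)

matrix = tf.genotype(cohort.candidates, min_informative=100)
est = tf.estimate_rates(cohort.pairs)
freqs = tf.site_frequencies(matrix)
vr, per_acc, _ = tf.classify_very_recent(freqs, matrix=matrix, freq_threshold=0.01)

clim_z, _ = tf.zscore_climate(cohort.climate)
cur = clim_z[clim_z.epoch == "current"].set_index("accession")[BIO_VARS]
fut = clim_z[clim_z.epoch == "future"].set_index("accession")[BIO_VARS]
data = cohort.panel.set_index("accession").join(cur)
fit, trace = tf.stepwise_select(per_acc.reindex(data.index).to_numpy(), data,
                                ["PC1", "PC2", "PC3", "modifier"], BIO_VARS)
fc = tf.forecast_transposition(fit, data, cur.loc[data.index], fut.loc[data.index])
```

prints (via the provenance log and the fitted objects):

```
                   dp_filter: removed   7, remaining 1804
 superfamily_class_blacklist: removed   4, remaining 1800
             min_informative: removed   5, remaining 1795
       no_carrier_pos_gt_neg: removed   6, remaining 1789
             flagged_absence: removed  23, remaining 1766
TIP/SNP slope (close pairs): 0.3074 +/- 0.0022
substitution rate:           0.0772 per genome per generation
selection scaling kappa:     1.306
elimination fraction:        90.14%
very recent TIPs:            1505 of 1766
stepwise additions:          ['BIO04']
model PVE:                   65.3%
modifier fold-change:        2.98x
forecast delta (carriers):     +0.060 insertions/genome
forecast delta (non-carriers): -0.004 insertions/genome
```

The filter cascade removes exactly the planted violations (DP < 3, few
informative genomes, heterozygous-like evidence, flagged absences, HELITRON
presence calls). The slope and elimination fraction recover the generating
values (0.304 and 1 − retention = 0.9); stepwise selection finds the single
planted bio-variable; carriers of the modifier allele are forecast to gain
insertions under the warmer future climate while non-carriers barely change —
the planted positive G×E interaction.

A `tipflow` command exposes the same steps on files
(`simulate`, `genotype`, `capture-filter`, `sfs`, `date`, `rates`,
`recurrence`, `expression`, `glm`, `mantel`, `envelopes`, `ce-shift`,
`forecast`); run `tipflow --help`.

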