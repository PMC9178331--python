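# Methods

## Data model

Genotypes are biallelic SNP calls stored as alt-allele dosage codes (0 hom-ref,
1 het, 2 hom-alt, −1 missing) in a samples × loci matrix with optional
per-call depth.  Coordinates are 1-based; chromosome order follows file
order.  Every statistic in the package is a pure function of these codes, so
the three paternity methods, the filters and the simulator are all
vectorised.

## Variant filtering

The filters reproduce standard site-filtering semantics on the matrix:

| filter | default | boundary |
|---|---|---|
| call rate | ≥ 0.80 of samples called | a locus at exactly the threshold is kept |
| missing count | ≤ 20 missing calls | kept at exactly the maximum |
| minor allele frequency | ≥ 0.30 | frequencies over non-missing calls only |
| Hardy–Weinberg exact test | drop when p < 0.05 | two-sided exact test, see below |
| depth mask | calls with DP < 5 set missing | calls without depth are never masked |
| distance thinning | ≥ 3 Mb between kept loci | greedy first-kept-wins per chromosome |

The Hardy–Weinberg test conditions on the observed allele counts and sums the
probabilities of all heterozygote counts whose probability does not exceed
that of the observed configuration (no mid-p correction); it is implemented
on the log scale and validated against an exact-rational enumeration oracle
for every genotype-count triple with n ≤ 30.  The composed
"likelihood-panel" recipe runs call-rate → MAF → HWE → depth mask →
missing-count → thinning; the order is configurable because the relative
placement of depth masking and the completeness screens is a legitimate
analysis choice.

## Paternity statistics

**ASR.**  A locus is informative for a (mother, father, offspring) trio iff
all three calls are present; it is abnormal iff some offspring allele occurs
in neither parent's call.  This allele-membership rule — rather than a strict
transmission check — is deliberate: a selfed offspring carries only maternal
alleles, so it scores near zero against *every* hypothetical father, which is
exactly the selfing signature the all-candidates rule (< 0.008 by default)
detects.  A strict-Mendelian variant is exposed as `mode="mendelian"` for
comparison.  The suggested exclusion cutline is the midpoint of the widest
gap between consecutive sorted ssASR values whose midpoint lies in the lower
half of the observed range; when no gap exceeds twice the median spacing the
named default 0.02 is returned.

**IBS.**  Allele sharing per co-called locus is `1 − |dose_a − dose_b|/2`,
averaged.  The acceptance threshold derives from the known mother–offspring
pairs (minimum IBS, floored to 2 decimals, default 0.72); mother–offspring
IBS above 0.84 flags selfing.  An offspring is assigned to its top candidate
only when that IBS clears the threshold and the mother ranks in the top two
candidates overall, i.e. the best-supported parental couple actually contains
the known mother.

**Trio likelihood.**  The error model treats a mistyped genotype as replaced
by a Hardy–Weinberg draw at the locus frequency, applied to the offspring
only (the parents in the motivating design are sequenced several-fold
deeper).  Allele frequencies are estimated from all genotyped samples by
default (configurable) and clamped to [0.001, 0.999].  Natural logs are used
throughout; with error rate 0 a father-impossible locus yields −∞, while a
locus impossible under the mother alone carries no paternal information and
contributes 0.  An assignment requires a positive best LOD (the trio must
beat random paternity) and a delta — best minus second-best LOD — at or above
the simulation-calibrated critical value; ties are never broken by chance but
left unassigned, as are tied row-minimum ASRs and tied top IBS values.

**Critical-delta simulation.**  Offspring are simulated from a known mother;
the true father is among the candidates with probability 0.75, loci are typed
at 0.99 with 1% mistyping, and only offspring with ≥ 500 typed loci are
scored (the defaults; all are parameters).  The first candidate is a
replicate of the offspring's own mother, mirroring an assignment run that
carries a mother replicate to detect selfing — without this the calibration
would overstate deltas, because in real assignment the mother replicate is
almost always the runner-up.  Deltas are evaluated over offspring that would
be assignable at all (positive best LOD), and the returned critical value is
the smallest threshold at which the fraction of correct best candidates
reaches the confidence level.  Deltas are non-negative by construction, so
when the full assignment set already meets the confidence level the critical
value is 0 — the expected outcome for a well-powered panel with a known
mother.  If no threshold reaches the confidence level the function returns
+∞ with a warning.  In the pipeline the minimum-typed-loci requirement is
capped at 90% of the panel size so that small panels remain usable.

**Consensus.**  A father or selfing verdict requires all three methods to
agree; anything else is unassigned.  Couple-summary tables report the ASR
column as an exclusion-style multi-count (an offspring counts under every
father passing the cutline, selfings under all of them), while the IBS,
likelihood and common columns are verdict counts.

## Trait analysis

The sprouting index (SPI) scores spring bud development per plant (0 dormant
… 6 one bud + three leaves, averaged over 5–10 buds).  Summaries report mean,
sample SD (n−1), CV as a percentage, range and n.  Cross comparisons and the
marker screen use the tie-corrected Kruskal–Wallis statistic with chi-square
p-values (group sizes in scope are ≥ 30, so no exact small-sample tables);
the statistic is validated against an independent rank-counting oracle on
small tied designs.  The screen reports markers significant at P < .001 in at
least one year or P < .01 in every year (the two-year rule generalises to
"all years"), keeps only the highest-K marker per linkage group (K compared
in the year of its best p), and renders significance as one star per level
passed among {0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001}, "ns" above 0.1
— the star convention of rank-based QTL screens.  Offspring missing either
the genotype or the trait are excluded pairwise per marker and year.  The
breeding-favorable genotype is the class with the highest mean trait (ties
are all reported), and the half-sib consistency check declares a marker
consistent iff that class attains the (possibly tied) highest mean in a
disjoint holdout set in every year.

## Synthetic-population generator

The generator emulates the motivating breeding design at its study scale: one
clonal mother, 14 candidate fathers and 388 offspring at 2000 unlinked
biallelic loci on 15 chromosomes of 200 Mb, with alt-allele frequencies
uniform on (0.05, 0.95).  Paternity follows a mixture with one dominant
father (weight 0.56), a selfing mass of 0.03, an unsampled-father mass of
0.24 and the remainder spread over the other candidates — the qualitative
structure of an OP population next to a widely planted cultivar.  Offspring
are produced by Mendelian transmission; genotyping error (1%) replaces a call
with a Hardy–Weinberg draw at the locus frequency (the "mistyped locus"
abstraction used by likelihood paternity simulations) and 1% of calls are set
missing; the deeply sequenced parents stay clean.  The trait model is
additive over a few QTL (default standardized effects 0.5/0.35/0.25 on
distinct chromosomes) plus year-correlated normal residuals (correlation 0.6,
reflecting marker effects that persist across years), affinely rescaled per
year to target means 5.465/4.457 and CVs 18.5%/17.6%, then clipped at 0.
With zero genetic and residual variance the trait is the constant target mean
and a warning notes that the CV target is unattainable.

What the generator does **not** emulate: linkage and recombination (loci are
independent, so the thinning filter has no LD to remove), population
structure or relatedness among the candidate fathers, dominance or epistasis
in the trait, and locus- or sample-specific error and depth profiles.
Passing recovery tests therefore demonstrate the statistics' behavior under
clean Mendelian inheritance with random error — they do not certify
performance on data with cryptic relatedness among candidates, which would
compress ASR and IBS separations.

## Numerical choices and problem sizes

Percentages in reports are rounded half-up to one decimal, so the prose
fields recompute exactly from the table counts.  Allele-frequency clamping
(0.001/0.999), the 0/0-locus convention above, and conservative tie handling
are the only places the likelihood departs from the textbook formulas.  The
test suite and the acceptance script run the recovery analyses at the full
study scale (388 offspring × 2000 loci) but calibrate the critical delta with
2000 simulated offspring on a 572-locus panel and the marker screen with 50
replicates of 217 offspring × 150 markers — sizes at which every Monte-Carlo
margin in the assertions is several standard errors wide while the whole
suite stays fast.

## Known limitations

* Only biallelic single-base SNPs are supported; indels and multi-allelic
  records are skipped at input.
* The likelihood error model is offspring-only; a full three-way error model
  would be needed for shallowly sequenced parents.
* Allele frequencies estimated from a sample dominated by one full-sib family
  are biased toward that family; in practice this makes the mother replicate
  score slightly better than the calibration assumes, so a small number of
  unsampled-father offspring can reach weakly positive selfing LODs.  The
  consensus absorbs these (ASR and IBS reject them), but the likelihood
  column alone should not be read as a selfing rate.
* `suggest_asr_cutline` assumes the ssASR distribution separates into a low
  (true-couple/selfing) and a high (false-couple) mass; on panels with no
  such structure it falls back to the named default rather than inventing a
  gap.
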