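# Methods

## S-allele number estimation

### Model

A population segregating for sporophytic self-incompatibility (SSI) holds
some number *N* of S-haplotypes.  A sample of *m* gene copies (2 per diploid
individual) identifies *n* distinct alleles; the repeatability index
estimates the total as

    N = n / (1 - (n - 2) / (m - 2)).

The denominator is the fraction of "repeat" observations beyond the first
two copies; as repeats vanish (n → m) the estimate diverges, and the
implementation returns an explicit unbounded flag rather than a number.
The literature sometimes prints this estimator as the bare expression
`1 - (n-2)/(m-2)`; that form never exceeds ~1.07 and cannot be an allele
count, so the package treats it as shorthand for the ratio form above.  It
remains available behind `repeatability_estimate(..., literal=True)` for
audit.  Rounding is to the nearest integer, ties up (`8.4 → 8`,
`0.933 → 1`); group means average the rounded per-population integers and
report two decimals, computed in decimal arithmetic so printed-table values
round identically.

Properties worth knowing: the estimator is strictly increasing in *n*,
returns exactly *n* when *n* = 2, and its rounded image at m = 16 is
{1, 2, 3, 5, 6, 8, 11, 14, 18, …} — it can never output 4 or 7 from a
16-copy sample.  Validation studies must therefore judge it by bracket
coverage, not point identity.

### Missing-allele inference

Allele-specific screening assays only detect a panel of known alleles, so a
single-amplification individual is ambiguous: homozygote, or carrier of an
undetectable second allele.  The flanking gene B80 sits in strong linkage
disequilibrium with *SRK* and resolves this: B80 homozygotes are called
S-locus homozygotes; B80 heterozygotes whose two haplotypes are not both
compatible with homozygosity gain an explicit unknown copy (`?`).  The edge
case — two different B80 haplotypes both associated only with the same
*SRK* allele (one allele, two genetic backgrounds) — defaults to a
homozygote call, with a `shared_background="two_alleles"` mode for the
conservative alternative.  B80 haplotypes absent from the link map leave
the record untouched and emit a warning; downstream tallying refuses
unresolved records rather than guessing.

Bounds over the unidentified copies: the minimum assumes all missing copies
are one shared novel allele (n_min = n_identified + 1), the maximum that
each is unique (n_max = n_identified + missing copies).  Both assume each
unidentified copy sits in a distinct individual, true of all data the
package ships.

Alleles known to be unlinked to the SI phenotype but co-amplified by the
assay (S45 in the packaged fixtures) are dropped through an exclusion list
before tallying; dropping such a third token restores diploidy.

### Packaged fixtures

`silocus/data/` carries genotype, link-map and metadata tables for the ten
populations whose published tallies are fully determined by the main survey
table (TC, TCA, PTP, WAS, RON, KTT, LPT, PIN, OWB, SBD).  Individual
genotypes were reconstructed from the printed per-allele incidences,
heterozygosity and homozygote calls; the remaining survey populations need
supplementary per-individual data and are deliberately not shipped.  One
known printing quirk: the TC row's heterozygosity prints 0.14 where 1 of 8
individuals is 0.125; the package computes the definition.

## Sporophytic SI genetics

Dominance is a strict partial order over S-alleles.  Only one relation has
direct experimental support — S1 recessive to every other allele — so the
default model asserts exactly that and treats all other pairs as
codominant; explicit `(dominant, recessive)` pairs may be supplied and are
checked for irreflexivity and acyclicity.  Expression is sporophytic on
both sides: a plant presents the dominant allele of its diploid genotype
(both alleles if unordered) on stigma and pollen coat alike, and a
pollination fails when the two expressed sets intersect.

Self-compatibility follows "scenario A": a recessive modifier locus,
unlinked to the S-locus, abolishes SI only in plants homozygous for both S1
and the recessive modifier allele *m*.  Under an F1 sib-cross of two
S1-carrying modifier heterozygotes this predicts a 1/16 SC fraction and
equal quarters of the four S-genotypes, with every SC plant an S1
homozygote but S1 homozygotes also appearing among SI plants — the
observations the model exists to explain.

Design choices in this module:

* **Modifier linkage** — free recombination (the model's premise); the cross
  simulator draws the two loci independently.
* **Male sterility** — no genetic model is available, so it is an
  independent masking probability (default 0) applied after genotype →
  phenotype mapping.
* **Leaky SI** — not generated by the genetic model (no mechanism to encode);
  it arises only from silique-count classification.
* **Phenotype classification** — the 5-of-6 silique rule generalises
  proportionally: SC when full siliques ≥ ⌈5·total/6⌉, SI when empty
  siliques pass the same bar, leaky when ≥ 2 partial siliques and neither
  rule fires, otherwise ambiguous; fewer than six pollinations is an error.
* **Segregation distortion** — a viability coefficient *s* against S1 can
  act on gametes (transmission weight 1 − s) or zygotes (survival
  (1 − s)^copies); segregation data cannot distinguish the two, so both are
  exposed and both default off.
* Exact F2 distributions come from exhaustive 4 × 4 gamete enumeration with
  `fractions.Fraction` probabilities; goodness-of-fit uses Pearson
  chi-square (`scipy.stats.chisquare`, df = classes − 1).

## Bulked-segregant scan

Pools have no diploid genotype, so "homozygous/fixed" is defined on read
fractions: minor-allele fraction ≤ 0.001 (configurable).  All thresholds
are inclusive: allele frequency ≥ 0.10 and score ≥ 25 for a call to
survive filtering.  The score is treated as an opaque per-site quality on a
phred-like scale supplied by the caller or the simulator; no attempt is
made to reproduce any particular caller's internal score.

Divergence of a pool at a site is the fraction of its reads differing from
the chosen reference allele (AL4 by default): 0 means fixation for the
reference.  Windows are 1-based, half-open [start, start + 200 000),
anchored at position 1 and advancing by 10 000 bp while the start does not
pass the chromosome's last SNP; empty windows carry NaN, missing data is
never imputed, and partial terminal windows are retained.  Candidate
regions are maximal runs of ≥ `min_windows` (default 10) consecutive
windows with SC mean ≤ 0.05 and SI mean ≥ 0.35, merged across the step
overlap and ranked by run length, then SC mean, then coordinate.  The
0.05/0.35 defaults encode "SC dips toward fixation with AL4 while SI stays
near 50 % heterozygosity"; they are configuration, not estimates.

The seven per-SNP categories: (1) SC pool fixed; (2) SC fixed, AL4 allele
defined, SI pool polymorphic; (3) SC and SI both fixed on different
alleles; (4) category 2 with the SC allele equal to AL4's; (5) SC fixed on
the MN47 reference base; (6) no SC coverage (suppresses 1–5); (7) indel.
Implications (4) ⇒ (2) ⇒ (1) and (6) ⇒ ¬(1) hold by construction and are
property-tested.  The candidate filter keeps non-indel SNPs where SC is
fixed on the AL4 allele, that allele differs from MN47, and SI is
polymorphic or fixed elsewhere; it is idempotent and monotone.  Per-gene
summaries assign a SNP falling in nested features to the shortest
containing interval.

## Synthetic data

### SI population sampler

Each sampled individual is the offspring of a random compatible mating:
parent genotypes are drawn from the allele frequencies, rejected until the
pollination passes the dominance-aware compatibility check, and one allele
is transmitted per parent.  The default conditions are K alleles in a
linear dominance hierarchy with geometric frequencies (ratio 0.7), most
recessive allele most frequent — the configuration negative
frequency-dependent selection maintains under SSI, and the regime in which
the repeatability index is approximately calibrated.  A rejection cap
raises "population not viable" rather than looping forever.  Partial
genotyping masks off-panel alleles (keeping them recoverable through
emitted B80 genotypes), so estimator validation can compare inferred
bounds against the known K.

The estimator-recovery study uses a fixed panel of the 4 commonest alleles
against true K ∈ {4..10} — mirroring the survey's 7-allele panel against
populations estimated to hold up to 14 haplotypes.  Measured bracket
coverage is ~0.59 overall (200 replicates), ranging from 0 at K = 4 (see
the estimator-image note above: no 16-copy sample can yield the value 4) to
~0.9 at K = 6–8.  Coverage, not point recovery, is the attainable
guarantee.

### F2 pooled-sequencing simulator

The mapping design: two fully homozygous, fully divergent grandparental
backgrounds (AL4-like carrying S1 and the recessive modifier *m*;
MN47-like carrying other S-alleles and *M*), F1 individuals heterozygous
everywhere, F2 from an F1 sib-cross.  Per meiosis each chromosome receives
a Poisson(1) number of crossovers at uniform positions — window-scale
realism, not a calibrated genetic map.  The S-locus sits at 9.5 Mb on a
20 Mb "chromosome 7", the modifier at 10 Mb on "chromosome 5"; scenario-A
phenotypes follow from ancestry at those two positions.  Pools of 10 SC and
10 SI plants are sequenced per site at Poisson(50×) depth with binomial
allele sampling and a symmetric error rate of 0.001 between the two
parental bases; scores are drawn from a tight normal (40 ± 3) so threshold
behaviour is controlled explicitly.  SNP density defaults to 50/Mb.

The default family size is 400 F2 plants.  A 97-plant family — the scale a
greenhouse study can raise — fills a 10-plant SC pool only ~8 % of the
time at the expected 1/16 SC rate, and the simulator treats an unfillable
pool as the error it is; 400 keeps the design identical while making the
pools reliably fillable for replicated validation.

Because scenario A has **two** causal loci with statistically exchangeable
pooled signals, localization success is defined as the top-ranked region
containing either causal position; no ranking could put the S-locus first
in ≥95 % of replicates when the modifier signal is its statistical twin.
The SC pool's fixation for the AL4 haplotype at the modifier is asserted
separately, completing the expected two-region picture.  Measured over 100
seeded replicates at the defaults: 96 top-region hits, 100/100 modifier
fixation.

### What the generators do not emulate

Real pools carry mapping bias, indel-adjacent artefacts, heterogeneous
per-site error, and reference divergence so large that the most
interesting gene can drop out of the SNP calls entirely (the fate of *SRK*
itself against an S13 reference).  Grandparents of a real cross are
outbred and heterozygous, not the idealized homozygous-divergent
backgrounds simulated here (a heterozygosity parameter could roughen this,
but the default is the clean limit).  Passing tests therefore demonstrate
correctness of the estimators, filters and scan logic under the stated
statistical model — not robustness to alignment pathology.

## Numerical conventions

* Rounding: half-up everywhere a table-style value is reported; group means
  computed in decimal arithmetic.
* Coordinates: 1-based positions; windows half-open; BED input converted
  from 0-based half-open on read; GFF3 taken as 1-based inclusive.
* Ties: pool major allele breaks count ties alphabetically; region ranking
  breaks length ties by SC mean then (chrom, start); nested gene assignment
  prefers the shortest interval, then the name.
* Randomness: every stochastic routine takes one integer seed (or a shared
  `numpy` Generator) and is bit-reproducible under it.
* Degenerate inputs raise: empty populations, ploidy violations, unresolved
  genotypes at tally time, depth/count mismatches (with the site named),
  windows of non-positive size, expected-proportion zero with observations.

## Problem sizes in the validation suite

The shipped tests run the full chain at deliberately modest scale: 100
seeded F2 replicates for localization, 200 populations for estimator
recovery, 1000 cross replicates for chi-square calibration, 50 random
1000-SNP fixtures for the window-scan oracle, and 100 000 random SNPs for
classifier consistency.  These sizes give the binomial error bands used in
the assertions; nothing in the logic depends on them.
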