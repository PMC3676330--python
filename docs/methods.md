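# Methods

## The deficit-of-homozygotes model

A recessive lethal acting before genotyping removes homozygotes from the
genotyped cohort. In an AI dairy population, progeny are genotyped together
with their sire and maternal grandsire (MGS), while dams usually are not.
For a window haplotype *k*, the expected number of homozygous progeny under
neutrality is built from transmission probabilities:

    E(k) = sum_ij  n_ij * p_ik * (q_jk + f_k) / 2

* `n_ij` — progeny count of sire *i* out of daughters of MGS *j*;
* `p_ik` — sire transmission probability, 0.5 (heterozygous) or 1
  (homozygous); only sires carrying *k* enter the sum, which makes the
  estimate robust to error in `f_k`;
* `q_jk` — MGS transmission probability to his daughter, 0 / 0.5 / 1;
* `f_k` — frequency of *k* on maternal chromosomes, counted only over
  genotyped animals with at least one progeny (this avoids frequency drift
  across generations biasing the contrast); haplotypes at or below 1% are
  not tested.

The ungenotyped dam carries *k* on her paternal chromosome with probability
`q_jk` and on her maternal chromosome with probability `f_k`, transmitting
either copy with probability ½ — hence the `(q_jk + f_k)/2` factor. When dams
are genotyped, their transmission probability `r_jk` replaces that factor and
E(k) no longer involves `f_k` (asserted as an invariance test).

Haplotype identity is exact allele-string identity over the window;
recombination is ignored in the counting, which is adequate because a
20-marker window at 50k-chip density spans ~1.2 Mb (per-meiosis crossover
probability ~1%).

Significance is the one-cell chi-square `(O-E)^2 / E` on 1 df (upper tail),
without continuity correction. This choice is pinned by a regression test: it
reproduces, at two significant figures, every reported p-value in a bundled
table of 35 published deficit regions from three French dairy breeds
(e.g. E=49, O=0 → 2.6E-12; E=68, O=24 → 9.5E-08). The statistic is symmetric,
but only the deficit direction (O < E) is biologically meaningful, so windows
with O > E are never reported as candidates. The 10⁻⁴ threshold is applied
per haplotype test with no multiple-testing correction — deliberately
matching the published procedure; users should treat borderline regions
accordingly.

Region merging: significant deficit windows are grouped into maximal runs of
consecutive windows per chromosome; within a run, the windows sharing the
run's minimum observed count are merged from the first marker of the
left-most to the last marker of the right-most, carrying the E, O, f and p of
the most significant window among them. The run-local (not chromosome-wide)
minimum is used so that two distinct regions on one chromosome are reported
separately.

## Fertility contrast

Conception is coded 1 if the insemination led to a calving, 0 otherwise.
Matings at risk are carrier bull × daughter of a carrier sire; under complete
lethality the conceptus is homozygous with probability (½)·(½+f)/2, so the
expected conception-rate loss is −µ(½+f)/4 → −µ/8 as f → 0 (−5 points at
µ=40%, −6.25 at µ=50%). Averaged over all daughters of a carrier bull the
loss is only −0.5(½+f)f·µ (−0.69 points at f=0.05, µ=0.5), which is why the
at-risk contrast is the detection design.

Implementation choices where the procedure was open:

* control group = noncarrier bull × daughter of noncarrier sire (cleanest
  null); a flag allows "all non-at-risk matings";
* Welch (unequal-variance) two-sample t-test, two-sided — immaterial at the
  sample sizes involved;
* the loss is the raw group difference in percentage points, not a
  model-adjusted estimate;
* heifers and lactating cows are analysed separately (independent
  confirmation, and heifers have the higher conception rate µ_h, hence the
  larger absolute loss); stars follow *p<0.05, **p<0.01, ***p<0.001.

## Variant filtering

The search region is the detected haplotype extended 6 Mb on each side
(clamped at the chromosome start, half-open in bp internally, printed as Mb
to one decimal) — incomplete linkage disequilibrium between a detected
haplotype and the causative mutation can place the mutation well outside the
window. The genotype filter keeps variants heterozygous in every carrier and
homozygous-reference in every control; missing genotypes fail the condition
by default (a `lenient` flag skips them, useful at modest sequencing depth).
The consequence filter consumes a precomputed annotation table — the two
deleteriousness columns stand for external missense predictors, which are
out of scope to recompute — keeping truncating classes unconditionally and
missense only when both predictors call it damaging; unannotated candidates
are kept with class "unknown" rather than silently dropped.

The key-ancestor association check explains the alt-allele carriers by
haplotypes using a greedy cover (ties broken by name for determinism): a
variant explained by a single haplotype is "exclusively associated"; a
variant observed homozygous in a live genotyped animal is eliminated as a
lethal candidate; a haplotype homozygote that is merely heterozygous for the
variant reveals an ancestral version of the haplotype without the mutation.

## Synthetic-data generator

The generator is a founder-pool gene drop, not a coalescent simulation: the
scan needs haplotype identity-by-state over short windows and an AI family
structure, which founders provide directly. Structure per replicate:

* founder pool of 30 chromosome-length haplotypes; sires and MGS draw two
  copies each; dams are daughters of MGS (paternal copy = MGS gamete with
  recombination, maternal copy = pool draw); progeny are gene-dropped from
  (sire, dam) matings;
* each lethal spec reserves one founder haplotype; its copies are placed by
  balanced allocation — exactly round(f·n) copies per chromosome-slot
  compartment, on distinct animals — so the realized frequency equals the
  target instead of fluctuating binomially. No founder is created as a
  lethal homozygote (at full penetrance such an animal could not be alive);
  homozygous dams and progeny die with probability = penetrance, dams being
  replaced and progeny removed before genotype emission. Viability
  conditioning leaves the realized frequency marginally below target
  (≈f/(1+f) in the unconditioned parts), far inside the tolerance of all
  frequency checks;
* insemination outcomes are Bernoulli with mean µ_parity × (1 − P(homozygous
  conceptus) × penetrance), with the homozygosity probability taken from the
  true parental diplotypes; `fertility_effect=False` instead models a
  non-lethal defect whose homozygotes are alive but never genotyped;
* the VCF generator emits background variants in Hardy-Weinberg proportions
  independent of carrier status plus one causative variant heterozygous in
  all carriers and absent in controls.

Default study conditions (one simulated breed): 80 sires, 80 MGS, 2,000
dams, Poisson(4) progeny per dam → ~8,000 genotyped animals, roughly half of
a mid-sized national cohort; 2 chromosomes × 250 markers over 15 Mb (~60 kb
spacing, matching 50k-chip density so a 20-marker window spans ~1.2 Mb);
recombination 10⁻⁸ per bp per meiosis; mean conception 55% (heifers) and 42%
(cows), inside the 40–55% range typical of dairy AI records; dam genotypes
withheld by default with a flag to emit them. Family-size and
insemination-count distributions are configurable, not inferred from data.

What the generator deliberately does **not** model: linkage-disequilibrium
decay (founder chromosomes are atomic, so detected IBS blocks are long and
merged regions much wider than real ones), selection across generations,
genotyping error, and pedigree errors. Passing tests therefore demonstrate
the statistical machinery — expectation formula, test calibration, power at
cohort scale, filter correctness — not robustness to real-data artefacts.

## Numerical and formatting conventions

* p-values are reported in scientific notation with 2 significant figures
  (IEEE round-half-even, e.g. `2.6E-12`);
* the deficit test is undefined at E=0; such haplotypes are skipped with a
  log entry. Windows that would cross a chromosome boundary are skipped, not
  an error;
* QC boundary conventions are strict: MAF "lower than 3%" removes
  MAF < 0.03, HWE removes p < 10⁻⁴, the haplotype filter keeps f > 1%;
* all randomness flows through numpy Generators seeded from the
  configuration seed (distinct fixed stream offsets per operation), making
  every output bit-for-bit reproducible;
* dropped records are logged at every stage (QC-removed markers, animals
  without a genotyped sire/MGS, unknown-status inseminations, missing
  annotations) so filters are auditable.

## Problem sizes used in the test suite

Unit tests run on ~800-progeny populations (1 chromosome, 60 markers). The
null-calibration test pools >10⁴ (window, haplotype) tests over four null
cohorts and bounds the deficit false-positive rate at 10× the nominal tail
mass (the one-cell chi-square is approximate and family structure correlates
sibling genotypes, so exact nominal calibration is not expected). The
parameter-recovery test runs 20 replicates of the default ~8,000-animal
cohort with a lethal at f=0.05 and penetrance 1, requiring the embedded
window to be reported with O=0 and p<10⁻⁴ in at least 19, and the pooled
at-risk fertility loss to match −µ(½+f)/4 within two binomial standard
errors in both parity classes. The E(k) formula is checked against a
transmission-sampling Monte-Carlo oracle at 10⁶ draws per pedigree on 20
random small pedigrees.
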