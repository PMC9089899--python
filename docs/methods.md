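# Methods

This note documents the models, decision rules and numerical conventions
implemented in `updtrio`, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the known limitations.

## Scope and data model

All inference operates on unphased diploid genotypes at biallelic SNVs for a
child/mother/father trio, coded 0 (hom-ref), 1 (het), 2 (hom-alt), −1
(missing), over sites ordered by (chromosome, position), 1-based inclusive
coordinates as in VCF. Multiallelic sites, indels, sex chromosomes and
phased data are out of scope. VCF I/O goes through pysam; the annotation
table for the filter funnel is tab-delimited with columns
`chrom pos ref alt gene consequence cadd_phred pop_maf gt_child gt_mother
gt_father`.

## Synthetic trio generator

The generator is the package's study substrate, not a fixture dump: each
stage is seeded from a single `numpy` `SeedSequence`, so a configuration is
bit-reproducible.

* **Sites.** Distinct uniform positions per chromosome over GRCh38-like
  autosome lengths (default four chromosomes including a 170.8 Mb
  chromosome 6); alternate-allele frequencies uniform on (0.05, 0.5). The
  default 3,000 sites per chromosome (≈1 site / 60 kb) is dense enough for
  stable kinship and ROH inference while keeping the full test suite well
  under a minute of simulation time; the frequency range keeps most sites
  informative (population heterozygosity ≈ 0.37).
* **Parents.** Each haplotype allele is an independent Bernoulli(alt_freq)
  draw — Hardy-Weinberg genotypes, unrelated parents, no linkage
  disequilibrium.
* **Transmission.** The child receives one maternal and one paternal
  haplotype per chromosome; recombination is off by default (the simplest
  model that preserves all inference behaviour), optionally Poisson-mean
  crossovers with uniform breakpoints. The per-site source-homolog record is
  retained and is required to reconcile exactly with the emitted genotypes
  before error injection.
* **UPD implantation.** Isodisomy copies one designated parental homolog
  into both child haplotypes (homozygosity across the segment); heterodisomy
  copies both homologs of one parent (child genotype equals that parent's).
  Segments on a chromosome must not overlap.
* **Observation model.** Each call is independently set missing with
  probability `missing_rate`, else replaced with probability `error_rate` by
  one of the other two genotypes uniformly — a symmetric perturbation chosen
  for simplicity; real genotyping errors are not symmetric (ref-biased,
  depth-dependent), which is a known mismatch.

What passing tests on this substrate do **not** show: robustness to linkage
disequilibrium, allele-frequency misspecification, batch effects,
CNV/deletion mimics of ROH, or mosaic UPD. The generator emulates the
statistical skeleton the inference assumes, nothing more.

### Annotated-variant table

The funnel fixture (default 90,000 rows) draws consequence classes from an
exome-like mixture (30% exonic/splice), per-class deleteriousness scores from
clipped normals in which only non-synonymous and splice classes regularly
exceed 20, and population frequencies from a mixture of a point mass at zero
(novel) and a long-tailed Beta component. Trio genotypes are Hardy-Weinberg
with Mendelian transmission for common variants and single-carrier-parent
for rare ones. Because the fixture's contract is *exactly k known
survivors*, background rows that would pass all four per-row stage
predicates by chance are redrawn to a common population frequency; the
engineered survivors (validated against the stage predicates at
construction) are then the complete ground-truth survivor set. The four
shipped survivors sit in RAPGEF2, ENPP1, SRCIN1 and MRPH8, the ENPP1 entry
mirroring the motivating proband configuration (child 1/1, mother 0/1,
father 0/0, score 22.8, population frequency 4×10⁻⁴).

## Kinship

The within-family estimator
φ = (N_het,het − 2·N_opp) / (N_het,i + N_het,j) is used rather than the
robust between-family variant because the analysis is within a known trio.
Missing genotypes are pairwise-deleted. The estimator can go negative for
unrelated pairs; that is expected sampling behaviour, not an error. A zero
denominator (no heterozygous calls in either sample) raises an explicit
undefined-kinship error.

Degree thresholds are the powers-of-√2 ladder — 0.354, 0.177, 0.0884,
0.0442 — with **closed upper bounds**: φ = 0.354 is first-degree,
φ = 0.177 is second-degree. The boundary convention is stated because the
interval endpoints themselves carry no convention in common usage.

Uncertainty: the model surface reports a delete-one-block jackknife standard
error over 50 site blocks; with unlinked sites this is close to the binomial
SE and is intended as a sanity scale, not an inferential guarantee under
linkage.

## Trio site classification

The taxonomy is generated by two constructibility predicates. With allele
multisets A(g) (A(0/0)={0,0}, A(0/1)={0,1}, A(1/1)={1,1}):

* biparental: child ∈ {a+b : a ∈ A(mother), b ∈ A(father)};
* single-parent P: child ∈ {a+b : a,b ∈ A(P)} (two copies of one allele,
  or P's exact genotype).

Biparental consistency takes precedence. A site is UPD-informative for P iff
single-parent-P holds and biparental fails; within that, parent het + child
hom is the *iso-informative* class and both-parents-hom-discordant is the
*evidence* class (the only single-site signal heterodisomy produces). When
biparental fails, the two single-parent predicates cannot both hold, so the
classification is total and single-valued over the 27 complete genotype
combinations; child het with both parents homozygous for the same allele is
a plain Mendelian error (de-novo-like), never UPD evidence. Any missing
member makes the site MISSING, excluded from all rates.

The Mendelian-inconsistency rate is (UPD-informative + other-error sites) /
classified sites, per chromosome and genome-wide.

## ROH detection

A deterministic greedy left-to-right scan per chromosome:

* homozygous calls start/extend a run; missing calls are skipped (neither
  extend nor break, not counted);
* heterozygous calls accumulate in a pending buffer; more than
  `max_consecutive_het` (default 1) consecutive hets closes the run;
* when the next homozygous call arrives, pending hets are absorbed only if
  the run's absorbed-het fraction *at that moment* stays ≤
  `max_het_fraction` (default 0.02); otherwise the run closes at its last
  homozygous site and a new run starts. The at-absorption-time check makes
  the scan single-pass and order-deterministic; its visible consequence is
  that a het early in a nascent run (before ~1/max_het_fraction homozygous
  sites) splits rather than being absorbed.
* a closed run is reported iff its span (last hom position − first hom
  position + 1) **strictly exceeds** `min_span_bp` (default 4,000,000 —
  "more than 4 Mb" read literally) and it contains ≥ `min_sites` (default
  25) counted sites. Coordinates are first/last homozygous-site positions —
  conservative, with no interpolation toward flanking heterozygotes.

Boundary behaviour worth knowing: around an implanted isodisomy segment the
child is also homozygous at flanking sites by chance (probability ≈ 0.64 per
site at the default frequencies), so detected runs extend beyond the
implanted interval by a geometric number of sites (~0.1–0.7 Mb at fixture
density). Detected boundaries coincide exactly with the realized maximal
homozygous site stretch; tests assert recovery against that realized truth.

## UPD calling

Per chromosome, evidence combines: maternal/paternal informative-site counts
split by child-ROH membership; ROH runs for all three samples; per-run
parent match fractions (share of the child's homozygous, non-missing run
sites whose allele the parent carries); and, outside child ROH, observed
versus Mendelian-expected counts of *obligate other-parent* sites — sites
where the child carries an allele the putative UPD parent lacks, which must
have come from the other parent. The expected count is Σ (other parent's
alt-or-ref dosage)/2 over sites where the putative parent is homozygous,
computed from the parents' genotypes; the observed/expected ratio is ≈1
under genuine biparental inheritance and ≈0 under heterodisomy.

Four gates, all configurable, all required (defaults in parentheses):
(a) winning-parent informative count ≥ `min_informative` (10);
(b) laterality: winning fraction ≥ `laterality_ratio` (0.95);
(c) every child ROH run's match fraction for the winning parent ≥
`match_threshold` (0.98);
(d) no child run majority-overlapped (> 0.5 of its span) by runs in either
parent — co-located parental ROH points to autozygosity/consanguinity, not
UPD. No-call is a value, not an error. The Mendelian-error concentration
ratio (chromosome rate / rest-of-genome rate) is reported with an
`error_concentration_ok` flag against a factor of 5, as a diagnostic rather
than a fifth gate: at realistic error rates a genuine segmental UPD can sit
below any fixed concentration factor, so gating on it would cost recall
without adding specificity beyond gates (a)–(d).

Mode assignment, given a call: no qualifying child ROH → *heterodisomy*;
ROH holding ≥ 90% of the winning parent's informative sites → *segmental*
when the outside region demonstrably passes the obligate-other-parent
biparental check (ratio ≥ `biparental_threshold` = 0.5, expected count ≥ 1)
and the ROH covers < 90% of the chromosome, else *isodisomy*; anything else
(signal both inside and outside ROH) → *mixed*. A chromosome whose
isodisomic segments coexist with a biparental remainder is thus labelled
"segmental"; the iso+heterodisomic combination is "mixed". Both readings of
a partially isodisomic chromosome are distinguishable in the reported
evidence (informative counts inside/outside, obligate-other-parent ratio),
so a reviewer can audit the label rather than trust it.

Nomenclature follows the standard `upd(<chrom>)mat` / `upd(<chrom>)pat`
rendering, with a strict parser provided for round-tripping.

## Variant filter funnel

Four per-row predicates in fixed order, each boundary strict as worded:
exonic/splice consequence; drop synonymous rows **and** any row with score
< 20 (the stricter of the two grammatical readings of the synonymous/score
clause; the score-applies-to-synonymous-only reading is available via
`synonymous_cadd_only`); population MAF ≤ 0.001, absent records treated as
novel; drop rows whose alternate allele both parents carry (any zygosity) —
the only reading under which a mother-het/father-wild-type proband variant
survives — with missing parental genotypes retained and flagged. Because
all predicates are per-row, the final survivor set is order-invariant; the
per-stage counts are not, so the report records the fixed order. Per-gene
score cutoffs (shipped: ENPP1 → 13.13; unknown genes fall back to the
global threshold of 20 with a flag) use strict "greater than".

Population MAF is a fraction throughout (0.001 = 0.1%); readers of tables
that print percentages must divide by 100 before constructing the
annotation frame.

## Pipeline, preset and problem sizes

`run_pipeline` chains simulate/load → kinship → classification → ROH (all
three samples) → evidence → UPD calls → funnel, writes every intermediate
(VCF, TSV/BED tables, funnel JSON, rendered report), and reconciles each
report section with the standalone module outputs. The `emulate_family6`
preset encodes the motivating study design: four autosomes at 3,000 sites
each, chromosome 6 carrying maternal isodisomy segments of 8.5, 14.6 and
11.0 Mb (the second spanning the ENPP1 locus region), genotyping error
0.2%, missingness 0.2%. At these sizes the whole pipeline runs in a few
seconds and the full test suite (including a 21-scenario caller-recovery
panel and 20 duo replicates of 20,000 sites) completes in well under a
minute; the sizes were chosen as the smallest at which the kinship SE
(≈0.006 at 20,000 sites) and per-chromosome informative counts (tens to
hundreds) leave comfortable margins around every decision threshold.

## Known limitations

* Sites are simulated unlinked; real exomes have LD, which inflates the
  variance of φ and of ROH false-positive behaviour relative to this model.
* The ROH scan is a fixed-rule segmenter, not an HMM; it has no notion of
  allele frequency inside runs and no autozygosity F statistic.
* The caller's gates are frequentist counts with hard thresholds; no
  mosaicism fraction, no probabilistic evidence combination.
* Heterodisomy detection rests entirely on both-parents-homozygous
  discordant sites; with few sites or high relatedness between parents the
  informative count can fall below `min_informative`, producing honest
  no-calls.
* Deleteriousness scores and gene-specific cutoffs are consumed as supplied
  annotations; the package does not compute them.
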