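# updtrio

Trio-based detection of uniparental disomy (UPD) from exome-style genotype
data: within-family kinship estimation, per-site Mendelian inheritance-pattern
classification, runs-of-homozygosity (ROH) screening, per-chromosome UPD
calling with standard `upd(<chrom>)mat` / `upd(<chrom>)pat` nomenclature, and
a stepwise rare-variant filter funnel — together with a synthetic trio
generator that implants UPD segments with exact ground truth, so every stage
can be validated without access to patient data.

## Who this is for

Clinical and research genomics analysts investigating apparent Mendelian
inconsistencies in child/mother/father trios — for example a proband
homozygous for a variant that only one parent carries. Such a configuration
can reflect genotyping error, a deletion, non-paternity, or uniparental
disomy: inheritance of both homologs (or both copies of a segment) of a
chromosome from a single parent. Maternal isodisomy of a recessive disease
allele makes a child homozygous for a variant the father does not carry.

## The statistics at the core

**Kinship.** For two samples, over sites called in both, tally the sites
where both are heterozygous (N<sub>het,het</sub>), where one is
homozygous-reference and the other homozygous-alternate
(N<sub>opp</sub>), and the per-sample heterozygous counts. The
within-family kinship coefficient is

φ = (N<sub>het,het</sub> − 2·N<sub>opp</sub>) / (N<sub>het,i</sub> + N<sub>het,j</sub>)

with expectation 0.5 for duplicates, 0.25 for parent-offspring, and 0 for
unrelated pairs. Degrees follow the standard φ ladder: first-degree in
(0.177, 0.354], second-degree in (0.0884, 0.177], and so on.

**Trio site classes.** Each biallelic site is classified by whether the
child's genotype is constructible from one allele of each parent
(biparental-consistent), from two alleles of one parent only
(UPD-informative for that parent — e.g. mother 0/1, father 0/0, child 1/1,
the maternal-isodisomy hallmark), or from neither (other Mendelian error).

**ROH.** A greedy scan grows runs through homozygous calls, absorbs isolated
heterozygotes under configurable tolerances, skips missing calls, and
reports runs spanning strictly more than 4 Mb by default.

**UPD calling.** Per chromosome, a call requires: enough UPD-informative
sites, ≥95% of them favouring one parent, that parent carrying the child's
homozygous allele at ≥98% of sites inside every child ROH run, and no
majority overlap of child runs by parental runs (which would suggest
autozygosity instead). The mode is isodisomy, heterodisomy, segmental
(UPD confined to ROH with a demonstrably biparental remainder), or mixed.

**Variant funnel.** Exonic/splice consequence → remove synonymous and any
variant with deleteriousness score < 20 → population MAF ≤ 0.001 → remove
variants whose alternate allele both parents carry; plus per-gene score
cutoffs (e.g. ENPP1: 13.13) for candidate review.

## Worked example

```python
from updtrio import TrioUPDModel
from updtrio.pipeline import emulate_family6

cfg = emulate_family6(seed=0)   # chr6 with three maternal isodisomy segments
res = TrioUPDModel.from_simulation(cfg.sim, cfg.upd_segments).fit()
print(res.summary())
```

```
                          Trio UPD Analysis Results
==============================================================================
No. sites:      12000    Chromosomes: 4    Mendelian-inconsistency rate: 0.01074
------------------------------------------------------------------------------
Kinship (within-family estimator)
sample_i sample_j  n_used     phi phi_se       degree
   child   mother   11946  0.2437 0.0044 first-degree
   child   father   11944  0.2154 0.0143 first-degree
  mother   father   11948 -0.0104 0.0078    unrelated
------------------------------------------------------------------------------
Runs of homozygosity
  child    6:29952760-38887049 (8.9 Mb), 6:124679193-140032301 (15.4 Mb), 6:149991280-161506076 (11.5 Mb)
  mother   none
  father   none
------------------------------------------------------------------------------
UPD calls
  upd(6)mat    mode=segmental    informative mat/pat = 99/0  segments=3
==============================================================================
```

Reading the output: both child-parent pairs estimate φ ≈ 0.22–0.24
(first-degree, so non-paternity is excluded), while the parents are mutually
unrelated. The child — and neither parent — carries three long ROH runs on
chromosome 6 that recover the implanted 8.5/14.6/11.0 Mb isodisomy
segments; all 99 UPD-informative sites on chromosome 6 favour the mother and
her alleles match the child inside every run, so the chromosome is called
`upd(6)mat`. The elevated genome Mendelian-inconsistency rate (1.1% versus
the 0.2% genotyping-error background) is concentrated on chromosome 6.

The same analysis is scriptable from the shell:

```bash
updtrio simulate --seed 0 --out trio.vcf
updtrio kinship  --vcf trio.vcf --out kinship.tsv
updtrio roh      --vcf trio.vcf --sample child --out roh.bed
updtrio upd      --vcf trio.vcf --out upd_calls.tsv
updtrio report   --seed 0 --out-dir out/        # full pipeline + funnel
```

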